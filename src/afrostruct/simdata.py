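"""Synthetic SNP-array genotypes with controllable population structure.

The generator emulates a continental-scale survey panel: a handful of
ancestral components, each drifted away from a shared ancestral allele
frequency under the Balding–Nichols model, and population samples whose
individuals are admixed mixtures of those components.  The Balding–Nichols
model draws the frequency of component *k* at a SNP with ancestral
frequency *p* from ``Beta(p(1-F_k)/F_k, (1-p)(1-F_k)/F_k)``, so the drawn
frequency has mean *p* and variance ``F_k p(1-p)``; the expected pairwise
(Hudson) FST between two components is then ``(F_a + F_b)/2``.

The default scenario reproduces the working shape of a continental-scale
sub-Saharan African SNP-array panel: 1,747 post-QC SNPs, six ancestral
components (Khoisan, Pygmies, East-1, East-2, NC-West, NC-East), and a
panel of population samples spanning pure and admixed ancestry profiles.
Component divergence is calibrated against a 15-entry matrix of pairwise
component FST values.  Two calibrations are available: a *star* model
(independent per-component drifts, least-squares fit via
``E[FST_ab] = (F_a+F_b)/2``) and a *tree* model (nested Balding–Nichols
draws down a fitted 6-leaf topology, which reproduces the non-additive
structure of the target matrix far more closely and is what
:func:`default_scenario` uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import warnings

import numpy as np
import pandas as pd
import yaml

from .genio import MISSING, GenotypeMatrix

__all__ = [
    "PopulationSpec",
    "SimulationScenario",
    "ComponentFrequencies",
    "ComponentTree",
    "DriftFit",
    "ComponentTreeFit",
    "COMPONENT_FST_CALIBRATION",
    "DEFAULT_COMPONENT_TOPOLOGY",
    "fit_drifts",
    "fit_component_tree",
    "default_scenario",
    "draw_component_frequencies",
    "simulate_genotypes",
    "resample_admixed_target",
    "scenario_to_yaml",
    "scenario_from_yaml",
]

# Calibration targets: pairwise FST between the six continental ancestry
# components recovered at K=6 (Khoisan, rainforest hunter-gatherers/Pygmies,
# two East African components, Niger-Congo West and Niger-Congo East).
COMPONENT_FST_CALIBRATION: dict[tuple[str, str], float] = {
    ("NC-East", "NC-West"): 0.042,
    ("NC-East", "East-1"): 0.099,
    ("NC-West", "East-1"): 0.081,
    ("NC-East", "East-2"): 0.123,
    ("NC-West", "East-2"): 0.109,
    ("East-1", "East-2"): 0.110,
    ("NC-East", "Pygmies"): 0.097,
    ("NC-West", "Pygmies"): 0.095,
    ("East-1", "Pygmies"): 0.132,
    ("East-2", "Pygmies"): 0.137,
    ("NC-East", "Khoisan"): 0.129,
    ("NC-West", "Khoisan"): 0.132,
    ("East-1", "Khoisan"): 0.165,
    ("East-2", "Khoisan"): 0.158,
    ("Pygmies", "Khoisan"): 0.102,
}

DEFAULT_N_SNPS = 1747
DEFAULT_SEED = 20150911


@dataclass
class PopulationSpec:
    """One population sample: label, size, ancestry mix, optional location."""

    label: str
    n_individuals: int
    ancestry: dict[str, float]  # component -> proportion, sums to 1
    lon: float | None = None
    lat: float | None = None


@dataclass
class DriftFit:
    """Per-component drift coefficients fitted to pairwise FST targets."""

    drifts: dict[str, float]
    residuals: dict[tuple[str, str], float]  # predicted - target per pair

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residuals.values())


@dataclass
class ComponentTree:
    """Node of a rooted component tree for nested Balding–Nichols draws.

    ``drift`` is the Balding–Nichols coefficient of the branch *above* this
    node (0 at the root).  Leaves carry component names.  The effective
    (root-to-leaf) drift of a leaf is ``1 - prod(1 - drift)`` along its
    path, and the expected pairwise FST between leaves a, b is
    ``(f_a + f_b - 2 f_m) / (2 (1 - f_m))`` with ``f_m`` the effective
    drift at their most recent common ancestor — which lets a tree
    reproduce non-additive divergence matrices a star model cannot.
    """

    drift: float
    name: str | None = None
    children: list["ComponentTree"] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out: list[str] = []
        for ch in self.children:
            out.extend(ch.leaves())
        return out

    def effective_drifts(self, _acc: float = 0.0) -> dict[str, float]:
        """Cumulative root-to-leaf drift per component."""
        f = 1.0 - (1.0 - _acc) * (1.0 - self.drift)
        if not self.children:
            return {self.name: f}
        out: dict[str, float] = {}
        for ch in self.children:
            out.update(ch.effective_drifts(f))
        return out

    def mrca_drifts(self) -> dict[tuple[str, str], float]:
        """Effective drift at the MRCA for every leaf pair."""
        out: dict[tuple[str, str], float] = {}

        def walk(node: "ComponentTree", acc: float):
            f = 1.0 - (1.0 - acc) * (1.0 - node.drift)
            for i, a in enumerate(node.children):
                for b in node.children[i + 1 :]:
                    for la in a.leaves():
                        for lb in b.leaves():
                            out[(la, lb)] = out[(lb, la)] = f
            for ch in node.children:
                walk(ch, f)

        walk(self, 0.0)
        return out

    def validate(self) -> None:
        if not self.children and self.name is None:
            raise ValueError("leaf nodes must carry a component name")
        if self.children and len(self.children) != 2:
            raise ValueError("component tree must be binary")
        if not 0 <= self.drift < 1:
            raise ValueError("branch drift must lie in [0, 1)")
        names = self.leaves()
        if len(set(names)) != len(names):
            raise ValueError("duplicate component names in tree")
        for ch in self.children:
            ch.validate()


@dataclass
class SimulationScenario:
    """Generative parameters for a structured genotype panel.

    ``drift`` holds the per-component (effective, root-to-leaf) drifts.
    When ``component_tree`` is None, components are drawn independently at
    those drifts (star model); otherwise frequencies are drawn branch by
    branch down the tree and ``drift`` is reporting metadata.
    """

    n_components: int
    component_names: list[str]
    drift: dict[str, float]  # Balding-Nichols F_k per component, in (0,1)
    n_snps: int
    populations: list[PopulationSpec]
    ancestral_freq_low: float = 0.05
    ancestral_freq_high: float = 0.95
    missing_rate: float = 0.0
    related_pairs: list[tuple[str, str]] = field(default_factory=list)
    component_tree: ComponentTree | None = None
    seed: int = DEFAULT_SEED

    def __post_init__(self) -> None:
        if self.n_components != len(self.component_names):
            raise ValueError("n_components does not match component_names")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name in self.component_names:
            f = self.drift.get(name)
            if f is None or not 0 < f < 1:
                raise ValueError(f"drift for {name!r} must be strictly in (0,1), got {f}")
        for pop in self.populations:
            if pop.n_individuals < 1:
                raise ValueError(f"population {pop.label!r} must have >= 1 individuals")
            q = np.array([pop.ancestry.get(c, 0.0) for c in self.component_names])
            if (q < 0).any() or abs(q.sum() - 1.0) > 1e-9:
                raise ValueError(
                    f"ancestry of {pop.label!r} must be non-negative and sum to 1"
                )
            unknown = set(pop.ancestry) - set(self.component_names)
            if unknown:
                raise ValueError(f"population {pop.label!r} references unknown components {unknown}")
        for pop_label, rel in self.related_pairs:
            if rel not in ("duplicate", "parent_child"):
                raise ValueError(f"unknown relationship {rel!r}")
            if pop_label not in {p.label for p in self.populations}:
                raise ValueError(f"related pair references unknown population {pop_label!r}")
        if self.component_tree is not None:
            self.component_tree.validate()
            if sorted(self.component_tree.leaves()) != sorted(self.component_names):
                raise ValueError("component_tree leaves must match component_names")

    def ancestry_matrix(self) -> np.ndarray:
        """Per-individual ancestry proportions, (total individuals, K)."""
        rows = []
        for pop in self.populations:
            q = np.array([pop.ancestry.get(c, 0.0) for c in self.component_names])
            rows.append(np.tile(q, (pop.n_individuals, 1)))
        return np.vstack(rows)


@dataclass
class ComponentFrequencies:
    """Component x SNP allele frequencies plus the ancestral draw."""

    freqs: np.ndarray  # (K, n_snps), in [0,1]
    component_names: list[str]
    ancestral: np.ndarray  # (n_snps,)

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        if self.freqs.shape != (len(self.component_names), len(self.ancestral)):
            raise ValueError("frequency matrix shape inconsistent with labels/ancestral")
        if ((self.freqs < 0) | (self.freqs > 1)).any():
            raise ValueError("component frequencies must lie in [0,1]")


def fit_drifts(
    targets: dict[tuple[str, str], float] | None = None,
    components: list[str] | None = None,
) -> DriftFit:
    """Least-squares fit of per-component drifts to pairwise FST targets.

    Uses the identity ``E[FST_ab] = (F_a + F_b)/2``: each of the 15 pairwise
    targets gives one linear equation in the 6 unknown drifts.  The system
    is overdetermined, so residuals are reported; one drift per component
    cannot reproduce every pair exactly.
    """
    if targets is None:
        targets = COMPONENT_FST_CALIBRATION
    if components is None:
        seen: dict[str, None] = {}
        for a, b in targets:
            seen.setdefault(a)
            seen.setdefault(b)
        components = list(seen)
    A = np.zeros((len(targets), len(components)))
    y = np.zeros(len(targets))
    for r, ((a, b), v) in enumerate(targets.items()):
        A[r, components.index(a)] = 0.5
        A[r, components.index(b)] = 0.5
        y[r] = v
    F, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ F
    residuals = {pair: float(p - v) for pair, p, v in zip(targets, pred, y)}
    return DriftFit(dict(zip(components, F.astype(float))), residuals)


# Topology used by the default calibration, chosen by exhaustive search over
# all 945 rooted binary topologies for the best least-squares fit to
# COMPONENT_FST_CALIBRATION (the two Niger-Congo components pair up, as do
# the two hunter-gatherer components).
DEFAULT_COMPONENT_TOPOLOGY = (
    ((("NC-East", "NC-West"), ("Pygmies", "Khoisan")), "East-1"),
    "East-2",
)


@dataclass
class ComponentTreeFit:
    """Tree-calibrated component model fitted to pairwise FST targets."""

    tree: ComponentTree
    residuals: dict[tuple[str, str], float]  # predicted - target per pair
    effective_drifts: dict[str, float]

    @property
    def max_abs_residual(self) -> float:
        return max(abs(r) for r in self.residuals.values())


def _build_topology(spec, drifts: dict[int, float], counter: list[int]) -> ComponentTree:
    nid = counter[0]
    counter[0] += 1
    if isinstance(spec, str):
        return ComponentTree(drift=drifts.get(nid, 0.0), name=spec)
    children = [_build_topology(s, drifts, counter) for s in spec]
    return ComponentTree(drift=drifts.get(nid, 0.0), children=children)


def fit_component_tree(
    targets: dict[tuple[str, str], float] | None = None,
    topology=DEFAULT_COMPONENT_TOPOLOGY,
) -> ComponentTreeFit:
    """Fit branch drifts of a component tree to pairwise FST targets.

    One drift per branch (root branch fixed at 0) is optimized by bounded
    least squares against ``FST_ab = (f_a + f_b - 2 f_m)/(2(1 - f_m))``.
    A 6-leaf tree has 10 free branches for 15 targets, and unlike the
    6-parameter star model can place shared drift on internal branches.
    """
    from scipy.optimize import least_squares

    if targets is None:
        targets = COMPONENT_FST_CALIBRATION

    # enumerate nodes in the same preorder as _build_topology
    n_nodes = [0]

    def count(spec):
        n_nodes[0] += 1
        if not isinstance(spec, str):
            for s in spec:
                count(s)

    count(topology)

    def tree_for(x: np.ndarray) -> ComponentTree:
        drifts = {i + 1: float(v) for i, v in enumerate(x)}  # node 0 = root
        return _build_topology(topology, drifts, [0])

    pairs = list(targets)
    y = np.array([targets[p] for p in pairs])

    def resid(x: np.ndarray) -> np.ndarray:
        t = tree_for(x)
        f = t.effective_drifts()
        fm = t.mrca_drifts()
        pred = np.array(
            [
                (f[a] + f[b] - 2 * fm[(a, b)]) / (2 * (1 - fm[(a, b)]))
                for a, b in pairs
            ]
        )
        return pred - y

    n_branches = n_nodes[0] - 1
    sol = least_squares(
        resid, np.full(n_branches, 0.05), bounds=(1e-4, 0.5), method="trf"
    )
    tree = tree_for(sol.x)
    residuals = dict(zip(pairs, (float(r) for r in resid(sol.x))))
    return ComponentTreeFit(tree, residuals, tree.effective_drifts())


_DEFAULT_COMPONENT_ORDER = [
    "NC-East", "NC-West", "East-1", "East-2", "Pygmies", "Khoisan",
]

# Default population panel: ~25 diploids per sample, ancestry profiles
# spanning pure components, two-way and three-way mixtures, and a
# Mozambique-like sample that is almost entirely NC-East.  Coordinates are
# rough sampling locations in decimal degrees (lon, lat).
_DEFAULT_PANEL: list[tuple[str, int, dict[str, float], float, float]] = [
    ("Juhoansi", 25, {"Khoisan": 1.0}, 20.0, -19.8),
    ("Karretjie", 25, {"Khoisan": 0.9, "NC-East": 0.1}, 24.5, -31.5),
    ("Khwe", 25, {"Khoisan": 0.55, "NC-West": 0.35, "East-1": 0.10}, 21.8, -18.0),
    ("Mbuti", 25, {"Pygmies": 1.0}, 28.8, 1.5),
    ("Biaka", 25, {"Pygmies": 0.7, "NC-West": 0.3}, 17.0, 4.0),
    ("Dinka", 25, {"East-1": 1.0}, 28.0, 9.0),
    ("Maasai", 25, {"East-1": 0.7, "East-2": 0.3}, 36.7, -1.5),
    ("Amhara", 25, {"East-2": 1.0}, 39.0, 11.5),
    ("Somali", 25, {"East-2": 0.8, "East-1": 0.2}, 45.0, 5.0),
    ("Yoruba", 25, {"NC-West": 1.0}, 3.9, 7.4),
    ("Mandenka", 25, {"NC-West": 0.95, "East-2": 0.05}, -12.0, 12.0),
    ("Owambo", 25, {"NC-West": 0.7, "NC-East": 0.3}, 16.0, -17.8),
    ("Mozambique", 25, {"NC-East": 0.97, "NC-West": 0.03}, 35.0, -17.0),
    ("Basotho", 25, {"NC-East": 0.65, "NC-West": 0.15, "Khoisan": 0.20}, 27.5, -29.5),
    ("AmaXhosa", 25, {"NC-East": 0.6, "NC-West": 0.15, "Khoisan": 0.25}, 27.0, -32.0),
]


def default_scenario(seed: int = DEFAULT_SEED) -> SimulationScenario:
    """Six-component continental-structure scenario.

    The component tree is fitted at call time from
    :data:`COMPONENT_FST_CALIBRATION`; 1,747 SNPs; fifteen population
    samples of 25 diploids each, including a Mozambique-like population
    that is >=95% NC-East.
    """
    fit = fit_component_tree()
    names = sorted(fit.effective_drifts, key=_DEFAULT_COMPONENT_ORDER.index)
    pops = [
        PopulationSpec(label, n, dict(anc), lon, lat)
        for label, n, anc, lon, lat in _DEFAULT_PANEL
    ]
    return SimulationScenario(
        n_components=6,
        component_names=names,
        drift={c: fit.effective_drifts[c] for c in names},
        n_snps=DEFAULT_N_SNPS,
        populations=pops,
        missing_rate=0.005,
        component_tree=fit.tree,
        seed=seed,
    )


def _bn_draw(p: np.ndarray, f: float, rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols Beta draw around frequencies p at drift f."""
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)


def draw_component_frequencies(scenario: SimulationScenario) -> ComponentFrequencies:
    """Draw ancestral and per-component allele frequencies.

    Ancestral frequencies are Uniform(low, high) per SNP (avoiding
    monomorphic sites, mimicking array ascertainment toward common
    variants).  Star scenarios draw each component independently from the
    ancestral vector; tree scenarios apply one Balding–Nichols draw per
    branch down the component tree, so sister components share the drift
    accumulated on their common ancestral branches.
    """
    rng = np.random.default_rng(scenario.seed)
    p = rng.uniform(scenario.ancestral_freq_low, scenario.ancestral_freq_high, scenario.n_snps)
    by_name: dict[str, np.ndarray] = {}
    if scenario.component_tree is None:
        for name in scenario.component_names:
            by_name[name] = _bn_draw(p, scenario.drift[name], rng)
    else:
        def walk(node: ComponentTree, freq: np.ndarray) -> None:
            if node.drift > 0:
                freq = _bn_draw(freq, node.drift, rng)
            if not node.children:
                by_name[node.name] = freq
                return
            for ch in node.children:
                walk(ch, freq)

        walk(scenario.component_tree, p)
    freqs = np.vstack([by_name[name] for name in scenario.component_names])
    return ComponentFrequencies(freqs, list(scenario.component_names), p)


def _draw_allele_copies(
    q: np.ndarray, freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """One haploid allele copy per individual per SNP under the admixture model."""
    n_snps = freqs.shape[1]
    comp = rng.choice(len(q), size=(n, n_snps), p=q)
    return (rng.random((n, n_snps)) < freqs[comp, np.arange(n_snps)[None, :]]).astype(np.int8)


def _draw_pop_genotypes(
    q: np.ndarray, freqs: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Admixture-model draw: each allele copy picks a component then an allele."""
    return _draw_allele_copies(q, freqs, n, rng) + _draw_allele_copies(q, freqs, n, rng)


def simulate_genotypes(
    scenario: SimulationScenario, freqs: ComponentFrequencies
) -> GenotypeMatrix:
    """Simulate the full panel under the admixture model.

    Each of the two allele copies of individual *i* at SNP *j* independently
    picks component *k* with probability ``q_ik`` and is then the counted
    allele with probability ``P_kj``.  Missingness is applied completely at
    random; related individuals (duplicates or parent-child pairs) are
    appended after their source population.
    """
    if freqs.freqs.shape != (scenario.n_components, scenario.n_snps):
        raise ValueError("component frequency shape inconsistent with scenario")
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    blocks = []
    sample_rows = []
    pop_row_ranges: dict[str, tuple[int, int]] = {}
    pop_q: dict[str, np.ndarray] = {}
    offset = 0
    for pop in scenario.populations:
        q = np.array([pop.ancestry.get(c, 0.0) for c in scenario.component_names])
        g = _draw_pop_genotypes(q, freqs.freqs, pop.n_individuals, rng)
        blocks.append(g)
        for i in range(pop.n_individuals):
            sample_rows.append((f"{pop.label}_{i:03d}", pop.label, pop.lon, pop.lat))
        pop_row_ranges[pop.label] = (offset, offset + pop.n_individuals)
        pop_q[pop.label] = q
        offset += pop.n_individuals

    G = np.vstack(blocks)

    # inject relatives: duplicates copy an existing row; parent-child pairs
    # transmit one allele per SNP from the parent, the other copy drawn from
    # the population's own admixture model
    rel_blocks = []
    for idx, (pop_label, rel) in enumerate(scenario.related_pairs):
        lo, hi = pop_row_ranges[pop_label]
        parent_row = lo + idx % (hi - lo)
        parent = G[parent_row]
        if rel == "duplicate":
            child = parent.copy()
            suffix = "dup"
        else:
            transmitted = np.where(
                parent == MISSING, MISSING,
                (rng.random(scenario.n_snps) < parent / 2.0).astype(np.int8),
            )
            # the untransmitted parental copy contributes nothing; the second
            # allele comes from an unrelated mate in the same population
            mate_copy = _draw_allele_copies(pop_q[pop_label], freqs.freqs, 1, rng)[0]
            child = np.where(transmitted == MISSING, MISSING, transmitted + mate_copy)
            suffix = "child"
        rel_blocks.append(child.astype(np.int8))
        sample_rows.append(
            (f"{pop_label}_{suffix}{idx:02d}", pop_label,
             scenario.populations[[p.label for p in scenario.populations].index(pop_label)].lon,
             scenario.populations[[p.label for p in scenario.populations].index(pop_label)].lat)
        )
    if rel_blocks:
        G = np.vstack([G, np.stack(rel_blocks)])

    if scenario.missing_rate > 0:
        miss = rng.random(G.shape) < scenario.missing_rate
        G = np.where(miss, np.int8(MISSING), G)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population", "lon", "lat"])
    variants = pd.DataFrame(
        {
            "chrom": "1",
            "id": [f"snp{j:05d}" for j in range(scenario.n_snps)],
            "pos": np.arange(1, scenario.n_snps + 1) * 1000,
            "allele1": "A",
            "allele2": "B",
        }
    )
    return GenotypeMatrix(G.astype(np.int8), samples, variants)


def resample_admixed_target(
    genotypes: GenotypeMatrix,
    donor: str,
    pop1: str,
    alpha: float,
    n_individuals: int | None = None,
    seed: int = 0,
    label: str | None = None,
) -> GenotypeMatrix:
    """Resample a synthetic admixed population from two observed samples.

    Each allele copy of each simulated diploid independently derives from
    the *donor* sample with probability ``alpha`` (else from *pop1*) and is
    then a Bernoulli draw from that sample's empirical allele frequency, so
    the expected simulated frequency at every SNP is
    ``alpha * f_donor + (1 - alpha) * f_pop1``.  SNPs where either source
    frequency is undefined (all genotypes missing) are excluded.

    ``n_individuals`` defaults to the donor sample size, keeping estimator
    noise comparable to a real target of that size.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = genotypes.dosages_float()
    freqs = {}
    for pop in (donor, pop1):
        rows = genotypes.sample_indices(pop)  # raises KeyError if absent
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN SNPs -> NaN
            freqs[pop] = np.nanmean(g[rows], axis=0) / 2.0
    if n_individuals is None:
        n_individuals = len(genotypes.sample_indices(donor))
    ok = ~(np.isnan(freqs[donor]) | np.isnan(freqs[pop1]))
    fa, fb = freqs[donor][ok], freqs[pop1][ok]
    m = int(ok.sum())

    dosage = np.zeros((n_individuals, m), dtype=np.int8)
    for _copy in range(2):
        from_donor = rng.random((n_individuals, m)) < alpha
        f = np.where(from_donor, fa[None, :], fb[None, :])
        dosage += (rng.random((n_individuals, m)) < f).astype(np.int8)

    if label is None:
        label = f"{donor}{alpha:g}|{pop1}{1 - alpha:g}"
    samples = pd.DataFrame(
        {
            "sample_id": [f"{label}_{i:03d}" for i in range(n_individuals)],
            "population": label,
        }
    )
    return GenotypeMatrix(dosage, samples, genotypes.variants.iloc[np.flatnonzero(ok)])


# ---------------------------------------------------------------------------
# YAML serialization
# ---------------------------------------------------------------------------

def _tree_to_doc(node: ComponentTree):
    if not node.children:
        return {"drift": float(node.drift), "name": node.name}
    return {
        "drift": float(node.drift),
        "children": [_tree_to_doc(ch) for ch in node.children],
    }


def _tree_from_doc(doc) -> ComponentTree:
    if "children" in doc:
        return ComponentTree(
            drift=float(doc["drift"]),
            children=[_tree_from_doc(d) for d in doc["children"]],
        )
    return ComponentTree(drift=float(doc["drift"]), name=doc["name"])


def scenario_to_yaml(scenario: SimulationScenario, path: str) -> None:
    doc = {
        "n_components": scenario.n_components,
        "component_names": list(scenario.component_names),
        "drift": {k: float(v) for k, v in scenario.drift.items()},
        "n_snps": scenario.n_snps,
        "ancestral_freq_low": scenario.ancestral_freq_low,
        "ancestral_freq_high": scenario.ancestral_freq_high,
        "missing_rate": scenario.missing_rate,
        "related_pairs": [list(p) for p in scenario.related_pairs],
        "component_tree": (
            _tree_to_doc(scenario.component_tree)
            if scenario.component_tree is not None
            else None
        ),
        "seed": scenario.seed,
        "populations": [
            {
                "label": p.label,
                "n_individuals": p.n_individuals,
                "ancestry": {k: float(v) for k, v in p.ancestry.items()},
                "lon": p.lon,
                "lat": p.lat,
            }
            for p in scenario.populations
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def scenario_from_yaml(path: str) -> SimulationScenario:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    pops = [
        PopulationSpec(
            p["label"], p["n_individuals"], p["ancestry"], p.get("lon"), p.get("lat")
        )
        for p in doc["populations"]
    ]
    return SimulationScenario(
        n_components=doc["n_components"],
        component_names=doc["component_names"],
        drift=doc["drift"],
        n_snps=doc["n_snps"],
        populations=pops,
        ancestral_freq_low=doc.get("ancestral_freq_low", 0.05),
        ancestral_freq_high=doc.get("ancestral_freq_high", 0.95),
        missing_rate=doc.get("missing_rate", 0.0),
        related_pairs=[tuple(p) for p in doc.get("related_pairs", [])],
        component_tree=(
            _tree_from_doc(doc["component_tree"])
            if doc.get("component_tree") is not None
            else None
        ),
        seed=doc.get("seed", DEFAULT_SEED),
    )
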