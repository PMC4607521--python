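"""Quality control for SNP-array genotype panels.

The chain mirrors standard array-QC practice for structure analyses:
call-rate filtering of SNPs then individuals, greedy sliding-window LD
pruning on squared dosage correlation, KING-robust kinship estimation with
removal of pairs inferred second-degree or closer, and exclusion of
individuals carrying excess ancestry from an outgroup reference component.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix

# kinship boundary between 2nd- and 3rd-degree relatives: 2^(-7/2)
SECOND_DEGREE_KINSHIP = 0.0884
MIN_PAIR_OVERLAP = 100

__all__ = [
    "QCStage",
    "QCReport",
    "PopFrequencies",
    "SECOND_DEGREE_KINSHIP",
    "filter_call_rate",
    "allele_frequencies",
    "ld_prune",
    "kinship_matrix",
    "remove_related",
    "remove_outgroup_admixed",
]


class AllFilteredError(RuntimeError):
    """Every SNP or every individual was removed by a filter."""


@dataclass
class QCStage:
    name: str
    threshold: float
    n_snps_removed: int = 0
    n_samples_removed: int = 0
    removed_snp_ids: list[str] = field(default_factory=list)
    removed_sample_ids: list[str] = field(default_factory=list)


@dataclass
class QCReport:
    """Bookkeeping of what each QC stage removed."""

    stages: list[QCStage] = field(default_factory=list)
    flagged_pairs: list[tuple[str, str, float]] = field(default_factory=list)

    def add(self, stage: QCStage) -> None:
        self.stages.append(stage)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stage": s.name,
                    "threshold": s.threshold,
                    "n_snps_removed": s.n_snps_removed,
                    "n_samples_removed": s.n_samples_removed,
                }
                for s in self.stages
            ]
        )


# ---------------------------------------------------------------------------
# call rate
# ---------------------------------------------------------------------------

def filter_call_rate(
    G: GenotypeMatrix, snp_threshold: float, sample_threshold: float
) -> tuple[GenotypeMatrix, QCReport]:
    """Drop SNPs below ``snp_threshold`` call rate, then individuals below
    ``sample_threshold`` computed on the surviving SNPs."""
    if not (0 <= snp_threshold <= 1 and 0 <= sample_threshold <= 1):
        raise ValueError("call-rate thresholds must lie in [0,1]")
    obs = ~G.missing_mask()
    snp_cr = obs.mean(axis=0)
    keep_snps = snp_cr >= snp_threshold
    if not keep_snps.any():
        raise AllFilteredError("call-rate filter removed every SNP")
    G1 = G.take_variants(np.flatnonzero(keep_snps))

    obs1 = ~G1.missing_mask()
    samp_cr = obs1.mean(axis=1) if G1.n_variants else np.ones(G1.n_samples)
    keep_samp = samp_cr >= sample_threshold
    if not keep_samp.any():
        raise AllFilteredError("call-rate filter removed every individual")
    G2 = G1.take_samples(np.flatnonzero(keep_samp))

    report = QCReport()
    stage = QCStage("snp_call_rate", snp_threshold)
    stage.n_snps_removed = int((~keep_snps).sum())
    stage.removed_snp_ids = list(G.variants["id"][~keep_snps])
    report.add(stage)
    stage = QCStage("sample_call_rate", sample_threshold)
    stage.n_samples_removed = int((~keep_samp).sum())
    stage.removed_sample_ids = list(G1.samples["sample_id"][~keep_samp])
    report.add(stage)
    return G2, report


# ---------------------------------------------------------------------------
# per-population allele frequencies
# ---------------------------------------------------------------------------

@dataclass
class PopFrequencies:
    """Per-population allele1 frequencies and non-missing copy counts (2n)."""

    populations: list[str]
    variant_ids: list[str]
    freq: np.ndarray  # (n_pops, n_snps); NaN where no data
    copies: np.ndarray  # (n_pops, n_snps) int; 2 * non-missing diploids

    def row(self, population: str) -> int:
        try:
            return self.populations.index(population)
        except ValueError:
            raise KeyError(f"population {population!r} not present") from None


def allele_frequencies(
    G: GenotypeMatrix, grouping: dict[str, str] | None = None
) -> PopFrequencies:
    """Frequency of allele1 among non-missing copies, per SNP per population.

    ``grouping`` maps sample_id to population; by default the matrix's own
    population labels are used.  A population with zero non-missing copies
    at a SNP gets frequency NaN and copies 0.
    """
    if grouping is None:
        labels = G.samples["population"].to_numpy()
    else:
        labels = np.array([grouping[s] for s in G.samples["sample_id"]])
    pops = list(dict.fromkeys(labels))
    g = G.dosages_float()
    freq = np.empty((len(pops), G.n_variants))
    copies = np.empty((len(pops), G.n_variants), dtype=np.int64)
    for r, pop in enumerate(pops):
        rows = g[labels == pop]
        if rows.shape[0] == 0:
            raise ValueError(f"population {pop!r} has no samples")
        n_obs = np.sum(~np.isnan(rows), axis=0)
        copies[r] = 2 * n_obs
        with np.errstate(invalid="ignore"):
            freq[r] = np.nansum(rows, axis=0) / np.maximum(copies[r], 1)
        freq[r, n_obs == 0] = np.nan
    return PopFrequencies(pops, list(G.variants["id"]), freq, copies)


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between SNP columns, pairwise-complete.

    ``g`` is (n_samples, n_window_snps) with NaN for missing.  Zero-variance
    SNPs get r^2 = 0 by convention.
    """
    m = (~np.isnan(g)).astype(np.float64)
    x = np.where(np.isnan(g), 0.0, g)
    n = m.T @ m  # pairwise-complete counts
    sx = x.T @ m  # sum of x over jointly observed
    sxx = (x * x).T @ m
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        n_safe = np.maximum(n, 1)
        cov = sxy / n_safe - (sx / n_safe) * (sx.T / n_safe)
        varx = sxx / n_safe - (sx / n_safe) ** 2
        r2 = cov**2 / (varx * varx.T)
    r2[~np.isfinite(r2)] = 0.0
    r2[n < 2] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    G: GenotypeMatrix,
    window_snps: int = 200,
    step_snps: int = 25,
    r2_max: float = 0.4,
) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy sliding-window LD pruning.

    Within each window of ``window_snps`` consecutive SNPs (stepping by
    ``step_snps``, never crossing a chromosome), while any retained pair has
    squared dosage correlation above ``r2_max``, the member of the worst
    pair with the lower minor-allele frequency is removed (ties: later map
    position).  After completion no retained pair within any window exceeds
    the cutoff.
    """
    g = G.dosages_float()
    chroms = G.variants["chrom"].to_numpy()
    maf = np.minimum(np.nanmean(g, axis=0) / 2.0, 1 - np.nanmean(g, axis=0) / 2.0)
    keep = np.ones(G.n_variants, dtype=bool)

    for chrom in dict.fromkeys(chroms):
        idx_all = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx_all):
            window = idx_all[start : start + window_snps]
            live = window[keep[window]]
            if len(live) > 1:
                r2 = _pairwise_r2(g[:, live])
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    # drop the lower-MAF member; ties -> later position
                    vi, vj = live[i], live[j]
                    if (maf[vi], -vi) < (maf[vj], -vj):
                        drop = i
                    else:
                        drop = j
                    keep[live[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + window_snps >= len(idx_all):
                break
            start += step_snps

    report = QCReport()
    stage = QCStage("ld_prune", r2_max)
    stage.n_snps_removed = int((~keep).sum())
    stage.removed_snp_ids = list(G.variants["id"][~keep])
    report.add(stage)
    return G.take_variants(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

def kinship_matrix(G: GenotypeMatrix) -> pd.DataFrame:
    """KING-robust pairwise kinship from identity-by-state counts.

    For a pair (i, j), ``phi = (N_het_both - 2 * N_opposite_hom) /
    (N_het_i + N_het_j)`` where counts are over jointly non-missing SNPs.
    Robust to population structure because it conditions on the pair's own
    heterozygosity rather than panel allele frequencies.  Duplicates give
    phi ~ 0.5, parent-child ~ 0.25; pairs above 0.0884 are second degree or
    closer.  Pairs with fewer than 100 jointly observed SNPs are flagged
    ``insufficient_overlap`` and their estimate set to NaN.
    """
    if G.n_samples < 2:
        raise ValueError("kinship needs >= 2 individuals")
    d = G.dosages
    het = (d == 1).astype(np.float64)
    hom0 = (d == 0).astype(np.float64)
    hom2 = (d == 2).astype(np.float64)
    obs = (~G.missing_mask()).astype(np.float64)

    n_joint = obs @ obs.T
    het_het = het @ het.T
    opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_i = het @ obs.T  # het in i among jointly observed with j
    denom = het_i + het_i.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (het_het - 2 * opp) / denom

    ids = G.samples["sample_id"].to_numpy()
    rows = []
    for i in range(G.n_samples):
        for j in range(i + 1, G.n_samples):
            insufficient = n_joint[i, j] < MIN_PAIR_OVERLAP
            rows.append(
                {
                    "id1": ids[i],
                    "id2": ids[j],
                    "kinship": np.nan if insufficient else phi[i, j],
                    "n_snps": int(n_joint[i, j]),
                    "insufficient_overlap": bool(insufficient),
                }
            )
    return pd.DataFrame(rows)


def remove_related(
    G: GenotypeMatrix,
    kinship: pd.DataFrame,
    threshold: float = SECOND_DEGREE_KINSHIP,
) -> tuple[GenotypeMatrix, QCReport]:
    """Iteratively drop the individual in the most flagged pairs.

    Ties are broken by lower call rate, then by later sample index, until no
    pair exceeds the kinship threshold.
    """
    flagged = kinship[kinship["kinship"] > threshold][["id1", "id2", "kinship"]]
    pairs = {frozenset((r.id1, r.id2)): r.kinship for r in flagged.itertuples()}
    call_rate = dict(
        zip(G.samples["sample_id"], (~G.missing_mask()).mean(axis=1))
    )
    index_of = {s: i for i, s in enumerate(G.samples["sample_id"])}

    removed: list[str] = []
    live = dict(pairs)
    while live:
        counts: dict[str, int] = {}
        for pair in live:
            for s in pair:
                counts[s] = counts.get(s, 0) + 1
        # most pairs first; ties -> lower call rate, then later sample index
        victim = max(counts, key=lambda s: (counts[s], -call_rate[s], index_of[s]))
        removed.append(victim)
        live = {p: v for p, v in live.items() if victim not in p}

    keep = [i for s, i in index_of.items() if s not in set(removed)]
    report = QCReport(
        flagged_pairs=[(min(p), max(p), float(v)) for p, v in pairs.items()]
    )
    stage = QCStage("remove_related", threshold)
    stage.n_samples_removed = len(removed)
    stage.removed_sample_ids = removed
    report.add(stage)
    return G.take_samples(sorted(keep)), report


# ---------------------------------------------------------------------------
# outgroup-admixture exclusion
# ---------------------------------------------------------------------------

def remove_outgroup_admixed(
    Q: pd.DataFrame, outgroup_component: str, threshold: float = 0.10
) -> tuple[list[str], QCReport]:
    """Drop individuals whose ancestry from an outgroup component exceeds
    ``threshold``.

    ``Q`` is indexed by sample_id with one column per component; intended to
    be run on a low-K fit that includes an outgroup reference population
    (e.g. a European sample at K=4).  Returns the kept sample ids.
    """
    if outgroup_component not in Q.columns:
        raise KeyError(f"component {outgroup_component!r} not in Q")
    excess = Q[outgroup_component] > threshold
    kept = list(Q.index[~excess])
    report = QCReport()
    stage = QCStage(f"outgroup_admixture[{outgroup_component}]", threshold)
    stage.n_samples_removed = int(excess.sum())
    stage.removed_sample_ids = list(Q.index[excess])
    report.add(stage)
    return kept, report
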