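"""Patterson's f3 admixture test with block jackknife, and power analysis.

For a trio (Target; A, B) the per-SNP statistic is ``(c-a)(c-b)`` with c,
a, b the sample allele frequencies; a significantly negative mean over
SNPs indicates that the target carries ancestry from populations related
to both A and B.  Because sample frequencies are noisy, the unbiased
estimator subtracts the target heterozygosity term ``h_c / (2 n_c)`` with
``h_c = c(1-c) * 2n_c / (2n_c - 1)``; a switch disables the correction for
population-parameter (closed-form) tests.

Standard errors come from a delete-one-block jackknife over consecutive
blocks of SNPs (default 100 per block, weighted for the ragged final
block), giving the Z-score used with the conventional Z < -3 significance
rule.

The power analysis resamples synthetic targets that mix a donor and a
second population in proportion alpha : 1-alpha and records how often the
test fires across an alpha grid.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix
from .qc import allele_frequencies
from .simdata import resample_admixed_target

Z_SIGNIFICANT = -3.0

__all__ = [
    "F3Result",
    "CVPowerDesign",
    "Z_SIGNIFICANT",
    "f3_per_snp",
    "block_jackknife",
    "f3_test",
    "f3_from_freqs",
    "f3_all_trios",
    "significant_counts",
    "cv_f3_power",
]


@dataclass
class F3Result:
    target: str
    popA: str
    popB: str
    f3_hat: float
    jackknife_se: float
    z_score: float
    n_snps_used: int
    block_size_snps: int
    n_blocks: int

    @property
    def significant(self) -> bool:
        return self.z_score < Z_SIGNIFICANT


def f3_per_snp(
    c: np.ndarray,
    n_c: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    het_correction: bool = True,
) -> np.ndarray:
    """Per-SNP f3 contributions; NaN where any frequency is missing.

    ``n_c`` is the target's diploid sample size per SNP (used only when the
    heterozygosity correction is on); SNPs with ``n_c < 2`` are excluded.
    """
    c = np.asarray(c, float)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    out = (c - a) * (c - b)
    if het_correction:
        n_c = np.asarray(n_c, float)
        with np.errstate(invalid="ignore", divide="ignore"):
            h_c = c * (1 - c) * (2 * n_c) / (2 * n_c - 1)
            out = out - h_c / (2 * n_c)
        out = np.where(n_c >= 2, out, np.nan)
    return out


def block_jackknife(
    contributions: np.ndarray, block_size: int = 100, weighted: bool = True
) -> tuple[float, float, int]:
    """Delete-one-block jackknife mean and SE over consecutive blocks.

    Blocks are consecutive runs of ``block_size`` values; the final block
    may be short.  The weighted form (block-size weights, the standard
    treatment for unequal blocks) is the default; the unweighted form
    treats all blocks equally.  Returns (estimate, SE, n_blocks).
    """
    x = np.asarray(contributions, float)
    x = x[~np.isnan(x)]
    n = x.size
    n_blocks = int(np.ceil(n / block_size))
    if n_blocks < 2:
        raise ValueError("insufficient SNPs for jackknife (need >= 2 blocks)")
    theta = x.mean()
    total = x.sum()
    bounds = [(i * block_size, min((i + 1) * block_size, n)) for i in range(n_blocks)]
    m = np.array([hi - lo for lo, hi in bounds], float)
    block_sums = np.array([x[lo:hi].sum() for lo, hi in bounds])
    theta_del = (total - block_sums) / (n - m)

    if weighted:
        g = n_blocks
        h = n / m
        theta_J = g * theta - ((1 - m / n) * theta_del).sum()
        tau = h * theta - (h - 1) * theta_del
        var = np.sum((tau - theta_J) ** 2 / (h - 1)) / g
    else:
        g = n_blocks
        var = (g - 1) / g * np.sum((theta_del - theta_del.mean()) ** 2)
    return float(theta), float(np.sqrt(var)), n_blocks


def f3_from_freqs(
    c: np.ndarray,
    n_c: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    labels: tuple[str, str, str] = ("target", "popA", "popB"),
    block_size: int = 100,
    het_correction: bool = True,
    weighted_jackknife: bool = True,
) -> F3Result:
    """f3 test from pre-computed frequencies (SNPs aligned across inputs)."""
    contrib = f3_per_snp(c, n_c, a, b, het_correction)
    contrib = contrib[~(np.isnan(c) | np.isnan(a) | np.isnan(b))]
    used = contrib[~np.isnan(contrib)]
    f3_hat, se, n_blocks = block_jackknife(used, block_size, weighted_jackknife)
    z = f3_hat / se if se > 0 else np.nan
    return F3Result(
        target=labels[0], popA=labels[1], popB=labels[2],
        f3_hat=f3_hat, jackknife_se=se, z_score=float(z),
        n_snps_used=int(used.size), block_size_snps=block_size, n_blocks=n_blocks,
    )


def f3_test(
    G: GenotypeMatrix,
    target: str,
    popA: str,
    popB: str,
    block_size: int = 100,
    het_correction: bool = True,
    weighted_jackknife: bool = True,
) -> F3Result:
    """f3(Target; A, B) with block-jackknife SE on one genotype matrix."""
    if len({target, popA, popB}) != 3:
        raise ValueError("target, popA and popB must be three distinct populations")
    pf = allele_frequencies(G)
    rt, ra, rb = pf.row(target), pf.row(popA), pf.row(popB)
    return f3_from_freqs(
        pf.freq[rt], pf.copies[rt] / 2.0, pf.freq[ra], pf.freq[rb],
        labels=(target, popA, popB), block_size=block_size,
        het_correction=het_correction, weighted_jackknife=weighted_jackknife,
    )


def f3_all_trios(G: GenotypeMatrix, block_size: int = 100) -> pd.DataFrame:
    """All (target; {A,B}) trios: P(P-1)(P-2)/2 rows for P populations."""
    pops = G.populations
    if len(pops) < 3:
        raise ValueError("need at least 3 populations")
    pf = allele_frequencies(G)
    rows = []
    for target in pops:
        others = [p for p in pops if p != target]
        for popA, popB in itertools.combinations(others, 2):
            rt, ra, rb = pf.row(target), pf.row(popA), pf.row(popB)
            res = f3_from_freqs(
                pf.freq[rt], pf.copies[rt] / 2.0, pf.freq[ra], pf.freq[rb],
                labels=(target, popA, popB), block_size=block_size,
            )
            rows.append(
                {
                    "target": target, "popA": popA, "popB": popB,
                    "f3": res.f3_hat, "se": res.jackknife_se, "z": res.z_score,
                    "n_snps": res.n_snps_used, "n_blocks": res.n_blocks,
                    "negative": res.f3_hat < 0, "significant": res.significant,
                }
            )
    return pd.DataFrame(rows)


def significant_counts(trios: pd.DataFrame) -> pd.DataFrame:
    """Per-target counts of negative and significant (Z < -3) f3 statistics."""
    return (
        trios.groupby("target", sort=False)
        .agg(
            n_tests=("z", "size"),
            n_negative=("negative", "sum"),
            n_significant=("significant", "sum"),
            min_z=("z", "min"),
        )
        .reset_index()
    )


# ---------------------------------------------------------------------------
# resampling-based power analysis
# ---------------------------------------------------------------------------

@dataclass
class CVPowerDesign:
    """Design of the resampling f3 power analysis.

    A synthetic target mixing ``donor`` (proportion alpha) and ``pop1``
    (1 - alpha) is resampled ``n_reps`` times per alpha and tested with
    f3(target; donor, pop1).  The default grid 0.05..0.95 in steps of 0.05
    with 100 replicates gives 1,900 tests per donor/pop1 pair.
    """

    donor: str
    pop1: str
    alpha_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.round(np.arange(0.05, 0.951, 0.05), 2))
    )
    n_reps: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        alphas = tuple(float(a) for a in self.alpha_grid)
        if any(not 0 < a < 1 for a in alphas):
            raise ValueError("alphas must lie strictly in (0, 1)")
        if list(alphas) != sorted(alphas):
            raise ValueError("alpha_grid must be sorted")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        self.alpha_grid = alphas

    @property
    def n_tests(self) -> int:
        return len(self.alpha_grid) * self.n_reps


def cv_f3_power(
    G: GenotypeMatrix,
    design: CVPowerDesign,
    block_size: int = 100,
    n_individuals: int | None = None,
) -> pd.DataFrame:
    """Power of the f3 test on resampled admixed targets.

    Returns one row per alpha with the replicate count, the count and
    proportion of tests with Z < -3, and the Z-score range.
    """
    pf = allele_frequencies(G)
    donor_f = pf.freq[pf.row(design.donor)]
    pop1_f = pf.freq[pf.row(design.pop1)]
    all_ids = G.variants["id"].to_numpy()
    rows = []
    for ai, alpha in enumerate(design.alpha_grid):
        zs = np.empty(design.n_reps)
        for rep in range(design.n_reps):
            seed = int(
                np.random.SeedSequence([design.seed, ai, rep]).generate_state(1)[0]
                % (2**31)
            )
            target = resample_admixed_target(
                G, design.donor, design.pop1, alpha,
                n_individuals=n_individuals, seed=seed, label="simulated_target",
            )
            if target.n_variants == G.n_variants:
                fa, fb = donor_f, pop1_f
            else:
                idx = np.flatnonzero(np.isin(all_ids, target.variants["id"].to_numpy()))
                fa, fb = donor_f[idx], pop1_f[idx]
            tfreq = target.dosages.mean(axis=0) / 2.0  # resampled targets are complete
            n_c = np.full(target.n_variants, target.n_samples, dtype=float)
            res = f3_from_freqs(
                tfreq, n_c, fa, fb,
                labels=("simulated_target", design.donor, design.pop1),
                block_size=block_size,
            )
            zs[rep] = res.z_score
        n_sig = int((zs < Z_SIGNIFICANT).sum())
        rows.append(
            {
                "donor": design.donor, "pop1": design.pop1, "alpha": alpha,
                "n_reps": design.n_reps, "n_significant": n_sig,
                "power": n_sig / design.n_reps,
                "mean_z": float(zs.mean()), "min_z": float(zs.min()),
                "max_z": float(zs.max()),
            }
        )
    return pd.DataFrame(rows)
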