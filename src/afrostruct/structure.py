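"""Model-based ancestry estimation and PCA.

The admixture model treats each genotype ``g_ij`` as a Binomial(2, f_ij)
draw with ``f_ij = sum_k q_ik p_kj``: individual *i* draws each of its two
allele copies from ancestral component *k* with probability ``q_ik`` and
the copy is the counted allele with probability ``p_kj``.  The
log-likelihood

    L(Q, P) = sum_ij [ g_ij ln f_ij + (2 - g_ij) ln (1 - f_ij) ]

(missing entries excluded) is maximised by alternating multiplicative EM
updates of Q and P; EM guarantees a monotone likelihood, which the fit
records and asserts.  The number of components K is chosen by held-out
genotype prediction: random entries are masked, the model is refit, and the
masked dosages are scored against the predicted dosage ``2 f_ij``.

FST between fitted components treats the P rows as population allele
frequency parameters and applies the Hudson-form ratio of averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .genio import GenotypeMatrix

P_EPS = 1e-6  # clamp for component frequencies, prevents log(0)

__all__ = [
    "PCAResult",
    "AdmixtureFit",
    "CVResult",
    "pca",
    "admixture_fit",
    "admixture_cv",
    "masked_cv_error",
    "component_fst",
    "align_components",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coordinates: np.ndarray  # (n_samples, n_components)
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray


def pca(G: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """Standardized genotype PCA.

    Missing dosages are mean-imputed per SNP; each SNP is centred and
    scaled by ``sqrt(p(1-p))`` with *p* the sample allele frequency
    (the usual drift-variance standardization); zero-variance SNPs are
    dropped; coordinates come from the SVD of the standardized matrix.
    """
    g = G.dosages_float()
    mean = np.nanmean(g, axis=0)
    g = np.where(np.isnan(g), mean[None, :], g)
    p = mean / 2.0
    scale = np.sqrt(p * (1 - p))
    ok = scale > 0
    x = (g[:, ok] - mean[None, ok]) / scale[None, ok]
    max_rank = min(x.shape) - 1 if min(x.shape) > 1 else 1
    if n_components > max_rank:
        warnings.warn(
            f"requested {n_components} components exceeds rank; truncating to {max_rank}",
            stacklevel=2,
        )
        n_components = max_rank
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    n = x.shape[0]
    eig = s**2 / (n - 1)
    total = eig.sum()
    coords = u[:, :n_components] * s[None, :n_components]
    return PCAResult(coords, eig[:n_components], eig[:n_components] / total)


# ---------------------------------------------------------------------------
# admixture EM
# ---------------------------------------------------------------------------

@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray  # (n_samples, K), rows sum to 1
    P: np.ndarray  # (K, n_snps), clamped to [P_EPS, 1-P_EPS]
    loglik: float
    n_iter: int
    seed: int
    converged: bool
    component_names: list[str] = field(default_factory=list)
    loglik_trace: np.ndarray | None = None


def _em_core(
    G: np.ndarray,
    W: np.ndarray,
    K: int,
    rng: np.random.Generator,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Multiplicative EM on weighted (0/1 mask W) genotypes.

    Returns (Q, P, loglik trace, converged).  Both Q and P are updated from
    the same posterior expectations each iteration, the standard EM for
    this model, which is monotone in the likelihood.
    """
    N, M = G.shape
    Q = rng.dirichlet(np.ones(K), N)
    P = rng.uniform(0.05, 0.95, (K, M))
    Gw = G * W
    G2w = (2.0 - G) * W
    trace = []
    converged = False
    for _ in range(max_iter):
        F = np.clip(Q @ P, P_EPS, 1 - P_EPS)
        ll = float(np.sum(Gw * np.log(F) + G2w * np.log1p(-F)))
        if trace and ll - trace[-1] < tol:
            trace.append(ll)
            converged = True
            break
        trace.append(ll)
        A = Gw / F
        B = G2w / (1 - F)
        Qn = Q * (A @ P.T + B @ (1 - P).T)
        Qn /= Qn.sum(axis=1, keepdims=True)
        Pnum = P * (Q.T @ A)
        Pden = Pnum + (1 - P) * (Q.T @ B)
        P = np.clip(Pnum / np.maximum(Pden, 1e-300), P_EPS, 1 - P_EPS)
        Q = Qn
    return Q, P, np.array(trace), converged


def admixture_fit(
    G: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 2000,
) -> AdmixtureFit:
    """Fit the K-component admixture model by EM.

    ``tol`` is the absolute log-likelihood gain below which iteration
    stops.  With K=1 the model collapses: Q is all ones and P equals the
    observed allele frequencies (the EM reaches this in one step).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    g = G.dosages_float() if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    W = (~np.isnan(g)).astype(np.float64)
    g = np.where(np.isnan(g), 0.0, g)
    rng = np.random.default_rng(seed)
    Q, P, trace, converged = _em_core(g, W, K, rng, tol, max_iter)
    if not np.isfinite(trace[-1]):
        raise FloatingPointError(
            f"non-finite log-likelihood at iteration {len(trace)}"
        )
    return AdmixtureFit(
        K=K, Q=Q, P=P, loglik=float(trace[-1]), n_iter=len(trace),
        seed=seed, converged=converged, loglik_trace=trace,
    )


def align_components(reference: np.ndarray, Q: np.ndarray, P: np.ndarray | None = None):
    """Permute components of (Q, P) to best match a reference Q.

    Uses the Hungarian assignment on the negative correlation between
    ancestry columns; resolves label switching between runs.
    """
    from scipy.optimize import linear_sum_assignment

    K = Q.shape[1]
    cost = np.zeros((K, K))
    for a in range(K):
        for b in range(K):
            ra = reference[:, a] - reference[:, a].mean()
            rb = Q[:, b] - Q[:, b].mean()
            denom = np.sqrt((ra**2).sum() * (rb**2).sum())
            cost[a, b] = -(ra @ rb) / denom if denom > 0 else 0.0
    _, perm = linear_sum_assignment(cost)
    return (Q[:, perm], P[perm] if P is not None else None, perm)


# ---------------------------------------------------------------------------
# cross-validation over K
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    K_values: list[int]
    mean_error: np.ndarray
    sd_error: np.ndarray
    chosen_K: int


def masked_cv_error(
    g: np.ndarray, mask_rows: np.ndarray, mask_cols: np.ndarray, fit: AdmixtureFit
) -> float:
    """Mean squared error between masked dosages and predicted dosage 2*QP."""
    pred = 2.0 * np.clip(fit.Q @ fit.P, P_EPS, 1 - P_EPS)
    return float(np.mean((g[mask_rows, mask_cols] - pred[mask_rows, mask_cols]) ** 2))


def admixture_cv(
    G: GenotypeMatrix | np.ndarray,
    K_range=range(2, 21),
    folds: int = 5,
    seeds_per_K: int = 3,
    seed: int = 0,
    tol: float = 1e-2,
    max_iter: int = 300,
    max_fold_retries: int = 20,
) -> CVResult:
    """Choose K by held-out genotype prediction error.

    Non-missing entries are split into ``folds`` random folds; per fold the
    model is fit with the fold's entries masked (best of ``seeds_per_K``
    random restarts by training likelihood) and scored on the masked
    entries; the chosen K minimizes the mean error across folds.  A fold
    that leaves some individual or SNP with no observed data is
    re-randomized (bounded retries).
    """
    K_values = list(K_range)
    if not K_values:
        raise ValueError("K_range is empty")
    g = G.dosages_float() if isinstance(G, GenotypeMatrix) else np.asarray(G, float)
    W_all = ~np.isnan(g)
    gz = np.where(np.isnan(g), 0.0, g)
    obs = np.argwhere(W_all)
    rng = np.random.default_rng(seed)

    # one fold assignment shared across K so errors are comparable
    for _attempt in range(max_fold_retries):
        perm = rng.permutation(len(obs))
        fold_masks = []
        ok = True
        for f in range(folds):
            hold = obs[perm[f::folds]]
            W = W_all.copy()
            W[hold[:, 0], hold[:, 1]] = False
            if (W.sum(axis=1) == 0).any() or (W.sum(axis=0) == 0).any():
                ok = False
                break
            fold_masks.append((hold, W.astype(np.float64)))
        if ok:
            break
    else:
        raise RuntimeError("could not build folds leaving data in every row/column")

    mean_err = np.empty(len(K_values))
    sd_err = np.empty(len(K_values))
    for ki, K in enumerate(K_values):
        errs = []
        for f, (hold, W) in enumerate(fold_masks):
            best = None
            for s in range(seeds_per_K):
                sub_rng = np.random.default_rng(
                    np.random.SeedSequence([seed, K, f, s])
                )
                Q, P, trace, conv = _em_core(gz, W, K, sub_rng, tol, max_iter)
                if best is None or trace[-1] > best[2]:
                    best = (Q, P, trace[-1])
            fit = AdmixtureFit(K, best[0], best[1], best[2], 0, seed, True)
            errs.append(masked_cv_error(gz, hold[:, 0], hold[:, 1], fit))
        mean_err[ki] = np.mean(errs)
        sd_err[ki] = np.std(errs)
    chosen = K_values[int(np.argmin(mean_err))]
    return CVResult(K_values, mean_err, sd_err, chosen)


# ---------------------------------------------------------------------------
# FST between components
# ---------------------------------------------------------------------------

def component_fst(P: np.ndarray, names: list[str] | None = None):
    """Hudson-form pairwise FST between component frequency vectors.

    P rows are treated as population allele-frequency *parameters* (no
    sampling correction): per SNP the numerator is ``(p_a - p_b)^2`` and the
    denominator ``p_a(1-p_b) + p_b(1-p_a)``; the estimate is the ratio of
    their averages over SNPs.  SNPs fixed identically in both components
    (both 0 or both 1) are excluded from both sums.
    """
    from .popdist import FstMatrix

    P = np.asarray(P, dtype=np.float64)
    K = P.shape[0]
    if K < 2:
        raise ValueError("need at least 2 components")
    if names is None:
        names = [f"comp{k}" for k in range(K)]
    fst = np.zeros((K, K))
    counts = np.zeros((K, K), dtype=np.int64)
    for a in range(K):
        for b in range(a + 1, K):
            pa, pb = P[a], P[b]
            fixed_same = ((pa <= P_EPS) & (pb <= P_EPS)) | ((pa >= 1 - P_EPS) & (pb >= 1 - P_EPS))
            use = ~fixed_same
            num = (pa[use] - pb[use]) ** 2
            den = pa[use] * (1 - pb[use]) + pb[use] * (1 - pa[use])
            fst[a, b] = fst[b, a] = num.sum() / den.sum() if den.sum() > 0 else 0.0
            counts[a, b] = counts[b, a] = int(use.sum())
    return FstMatrix(list(names), fst, counts)
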