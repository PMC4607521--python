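"""Population differentiation: Weir–Cockerham FST, FST trees, ancestry maps.

Pairwise FST between population samples uses the Weir & Cockerham (1984)
variance-component estimator theta: per SNP the among-population (a),
among-individual-within-population (b) and within-individual (c)
components are computed from sample sizes, allele frequencies and observed
heterozygosity, and theta is the ratio of averages ``sum(a) /
sum(a+b+c)`` across SNPs (lower variance than averaging per-SNP ratios;
negative per-SNP components are retained for unbiasedness).

A complete-linkage dendrogram over the FST matrix summarizes population
relationships, and inverse-distance-weighted (IDW) interpolation projects
per-population ancestry proportions onto a geographic grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, HierTree

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "FstMatrix",
    "GeoGrid",
    "wc_fst_components",
    "wc_fst_pair",
    "wc_fst_matrix",
    "hudson_fst_freqs",
    "complete_linkage_tree",
    "great_circle_km",
    "idw_interpolate",
]


@dataclass
class FstMatrix:
    """Symmetric pairwise FST with per-pair SNP counts."""

    labels: list[str]
    values: np.ndarray
    n_snps: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        k = len(self.labels)
        if self.values.shape != (k, k):
            raise ValueError("FST matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("FST matrix must be symmetric")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


# ---------------------------------------------------------------------------
# Weir-Cockerham theta
# ---------------------------------------------------------------------------

def _pop_snp_stats(G: GenotypeMatrix, pop: str):
    """Per-SNP sample size, allele1 frequency and observed het for one population."""
    rows = G.dosages[G.sample_indices(pop)]
    obs = rows != -1
    n = obs.sum(axis=0).astype(np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, rows, 0).sum(axis=0) / (2.0 * n)
        h = (rows == 1).sum(axis=0) / n
    return n, p, h


def wc_fst_components(G: GenotypeMatrix, popA: str, popB: str):
    """Per-SNP Weir–Cockerham a, b, c variance components for two populations.

    Returns (a, b, c, usable) arrays; a SNP is usable when both populations
    have at least 2 genotyped individuals and the site is not monomorphic
    across both samples.
    """
    n1, p1, h1 = _pop_snp_stats(G, popA)
    n2, p2, h2 = _pop_snp_stats(G, popB)
    r = 2.0
    usable = (n1 >= 2) & (n2 >= 2)
    mono = ((p1 <= 0) & (p2 <= 0)) | ((p1 >= 1) & (p2 >= 1))
    usable &= ~mono

    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = (n1 + n2) / r
        nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        c = hbar / 2
    return a, b, c, usable


def wc_fst_pair(G: GenotypeMatrix, popA: str, popB: str) -> float:
    """Weir–Cockerham theta between two populations, ratio of averages."""
    a, b, c, usable = wc_fst_components(G, popA, popB)
    if usable.sum() == 0:
        raise ValueError(f"no usable SNPs between {popA!r} and {popB!r}")
    denom = (a + b + c)[usable].sum()
    if denom == 0:
        return 0.0
    return float(a[usable].sum() / denom)


def wc_fst_matrix(G: GenotypeMatrix) -> FstMatrix:
    """All pairwise Weir–Cockerham theta values."""
    pops = G.populations
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    k = len(pops)
    vals = np.zeros((k, k))
    counts = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            a, b, c, usable = wc_fst_components(G, pops[i], pops[j])
            if usable.sum() == 0:
                raise ValueError(f"no usable SNPs between {pops[i]!r} and {pops[j]!r}")
            denom = (a + b + c)[usable].sum()
            vals[i, j] = vals[j, i] = a[usable].sum() / denom if denom else 0.0
            counts[i, j] = counts[j, i] = int(usable.sum())
    return FstMatrix(pops, vals, counts)


def hudson_fst_freqs(
    p1: np.ndarray, n1: np.ndarray, p2: np.ndarray, n2: np.ndarray
) -> float:
    """Hudson FST from sample frequencies and diploid sample sizes.

    Per SNP: numerator ``(p1-p2)^2 - p1(1-p1)/(2n1-1) - p2(1-p2)/(2n2-1)``,
    denominator ``p1(1-p2) + p2(1-p1)``; ratio of averages.  Used as the
    calibration check for simulated divergence (expected value
    ``(F_a+F_b)/2`` for two drifted populations).
    """
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (2 * n1 - 1) - p2 * (1 - p2) / (2 * n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(num) & np.isfinite(den) & (den > 0)
    return float(num[ok].sum() / den[ok].sum())


# ---------------------------------------------------------------------------
# complete-linkage tree
# ---------------------------------------------------------------------------

def complete_linkage_tree(D: FstMatrix) -> HierTree:
    """Agglomerative clustering with maximum (complete) linkage.

    At each step the two clusters with the smallest maximum member-pair
    distance merge at that height; ties are broken by the lexicographically
    smallest pair of cluster leader labels.  Complete linkage never
    produces height inversions, so the tree is ultrametric.
    """
    labels = D.labels
    vals = D.values
    if np.isnan(vals).any():
        i, j = map(int, np.argwhere(np.isnan(vals))[0])
        raise ValueError(f"NaN distance between {labels[i]!r} and {labels[j]!r}")
    n = len(labels)
    tree = HierTree(list(labels))
    # active cluster: node id -> (member leaf indices, leader label)
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    leader = {i: labels[i] for i in range(n)}
    next_node = n
    while len(active) > 1:
        best = None
        for a in active:
            for b in active:
                if a >= b:
                    continue
                d = max(vals[i, j] for i in active[a] for j in active[b])
                key = tuple(sorted((leader[a], leader[b])))
                if best is None or (d, key) < (best[0], best[3]):
                    best = (d, a, b, key)
        d, a, b, _ = best
        tree.merges.append((a, b, float(d)))
        active[next_node] = active.pop(a) + active.pop(b)
        leader[next_node] = min(leader[a], leader[b])
        next_node += 1
    return tree


# ---------------------------------------------------------------------------
# IDW interpolation
# ---------------------------------------------------------------------------

@dataclass
class GeoGrid:
    """Regular lon/lat grid with interpolated values at each node."""

    lons: np.ndarray  # (n_lon,)
    lats: np.ndarray  # (n_lat,)
    values: np.ndarray  # (n_lat, n_lon)

    def to_frame(self) -> pd.DataFrame:
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {"lon": lon_g.ravel(), "lat": lat_g.ravel(), "value": self.values.ravel()}
        )


def great_circle_km(
    lon1: np.ndarray, lat1: np.ndarray, lon2: np.ndarray, lat2: np.ndarray
) -> np.ndarray:
    """Great-circle distance on a spherical Earth (radius 6371 km), haversine."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def idw_interpolate(
    points: list[tuple[float, float, float]],
    lon_range: tuple[float, float],
    lat_range: tuple[float, float],
    step_deg: float = 1.0,
    power: float = 3.0,
) -> GeoGrid:
    """Inverse-distance-weighted interpolation onto a regular grid.

    Node value = ``sum_i w_i v_i / sum_i w_i`` with ``w_i = d_i^-power`` and
    great-circle distances; a node within 1e-9 km of a sample point takes
    that point's value exactly.  Weights are convex, so every node lies
    within the input value range.
    """
    if not points:
        raise ValueError("need at least one point")
    pts = np.asarray(points, dtype=np.float64)
    # identical coordinates with conflicting values are ambiguous
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            if (
                abs(pts[i, 0] - pts[j, 0]) < 1e-12
                and abs(pts[i, 1] - pts[j, 1]) < 1e-12
                and abs(pts[i, 2] - pts[j, 2]) > 1e-12
            ):
                raise ValueError(
                    f"conflicting values at identical coordinates {tuple(pts[i, :2])}"
                )
    lons = np.arange(lon_range[0], lon_range[1] + step_deg / 2, step_deg)
    lats = np.arange(lat_range[0], lat_range[1] + step_deg / 2, step_deg)
    if lons.size == 0 or lats.size == 0:
        raise ValueError("empty grid")
    lon_g, lat_g = np.meshgrid(lons, lats)
    d = great_circle_km(
        lon_g.ravel()[:, None], lat_g.ravel()[:, None], pts[None, :, 0], pts[None, :, 1]
    )  # (n_nodes, n_points)
    vals = np.empty(d.shape[0])
    exact = d < 1e-9
    has_exact = exact.any(axis=1)
    vals[has_exact] = pts[np.argmax(exact[has_exact], axis=1), 2]
    w = d[~has_exact] ** (-power)
    vals[~has_exact] = (w * pts[None, :, 2]).sum(axis=1) / w.sum(axis=1)
    return GeoGrid(lons, lats, vals.reshape(lat_g.shape))
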