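"""Genotype container and file formats.

The central data structure is :class:`GenotypeMatrix`, an individuals x SNPs
dosage matrix with sample and variant metadata.  Dosages count copies of
allele1 (the "counted" allele, PLINK's A1) — this convention is fixed and
enforced so that allele polarity is consistent across every statistic
computed downstream; silent polarity flips are the classic bug in
f-statistics.

Supported formats: PLINK text (.ped/.map), PLINK 1 binary (.bed/.bim/.fam,
SNP-major 2-bit encoding), Newick for hierarchical trees, and TSV tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # dosage code for a missing genotype

__all__ = [
    "GenotypeMatrix",
    "HierTree",
    "PlinkFormatError",
    "MISSING",
    "read_plink_text",
    "write_plink_text",
    "read_plink_binary",
    "write_plink_binary",
    "write_newick",
    "newick_string",
    "write_table",
    "read_table",
]


class PlinkFormatError(ValueError):
    """Malformed PLINK input (ragged rows, bad magic, >2 alleles...)."""


@dataclass
class GenotypeMatrix:
    """Diploid biallelic dosage matrix with metadata.

    Parameters
    ----------
    dosages
        ``(n_samples, n_variants)`` int8 array with values ``{0, 1, 2}`` or
        :data:`MISSING`.  A dosage counts copies of ``allele1``.
    samples
        DataFrame with columns ``sample_id``, ``population`` and optional
        ``lon``/``lat`` (decimal degrees; NaN when unknown).
    variants
        DataFrame with columns ``chrom`` (string), ``id``, ``pos`` (1-based
        bp), ``allele1``, ``allele2``.
    """

    dosages: np.ndarray
    samples: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.samples = self.samples.reset_index(drop=True)
        self.variants = self.variants.reset_index(drop=True)
        for col in ("lon", "lat"):
            if col not in self.samples.columns:
                self.samples[col] = np.nan
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        bad = ~np.isin(self.dosages, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be 0, 1, 2 or missing (-1)")
        if self.samples["sample_id"].duplicated().any():
            dup = self.samples["sample_id"][self.samples["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        if self.variants["id"].duplicated().any():
            dup = self.variants["id"][self.variants["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate variant id {dup!r}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.samples["population"]))

    def dosages_float(self) -> np.ndarray:
        """Dosages as float64 with missing mapped to NaN."""
        g = self.dosages.astype(np.float64)
        g[self.dosages == MISSING] = np.nan
        return g

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def sample_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero(self.samples["population"].to_numpy() == population)
        if idx.size == 0:
            raise KeyError(f"population {population!r} not present")
        return idx

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[idx], self.samples.iloc[idx], self.variants)

    def take_variants(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(self.dosages[:, idx], self.samples, self.variants.iloc[idx])


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------

def write_plink_text(G: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix.ped`` and ``prefix.map``.

    Population labels are stored in the family-ID column; missing genotypes
    are encoded ``0 0``.
    """
    var = G.variants
    with open(f"{prefix}.map", "w") as fh:
        for _, v in var.iterrows():
            fh.write(f"{v['chrom']}\t{v['id']}\t0\t{v['pos']}\n")
    a1 = var["allele1"].to_numpy()
    a2 = var["allele2"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i in range(G.n_samples):
            s = G.samples.iloc[i]
            fields = [str(s["population"]), str(s["sample_id"]), "0", "0", "0", "-9"]
            row = G.dosages[i]
            for j in range(G.n_variants):
                d = row[j]
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink_text(ped_path: str, map_path: str) -> GenotypeMatrix:
    """Read a .ped/.map pair into a :class:`GenotypeMatrix`.

    Sites must be biallelic.  The counted allele (allele1) at each site is
    taken from the allele order of the first heterozygous genotype — the
    writer emits heterozygotes as ``a1 a2`` — falling back to the first
    non-missing allele in file order at sites with no heterozygote.  (The
    .ped format itself carries no polarity, so a site whose only observed
    genotype class is homozygous allele2 cannot be repolarized on read.)
    """
    variants = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkFormatError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            variants.append((parts[0], parts[1], int(parts[3])))
    n_var = len(variants)

    sample_rows = []
    allele_rows = []  # per sample: array of (a, b) strings
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_var:
                raise PlinkFormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_var} fields, got {len(parts)}"
                )
            sample_rows.append((parts[1], parts[0]))
            allele_rows.append(np.array(parts[6:], dtype=object).reshape(n_var, 2))

    n_samp = len(sample_rows)
    dosages = np.full((n_samp, n_var), MISSING, dtype=np.int8)
    a1s, a2s = [], []
    alleles = np.stack(allele_rows) if allele_rows else np.empty((0, n_var, 2), dtype=object)
    for j in range(n_var):
        col = alleles[:, j, :] if n_samp else np.empty((0, 2), dtype=object)
        observed = [a for a in col.ravel() if a != "0"]
        uniq = list(dict.fromkeys(observed))
        if len(uniq) > 2:
            raise PlinkFormatError(
                f"{ped_path}: variant {variants[j][1]} has >2 alleles: {sorted(set(uniq))}"
            )
        first_het = next(
            (tuple(ab) for ab in col if ab[0] != ab[1] and "0" not in ab), None
        )
        if first_het is not None:
            a1 = first_het[0]
        else:
            a1 = uniq[0] if uniq else "A"
        others = [u for u in uniq if u != a1]
        a2 = others[0] if others else ("B" if a1 != "B" else "C")
        a1s.append(a1)
        a2s.append(a2)
        for i in range(n_samp):
            a, b = col[i]
            if a == "0" or b == "0":
                continue
            dosages[i, j] = (a == a1) + (b == a1)

    samples = pd.DataFrame(sample_rows, columns=["sample_id", "population"])
    var_df = pd.DataFrame(variants, columns=["chrom", "id", "pos"])
    var_df["allele1"] = a1s
    var_df["allele2"] = a2s
    return GenotypeMatrix(dosages, samples, var_df)


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed / .bim / .fam)
# ---------------------------------------------------------------------------

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))
# 2-bit codes, SNP-major: 00 = hom allele1 (dosage 2), 10 = het (1),
# 11 = hom allele2 (0), 01 = missing
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, MISSING: 0b01}
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def write_plink_binary(G: GenotypeMatrix, prefix: str) -> None:
    """Write ``prefix.bed/.bim/.fam`` (PLINK 1, SNP-major)."""
    with open(f"{prefix}.bim", "w") as fh:
        for _, v in G.variants.iterrows():
            fh.write(f"{v['chrom']}\t{v['id']}\t0\t{v['pos']}\t{v['allele1']}\t{v['allele2']}\n")
    with open(f"{prefix}.fam", "w") as fh:
        for _, s in G.samples.iterrows():
            fh.write(f"{s['population']}\t{s['sample_id']}\t0\t0\t0\t-9\n")

    n = G.n_samples
    codes = np.empty_like(G.dosages, dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[G.dosages == d] = c
    n_bytes = math.ceil(n / 4)
    padded = np.zeros((G.n_variants, n_bytes * 4), dtype=np.uint8)
    padded[:, :n] = codes.T  # pad codes are 00 (hom a1) but ignored on read
    shifted = padded.reshape(G.n_variants, n_bytes, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = shifted[..., 0] | shifted[..., 1] | shifted[..., 2] | shifted[..., 3]
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_plink_binary(bed_path: str, bim_path: str, fam_path: str) -> GenotypeMatrix:
    """Read PLINK 1 binary files into a :class:`GenotypeMatrix`."""
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "id", "cm", "pos", "allele1", "allele2"],
        dtype={"chrom": str, "id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["population", "sample_id", "pat", "mat", "sex", "pheno"],
        dtype={"population": str, "sample_id": str},
    )
    n, m = len(fam), len(bim)
    n_bytes = math.ceil(n / 4)
    with open(bed_path, "rb") as fh:
        magic = fh.read(3)
        if magic[:2] != _BED_MAGIC[:2]:
            raise PlinkFormatError(f"{bed_path}: bad magic bytes {magic[:2]!r}")
        if magic[2:3] != b"\x01":
            raise PlinkFormatError(f"{bed_path}: not in SNP-major order")
        body = fh.read()
    expected = m * n_bytes
    if len(body) != expected:
        raise PlinkFormatError(
            f"{bed_path}: expected {expected} data bytes for {n} samples x {m} variants, "
            f"got {len(body)}"
        )
    raw = np.frombuffer(body, dtype=np.uint8).reshape(m, n_bytes)
    codes = np.stack([(raw >> s) & 0b11 for s in (0, 2, 4, 6)], axis=-1).reshape(m, n_bytes * 4)
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T

    samples = fam[["sample_id", "population"]].copy()
    variants = bim[["chrom", "id", "pos", "allele1", "allele2"]].copy()
    return GenotypeMatrix(dosages, samples, variants)


# ---------------------------------------------------------------------------
# Hierarchical trees / Newick
# ---------------------------------------------------------------------------

@dataclass
class HierTree:
    """Rooted binary merge tree over population labels.

    ``merges[i] = (left, right, height)`` creates internal node
    ``n_leaves + i`` by joining child nodes ``left`` and ``right`` at the
    given height (an FST-scale distance).  Leaves are nodes
    ``0 .. n_leaves-1`` in ``labels`` order.  Complete linkage guarantees
    heights are non-decreasing from leaves to root.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def node_height(self, node: int) -> float:
        return 0.0 if node < self.n_leaves else self.merges[node - self.n_leaves][2]

    def validate(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("tree is not fully resolved")
        for left, right, h in self.merges:
            if h < self.node_height(left) - 1e-12 or h < self.node_height(right) - 1e-12:
                raise ValueError("merge heights must be non-decreasing toward the root")


def newick_string(tree: HierTree) -> str:
    """Render a :class:`HierTree` as Newick with branch lengths.

    A branch length is the parent's merge height minus the child's height,
    so leaf-to-root path lengths reproduce the ultrametric merge heights.
    """
    if tree.n_leaves == 1:
        return f"{tree.labels[0]};"
    tree.validate()

    def render(node: int, parent_h: float) -> str:
        bl = parent_h - tree.node_height(node)
        if node < tree.n_leaves:
            return f"{tree.labels[node]}:{bl:.10g}"
        left, right, h = tree.merges[node - tree.n_leaves]
        return f"({render(left, h)},{render(right, h)}):{bl:.10g}"

    root = tree.n_leaves + len(tree.merges) - 1
    left, right, h = tree.merges[-1]
    return f"({render(left, h)},{render(right, h)});"


def write_newick(tree: HierTree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(records, path: str) -> None:
    """Write records (DataFrame or list of dicts) as TSV.

    Column order follows the input; floats are written with enough digits to
    round-trip to 1e-12.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
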