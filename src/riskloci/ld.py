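"""Linkage-disequilibrium regions around sentinel SNPs.

A risk locus is the interval spanning all SNPs with r^2 >= 0.2 to the
sentinel ("LD0.2 region"). The background set is the merged union of the
LD regions of every panel SNP, with any merged interval overlapping a
risk locus removed entirely.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import BackgroundRegions, GenotypeMatrix, HaplotypePanel, RiskLocus
from .intervals import merge_intervals, overlaps

__all__ = [
    "compute_r2",
    "r2_with_sentinel",
    "define_ld_region",
    "build_background_regions",
]

R2_THRESHOLD = 0.2


def _check_polymorphic(v: np.ndarray, name: str) -> None:
    if np.unique(v).size < 2:
        raise ValueError(f"SNP {name} is monomorphic; r^2 undefined")


def compute_r2(
    data: HaplotypePanel | GenotypeMatrix, snp_a: str, snp_b: str
) -> float:
    """Pairwise r^2 between two biallelic SNPs.

    Haplotype input uses D^2 / (p_A p_a p_B p_b); genotype (dosage)
    input uses the squared Pearson correlation of dosages over samples
    non-missing at both SNPs.
    """
    ia, ib = data.snp_index(snp_a), data.snp_index(snp_b)
    if isinstance(data, HaplotypePanel):
        a = data.haplotypes[:, ia].astype(float)
        b = data.haplotypes[:, ib].astype(float)
        _check_polymorphic(a, snp_a)
        _check_polymorphic(b, snp_b)
        p_a, p_b = a.mean(), b.mean()
        d = (a * b).mean() - p_a * p_b
        r2 = d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))
    else:
        a = data.dosages[:, ia].astype(float)
        b = data.dosages[:, ib].astype(float)
        keep = (a >= 0) & (b >= 0)
        a, b = a[keep], b[keep]
        _check_polymorphic(a, snp_a)
        _check_polymorphic(b, snp_b)
        r = np.corrcoef(a, b)[0, 1]
        r2 = r * r
    return float(min(max(r2, 0.0), 1.0))


def r2_with_sentinel(panel: HaplotypePanel, sentinel: str) -> np.ndarray:
    """Vector of r^2 between the sentinel and every panel SNP.

    Monomorphic SNPs get r^2 = 0 (they can never qualify as proxies).
    """
    i = panel.snp_index(sentinel)
    h = panel.haplotypes.astype(float)
    s = h[:, i]
    _check_polymorphic(s, sentinel)
    p = h.mean(axis=0)
    var = p * (1 - p)
    cov = (h * s[:, None]).mean(axis=0) - p * p[i]
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(var > 0, cov * cov / (var * var[i]), 0.0)
    return np.clip(r2, 0.0, 1.0)


def define_ld_region(
    data: HaplotypePanel,
    sentinel: str,
    candidates: pd.DataFrame | None = None,
    r2_threshold: float = R2_THRESHOLD,
    r2_table: pd.Series | None = None,
) -> RiskLocus:
    """Build the risk locus of a sentinel SNP.

    Proxies are all candidate SNPs with r^2 >= ``r2_threshold`` to the
    sentinel (boundary inclusive); the locus interval spans the minimum
    to maximum proxy position, half-open at max + 1. Precomputed r^2
    values may be supplied as ``r2_table`` (a Series indexed by SNP id),
    the accepted input dialect for externally computed LD.
    """
    if candidates is None:
        candidates = pd.DataFrame(
            {"pos": data.positions}, index=pd.Index(data.snp_ids, name="snp")
        )
    if sentinel not in candidates.index:
        raise ValueError(f"sentinel {sentinel!r} missing from candidate set")
    if r2_table is not None:
        r2 = candidates.index.map(r2_table).to_numpy(dtype=float)
        r2 = np.where(np.isnan(r2), 0.0, r2)
        r2 = np.where(candidates.index == sentinel, 1.0, r2)
    else:
        full = pd.Series(r2_with_sentinel(data, sentinel), index=data.snp_ids)
        r2 = candidates.index.map(full).to_numpy(dtype=float)
    keep = r2 >= r2_threshold
    proxies = candidates.loc[keep, ["pos"]].copy()
    proxies["r2"] = r2[keep]
    pos = proxies["pos"].to_numpy()
    sentinel_pos = int(candidates.loc[sentinel, "pos"])
    return RiskLocus(
        sentinel=sentinel,
        sentinel_pos=sentinel_pos,
        contig=data.contig,
        proxies=proxies,
        start=int(pos.min()),
        end=int(pos.max()) + 1,
    )


def _per_snp_regions(panel: HaplotypePanel, r2_threshold: float) -> np.ndarray:
    """LD-region interval of every polymorphic panel SNP, blockwise."""
    h = panel.haplotypes.astype(float)
    regions = []
    for block in np.unique(panel.block_ids):
        idx = np.flatnonzero(panel.block_ids == block)
        sub = h[:, idx]
        p = sub.mean(axis=0)
        poly = (p > 0) & (p < 1)
        if not poly.any():
            continue
        sub = sub[:, poly]
        pos = panel.positions[idx][poly]
        r = np.corrcoef(sub, rowvar=False)
        r2 = np.atleast_2d(r) ** 2
        # cross-block LD is zero by construction of the block panel
        for i in range(r2.shape[0]):
            mates = pos[r2[i] >= r2_threshold]
            regions.append((int(mates.min()), int(mates.max()) + 1))
    return np.asarray(regions, dtype=np.int64).reshape(-1, 2)


def build_background_regions(
    panel: HaplotypePanel,
    exclusion_loci: list[RiskLocus],
    r2_threshold: float = R2_THRESHOLD,
) -> BackgroundRegions:
    """Merged union of per-SNP LD regions minus risk-locus regions.

    Every merged interval that overlaps any exclusion locus is dropped
    in full (region-level exclusion, a conservative background).
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    merged = merge_intervals(_per_snp_regions(panel, r2_threshold))
    excl = np.asarray(
        [(loc.start, loc.end) for loc in exclusion_loci], dtype=np.int64
    ).reshape(-1, 2)
    keep = ~overlaps(merged, excl)
    return BackgroundRegions(intervals=merged[keep], excluded=excl)
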