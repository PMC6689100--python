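"""Allelic imbalance of chromatin accessibility at risk-locus SNPs.

Reference/alternative read counts are pooled across heterozygous
samples (per-sample reference ratio within 0.1-0.9, a genotyping-error
guard), a beta-binomial null is fitted on background SNPs outside LD
with the sentinels, each testable risk-locus SNP is tested two-sidedly
against that null, and discoveries are controlled at FDR < 0.1.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import AlleleCountTable, GenotypeMatrix
from .intervals import contains_points
from .stats import (
    BetaBinomNull,
    TestResult,
    adjust_pvalues,
    betabinom_test,
    fisher_exact_2x2,
    fit_betabinom,
)

__all__ = [
    "RATIO_WINDOW",
    "pool_het_counts",
    "pooled_counts_per_snp",
    "select_test_snps",
    "build_null",
    "test_imbalance",
    "qtl_overlap_enrichment",
]

RATIO_WINDOW = (0.1, 0.9)
MIN_HET = 3
MIN_READS = 10
FDR_Q = 0.1


def _annotated_counts(
    table: AlleleCountTable, genotypes: GenotypeMatrix
) -> pd.DataFrame:
    """Counts joined with the per-call genotype and the ratio filter."""
    df = table.counts.copy()
    geno = genotypes.to_frame().stack()
    geno.index.names = ["sample", "snp"]
    df["genotype"] = geno.reindex(
        pd.MultiIndex.from_frame(df[["sample", "snp"]])
    ).to_numpy()
    df["total"] = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore"):
        df["ratio"] = np.where(df["total"] > 0, df["ref_count"] / df["total"], np.nan)
    df["het"] = df["genotype"] == 1
    df["usable"] = (
        df["het"]
        & (df["total"] > 0)
        & (df["ratio"] >= RATIO_WINDOW[0])
        & (df["ratio"] <= RATIO_WINDOW[1])
    )
    return df


def pooled_counts_per_snp(
    table: AlleleCountTable, genotypes: GenotypeMatrix
) -> pd.DataFrame:
    """Per-SNP pooled (ref, total) over ratio-passing heterozygotes.

    ``n_het`` counts heterozygous samples with any reads at the SNP
    (before the ratio filter); pooled counts apply the filter.
    """
    df = _annotated_counts(table, genotypes)
    het_counts = (
        df[df["het"] & (df["total"] > 0)].groupby("snp").size().rename("n_het")
    )
    used = df[df["usable"]]
    pooled = used.groupby("snp").agg(
        pooled_ref=("ref_count", "sum"), pooled_total=("total", "sum")
    )
    out = pooled.join(het_counts, how="outer").fillna(0)
    return out.astype({"pooled_ref": int, "pooled_total": int, "n_het": int})


def pool_het_counts(
    table: AlleleCountTable, genotypes: GenotypeMatrix, snp: str
) -> tuple[int, int]:
    """Pooled (reference, total) read counts for one SNP."""
    pooled = pooled_counts_per_snp(table, genotypes)
    if snp not in pooled.index:
        return 0, 0
    row = pooled.loc[snp]
    return int(row["pooled_ref"]), int(row["pooled_total"])


def select_test_snps(
    table: AlleleCountTable,
    genotypes: GenotypeMatrix,
    min_het: int = MIN_HET,
    min_reads: int = MIN_READS,
) -> list[str]:
    """Risk-locus SNPs testable for allelic imbalance.

    Keeps LD-proxy SNPs inside accessibility peaks with at least
    ``min_het`` heterozygous samples and a ratio-filtered pooled read
    total of at least ``min_reads``.
    """
    pooled = pooled_counts_per_snp(table, genotypes)
    candidates = table.snps.index[table.snps["ld_proxy"] & table.snps["in_peak"]]
    keep = []
    for snp in candidates:
        if snp not in pooled.index:
            continue
        row = pooled.loc[snp]
        if row["n_het"] >= min_het and row["pooled_total"] >= min_reads:
            keep.append(snp)
    return keep


def build_null(
    table: AlleleCountTable,
    genotypes: GenotypeMatrix,
    exclusion_regions: np.ndarray | None = None,
) -> BetaBinomNull:
    """Beta-binomial null from pooled background-SNP heterozygote counts.

    Background SNPs inside any exclusion interval (e.g. HLA-like,
    immunoglobulin-like, or imprinted regions) are removed before the
    maximum-likelihood fit.
    """
    bg = table.snps[table.snps["background"]]
    if exclusion_regions is not None and len(exclusion_regions):
        inside = contains_points(exclusion_regions, bg["pos"].to_numpy())
        bg = bg[~inside]
    pooled = pooled_counts_per_snp(table, genotypes)
    pooled = pooled[pooled.index.isin(bg.index) & (pooled["pooled_total"] > 0)]
    if len(pooled) < 10:
        raise ValueError(f"only {len(pooled)} background SNPs after filters; need >= 10")
    pairs = list(zip(pooled["pooled_ref"], pooled["pooled_total"]))
    return fit_betabinom(pairs)


def test_imbalance(
    table: AlleleCountTable,
    genotypes: GenotypeMatrix,
    snp_ids: list[str],
    null: BetaBinomNull,
    fdr_q: float = FDR_Q,
) -> pd.DataFrame:
    """Per-SNP beta-binomial imbalance test with BH control.

    The reported central tendency is the pooled reference-allele ratio;
    its 95% CI uses the normal approximation with the pooled read total
    as the sample size, clipped to [0, 1].
    """
    pooled = pooled_counts_per_snp(table, genotypes)
    rows = []
    for snp in snp_ids:
        r = pooled.loc[snp]
        k, n = int(r["pooled_ref"]), int(r["pooled_total"])
        res = betabinom_test(k, n, null)
        ratio = k / n
        half = 1.96 * np.sqrt(ratio * (1 - ratio) / n)
        rows.append(
            {
                "snp": snp,
                "pooled_ref": k,
                "pooled_total": n,
                "ratio": ratio,
                "p_value": res.p_value,
                "ci_low": max(0.0, ratio - half),
                "ci_high": min(1.0, ratio + half),
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        out["fdr"] = []
        out["significant"] = []
        return out
    out["fdr"] = adjust_pvalues(out["p_value"].to_numpy(), "bh")
    out["significant"] = out["fdr"] < fdr_q
    return out


def qtl_overlap_enrichment(ai: pd.DataFrame, qtl_snps: set[str]) -> TestResult:
    """Fisher exact test of AI-significant SNPs overlapping QTL SNPs."""
    if ai.empty:
        raise ValueError("empty allelic-imbalance table")
    sig = ai["significant"].to_numpy(dtype=bool)
    overlap = ai["snp"].isin(qtl_snps).to_numpy()
    a = int((sig & overlap).sum())
    b = int((sig & ~overlap).sum())
    c = int((~sig & overlap).sum())
    d = int((~sig & ~overlap).sum())
    return fisher_exact_2x2([[a, b], [c, d]])
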