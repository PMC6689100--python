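"""Molecular QTL scanning across data layers.

Per layer the pipeline is: feature eligibility by genotype subgroup,
principal-component residualization of latent confounders, rank-based
inverse-normal transform, and a simple linear regression of the
transformed feature on the 0/1/2 risk-allele dosage, with
Benjamini-Hochberg control at FDR < 0.05 across all tests in the layer.
Candidate genes for the expression layer are restricted to the
topologically associating domains (TADs) spanning the LD region.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import stdtr

from .containers import MISSING, FeatureMatrix, GenotypeMatrix, RiskLocus
from .stats import adjust_pvalues, inverse_normal_transform

__all__ = [
    "TADMap",
    "QTLResult",
    "DEFAULT_FACTORS",
    "feature_eligibility",
    "residualize",
    "qtl_test",
    "run_layer_scan",
    "tad_candidate_genes",
    "direction_concordance",
]

#: latent-factor counts per layer (accessibility, H3K27ac, methylation,
#: expression), mirroring the confounder dimensions used for each assay
DEFAULT_FACTORS = {
    "accessibility": 10,
    "h3k27ac": 10,
    "methylation": 45,
    "expression": 65,
}

EXPRESSION_FLOOR = 4.5


@dataclass
class TADMap:
    """TAD intervals plus gene annotations on the same contig."""

    tads: pd.DataFrame  # index tad_id: start, end
    genes: pd.DataFrame  # index gene_id: start, end

    def tads_overlapping(self, start: int, end: int) -> pd.DataFrame:
        t = self.tads
        return t[(t["start"] < end) & (start < t["end"])]


@dataclass
class QTLResult:
    sentinel: str
    feature: str
    layer: str
    beta: float
    t_statistic: float
    p_value: float
    n_used: int
    fdr: float | None = None


def feature_eligibility(
    matrix: FeatureMatrix,
    genotypes: GenotypeMatrix,
    sentinel: str,
    min_fraction: float = 0.10,
    min_count: int = 2,
    expression_floor: float = EXPRESSION_FLOOR,
) -> list[str]:
    """Features testable against one sentinel SNP.

    Peaks must be present -- and expression probes expressed (level
    strictly above the floor) -- in at least max(min_count,
    ceil(min_fraction * subgroup size)) patients of at least one
    genotype subgroup (homozygous non-risk / heterozygous / homozygous
    risk). Methylation probes are measured on every array and are all
    eligible.
    """
    dosage = genotypes.dosage_of(sentinel)
    if matrix.layer == "methylation":
        return list(matrix.feature_ids)
    if matrix.layer == "expression":
        present = matrix.values > expression_floor
    else:
        present = matrix.presence
    sample_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    rows = [sample_pos[s] for s in matrix.sample_ids]
    dos = dosage[rows]
    eligible = np.zeros(len(matrix.feature_ids), dtype=bool)
    for g in (0, 1, 2):
        grp = dos == g
        size = int(grp.sum())
        if size == 0:
            continue
        need = max(min_count, math.ceil(min_fraction * size))
        eligible |= present[grp].sum(axis=0) >= need
    return [f for f, e in zip(matrix.feature_ids, eligible) if e]


def residualize(values: np.ndarray, k_factors: int) -> np.ndarray:
    """Remove the top-k principal components from a samples x features matrix.

    Components are estimated on the column-standardized matrix;
    residuals (of the column-centered data) are orthogonal to the
    removed components. ``k_factors = 0`` returns the input unchanged.
    """
    x = np.asarray(values, dtype=float)
    if k_factors == 0:
        return x.copy()
    rank = min(x.shape)
    if k_factors >= rank or k_factors < 0:
        raise ValueError(f"k_factors {k_factors} must be in [0, rank {rank})")
    centered = x - x.mean(axis=0)
    sd = centered.std(axis=0)
    std = centered / np.where(sd > 0, sd, 1.0)
    u, s, _ = np.linalg.svd(std, full_matrices=False)
    uk = u[:, :k_factors]
    return centered - uk @ (uk.T @ centered)


def qtl_test(values: np.ndarray, dosages: np.ndarray) -> tuple[float, float, float, int]:
    """Simple linear regression of a (transformed) feature on dosage.

    Missing dosages (MISSING) and non-finite values are dropped
    pairwise. Returns (beta, t, two-sided p with n-2 df, n used).
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(dosages, dtype=float)
    keep = (d != MISSING) & np.isfinite(v)
    v, d = v[keep], d[keep]
    n = v.size
    if n < 3:
        raise ValueError("need at least 3 complete observations")
    if np.all(d == d[0]):
        raise ValueError("zero dosage variance among analyzed samples")
    dx = d - d.mean()
    vy = v - v.mean()
    sxx = float(dx @ dx)
    beta = float(dx @ vy) / sxx
    resid = vy - beta * dx
    dof = n - 2
    s2 = float(resid @ resid) / dof
    if s2 <= 0:
        return beta, math.inf if beta != 0 else 0.0, 0.0 if beta != 0 else 1.0, n
    se = math.sqrt(s2 / sxx)
    t = beta / se
    p = 2.0 * float(stdtr(dof, -abs(t)))
    return beta, t, p, n


def _test_window(locus: RiskLocus, tad_map: TADMap | None) -> tuple[int, int]:
    if tad_map is None:
        return locus.start, locus.end
    tads = tad_map.tads_overlapping(locus.start, locus.end)
    if tads.empty:
        return locus.start, locus.end
    return int(min(tads["start"].min(), locus.start)), int(max(tads["end"].max(), locus.end))


def run_layer_scan(
    matrix: FeatureMatrix,
    loci: list[RiskLocus],
    genotypes: GenotypeMatrix,
    tad_map: TADMap | None = None,
    fdr_q: float = 0.05,
    k_factors: int | None = None,
) -> pd.DataFrame:
    """Scan every (sentinel, eligible in-window feature) pair in one layer.

    The per-locus test window is the union of TADs spanning the LD
    region (the LD region itself when no TAD map is supplied). BH
    adjustment is applied across all tests within the layer.
    """
    if k_factors is None:
        k_factors = DEFAULT_FACTORS.get(matrix.layer, 0)
    k_factors = min(k_factors, min(matrix.values.shape) - 1)
    resid = residualize(matrix.values, k_factors)
    transformed = np.full_like(resid, np.nan)
    for j in range(resid.shape[1]):
        try:
            transformed[:, j] = inverse_normal_transform(resid[:, j])
        except ValueError:
            pass  # constant feature: left NaN, dropped by qtl_test
    sample_pos = {s: i for i, s in enumerate(genotypes.sample_ids)}
    rows = [sample_pos[s] for s in matrix.sample_ids]
    records = []
    for locus in loci:
        if locus.sentinel not in genotypes.snp_ids:
            continue
        dosage = genotypes.dosage_of(locus.sentinel)[rows]
        w0, w1 = _test_window(locus, tad_map)
        in_window = (matrix.starts < w1) & (w0 < matrix.ends)
        eligible = set(feature_eligibility(matrix, genotypes, locus.sentinel))
        for j in np.flatnonzero(in_window):
            fid = matrix.feature_ids[j]
            if fid not in eligible:
                continue
            try:
                beta, t, p, n = qtl_test(transformed[:, j], dosage)
            except ValueError:
                continue
            records.append(
                {
                    "sentinel": locus.sentinel,
                    "feature": fid,
                    "layer": matrix.layer,
                    "beta": beta,
                    "t": t,
                    "p": p,
                    "n_used": n,
                }
            )
    if not records:
        warnings.warn(f"no testable (sentinel, feature) pairs in layer {matrix.layer}")
        return pd.DataFrame(
            columns=["sentinel", "feature", "layer", "beta", "t", "p", "n_used", "fdr", "significant"]
        )
    out = pd.DataFrame(records)
    out["fdr"] = adjust_pvalues(out["p"].to_numpy(), "bh")
    out["significant"] = out["fdr"] < fdr_q
    return out


def tad_candidate_genes(locus: RiskLocus, tad_map: TADMap) -> set[str]:
    """Genes in every TAD intersecting the LD region (half-open overlap)."""
    tads = tad_map.tads_overlapping(locus.start, locus.end)
    if tads.empty:
        warnings.warn(f"no TAD overlaps locus {locus.sentinel}")
        return set()
    genes: set[str] = set()
    g = tad_map.genes
    for _, tad in tads.iterrows():
        hit = g[(g["start"] < tad["end"]) & (tad["start"] < g["end"])]
        genes.update(hit.index)
    return genes


def direction_concordance(
    results_by_layer: dict[str, pd.DataFrame],
    matrices: dict[str, FeatureMatrix],
) -> pd.DataFrame:
    """Sign agreement of overlapping significant QTLs across layers.

    Accessibility and H3K27ac effects are concordant when their slopes
    share a sign; methylation against either activity layer is
    concordant when the signs are opposite (more methylation with less
    activity). Pairs are matched on the sentinel with intersecting
    feature intervals.
    """
    act_pairs = [("accessibility", "h3k27ac", True)]
    meth_pairs = [("methylation", "accessibility", False), ("methylation", "h3k27ac", False)]
    rows = []
    for la, lb, same_sign in act_pairs + meth_pairs:
        ra = results_by_layer.get(la)
        rb = results_by_layer.get(lb)
        if ra is None or rb is None or ra.empty or rb.empty:
            continue
        sa = ra[ra["significant"]]
        sb = rb[rb["significant"]]
        ma, mb = matrices[la], matrices[lb]
        for _, qa in sa.iterrows():
            ja = ma.feature_index(qa["feature"])
            for _, qb in sb[sb["sentinel"] == qa["sentinel"]].iterrows():
                jb = mb.feature_index(qb["feature"])
                if ma.starts[ja] < mb.ends[jb] and mb.starts[jb] < ma.ends[ja]:
                    agree = np.sign(qa["beta"]) == np.sign(qb["beta"])
                    rows.append(
                        {
                            "layer_a": la,
                            "layer_b": lb,
                            "sentinel": qa["sentinel"],
                            "feature_a": qa["feature"],
                            "feature_b": qb["feature"],
                            "concordant": bool(agree == same_sign),
                        }
                    )
    return pd.DataFrame(rows, columns=["layer_a", "layer_b", "sentinel", "feature_a", "feature_b", "concordant"])
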