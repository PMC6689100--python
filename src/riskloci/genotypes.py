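"""Genotype assignment: probability calling, QC, and imputed/WGS merging.

The reconciliation ledger follows a fixed rule order: drop poorly
imputed SNPs (information measure < 0.85), call genotypes from
imputation probability triples (uncertainty > 0.1 precludes a call),
mask calls inside per-sample copy-number-altered intervals, validate
WGS calls (depth >= 10, mapping/base quality pass, normal == tumor),
exclude samples with < 90% imputed-vs-WGS concordance, switch SNPs with
< 90% concordance to WGS-only, resolve remaining conflicts in favor of
WGS, and fill missing imputed calls from WGS.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix
from .intervals import contains_points
from .stats import hwe_exact_test

__all__ = [
    "ImputedCalls",
    "WGSCalls",
    "ReconciliationReport",
    "call_from_probabilities",
    "call_matrix_from_probabilities",
    "snp_qc",
    "sample_qc",
    "reconcile",
]

INFO_MIN = 0.85
UNCERTAINTY_MAX = 0.1
CONCORDANCE_MIN = 0.9
MIN_DEPTH = 10


@dataclass
class ImputedCalls:
    """Imputation probability triples with per-SNP info measures."""

    sample_ids: list[str]
    snp_ids: list[str]
    positions: np.ndarray
    contig: str
    info: np.ndarray  # per SNP, in [0, 1]
    probs: np.ndarray  # (n_samples, n_snps, 3), rows sum to 1

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.info = np.asarray(self.info, dtype=float)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.probs.shape != (len(self.sample_ids), len(self.snp_ids), 3):
            raise ValueError("probability array shape mismatch")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("probability triples must sum to 1")


@dataclass
class WGSCalls:
    """Per sample x SNP whole-genome-sequencing calls with quality flags."""

    sample_ids: list[str]
    snp_ids: list[str]
    normal: np.ndarray  # int8, MISSING allowed
    tumor: np.ndarray
    depth: np.ndarray  # int read depth
    mq_pass: np.ndarray  # bool, mapping quality >= 30
    bq_pass: np.ndarray  # bool, base quality >= 30

    def __post_init__(self) -> None:
        shape = (len(self.sample_ids), len(self.snp_ids))
        for name in ("normal", "tumor", "depth", "mq_pass", "bq_pass"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shape:
                raise ValueError(f"{name} shape mismatch")
            setattr(self, name, arr)
        for g in (self.normal, self.tumor):
            if not np.isin(g, (MISSING, 0, 1, 2)).all():
                raise ValueError("genotypes must be in {0, 1, 2, -1}")

    def valid_calls(self) -> np.ndarray:
        """WGS genotype matrix after depth/quality and normal==tumor rules."""
        ok = (
            (self.depth >= MIN_DEPTH)
            & self.mq_pass.astype(bool)
            & self.bq_pass.astype(bool)
            & (self.normal != MISSING)
            & (self.normal == self.tumor)
        )
        return np.where(ok, self.normal, MISSING).astype(np.int8)


@dataclass
class ReconciliationReport:
    excluded_samples: dict[str, str]
    wgs_only_snps: list[str]
    low_info_snps: list[str]
    provenance_counts: dict[str, int]
    concordance_per_sample: pd.Series
    concordance_per_snp: pd.Series
    n_conflicts: int


def call_from_probabilities(
    triple: Sequence[float], uncertainty_threshold: float = UNCERTAINTY_MAX
) -> int:
    """Genotype from one probability triple; MISSING if too uncertain.

    Uncertainty is 1 - max(triple); a call is made iff it does not
    exceed the threshold (exactly 0.1 still calls).
    """
    t = np.asarray(triple, dtype=float)
    if t.shape != (3,) or not np.isclose(t.sum(), 1.0, atol=1e-6) or np.any(t < 0):
        raise ValueError(f"malformed probability triple {triple!r}")
    if 1.0 - t.max() > uncertainty_threshold + 1e-12:
        return MISSING
    return int(t.argmax())


def call_matrix_from_probabilities(
    probs: np.ndarray, uncertainty_threshold: float = UNCERTAINTY_MAX
) -> np.ndarray:
    p = np.asarray(probs, dtype=float)
    calls = p.argmax(axis=-1).astype(np.int8)
    uncertain = 1.0 - p.max(axis=-1) > uncertainty_threshold + 1e-12
    calls[uncertain] = MISSING
    return calls


def snp_qc(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP QC: call rate >= 95%, MAF >= 1%, HWE exact p >= 1e-6.

    Reasons accumulate; a SNP may fail several rules at once.
    """
    rows = []
    d = matrix.dosages
    for j, snp in enumerate(matrix.snp_ids):
        col = d[:, j]
        called = col[col != MISSING]
        call_rate = called.size / col.size
        reasons = []
        if call_rate < 0.95:
            reasons.append("call_rate")
        if called.size:
            af = called.mean() / 2.0
            maf = min(af, 1 - af)
            n_aa = int((called == 0).sum())
            n_ab = int((called == 1).sum())
            n_bb = int((called == 2).sum())
            hwe_p = hwe_exact_test(n_aa, n_ab, n_bb).p_value
        else:
            maf, hwe_p = 0.0, 1.0
        if maf < 0.01:
            reasons.append("maf")
        if hwe_p < 1e-6:
            reasons.append("hwe")
        rows.append(
            {
                "snp": snp,
                "call_rate": call_rate,
                "maf": maf,
                "hwe_p": hwe_p,
                "passed": not reasons,
                "reasons": ",".join(reasons),
            }
        )
    return pd.DataFrame(rows).set_index("snp")


def sample_qc(
    matrix: GenotypeMatrix,
    het_sd: float = 3.0,
    identity_threshold: float = 0.9,
) -> dict[str, str]:
    """Sample exclusions for excessive heterozygosity or relatedness.

    Heterozygosity outliers lie more than ``het_sd`` standard deviations
    from the cohort mean heterozygote rate; related pairs share > 90%
    identical calls over jointly non-missing SNPs, dropping the member
    with the lower call rate.
    """
    if len(matrix.sample_ids) < 3:
        raise ValueError("need at least 3 samples for cohort QC")
    d = matrix.dosages
    called = d != MISSING
    with np.errstate(invalid="ignore"):
        het = np.where(called.sum(1) > 0, (d == 1).sum(1) / called.sum(1), 0.0)
    excluded: dict[str, str] = {}
    mu, sd = het.mean(), het.std()
    if sd > 0:
        for i in np.flatnonzero(np.abs(het - mu) > het_sd * sd):
            excluded[matrix.sample_ids[i]] = "excessive_heterozygosity"
    call_rates = called.mean(axis=1)
    n = d.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            if not shared.any():
                continue
            identity = (d[i, shared] == d[j, shared]).mean()
            if identity > identity_threshold:
                drop = i if call_rates[i] <= call_rates[j] else j
                sid = matrix.sample_ids[drop]
                if sid not in excluded:
                    excluded[sid] = "relatedness"
    return excluded


def _concordance(a: np.ndarray, b: np.ndarray, axis: int) -> np.ndarray:
    """Fraction of equal calls over positions non-missing in both."""
    both = (a != MISSING) & (b != MISSING)
    agree = (a == b) & both
    denom = both.sum(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        conc = np.where(denom > 0, agree.sum(axis=axis) / np.maximum(denom, 1), np.nan)
    return conc


def reconcile(
    imputed: ImputedCalls,
    wgs: WGSCalls,
    cna_mask: Mapping[str, np.ndarray] | None = None,
    sentinel_snps: Sequence[str] | None = None,
) -> tuple[GenotypeMatrix, ReconciliationReport]:
    """Merge imputed and WGS calls under the concordance ledger.

    ``cna_mask`` maps sample id to an (k, 2) array of intervals with a
    copy-number alteration in that sample; no genotype is assigned there.
    The per-sample concordance check (exclusion below 90%) is evaluated
    over ``sentinel_snps`` when given -- the fidelity-check subset --
    and over all shared SNPs otherwise; the per-SNP rule always uses the
    full sample set that survives exclusion. Samples and SNPs are
    aligned on the shared universe; an empty intersection is an error.
    """
    samples = [s for s in imputed.sample_ids if s in set(wgs.sample_ids)]
    snps = [s for s in imputed.snp_ids if s in set(wgs.snp_ids)]
    if not samples or not snps:
        raise ValueError("empty intersection of sample/SNP universes")
    si = [imputed.sample_ids.index(s) for s in samples]
    ki = [imputed.snp_ids.index(s) for s in snps]
    sw = [wgs.sample_ids.index(s) for s in samples]
    kw = [wgs.snp_ids.index(s) for s in snps]

    info = imputed.info[ki]
    positions = imputed.positions[ki]
    low_info = info < INFO_MIN

    # (1)+(2) probability calling; low-info SNP columns never yield imputed calls
    imp = call_matrix_from_probabilities(imputed.probs[np.ix_(si, ki)])
    imp[:, low_info] = MISSING

    # (4) WGS validity
    wgs_geno = wgs.valid_calls()[np.ix_(sw, kw)]

    # (3) CNA masking applies to both sources
    masked = np.zeros(imp.shape, dtype=bool)
    if cna_mask:
        for idx, sid in enumerate(samples):
            iv = np.asarray(cna_mask.get(sid, np.empty((0, 2))), dtype=np.int64)
            if iv.size:
                masked[idx] = contains_points(iv, positions)
    imp[masked] = MISSING
    wgs_geno[masked] = MISSING

    # (5) per-sample concordance, over the fidelity-check SNP subset
    if sentinel_snps is not None:
        cols = np.array([s in set(sentinel_snps) for s in snps])
        if not cols.any():
            raise ValueError("no sentinel SNPs in the shared universe")
    else:
        cols = np.ones(len(snps), dtype=bool)
    conc_sample = pd.Series(
        _concordance(imp[:, cols], wgs_geno[:, cols], axis=1), index=samples
    )
    excluded = {
        s: "imputed_wgs_discordance"
        for s, c in conc_sample.items()
        if np.isfinite(c) and c < CONCORDANCE_MIN
    }
    keep = np.array([s not in excluded for s in samples])

    # (6) per-SNP concordance over retained samples
    conc_snp = pd.Series(_concordance(imp[keep], wgs_geno[keep], axis=0), index=snps)
    wgs_only = conc_snp.index[(conc_snp < CONCORDANCE_MIN).fillna(False)].tolist()
    wgs_only_mask = np.array([s in set(wgs_only) for s in snps])

    merged = imp.copy()
    prov = np.full(imp.shape, "imputed", dtype=object)
    prov[imp == MISSING] = "missing"

    merged[:, wgs_only_mask] = wgs_geno[:, wgs_only_mask]
    prov[:, wgs_only_mask] = np.where(
        wgs_geno[:, wgs_only_mask] != MISSING, "wgs_only", "missing"
    )

    regular = ~wgs_only_mask
    imp_r, wgs_r = imp[:, regular], wgs_geno[:, regular]
    conflict = (imp_r != MISSING) & (wgs_r != MISSING) & (imp_r != wgs_r)
    fill = (imp_r == MISSING) & (wgs_r != MISSING)
    conflict &= keep[:, None]  # excluded samples end fully missing anyway
    fill &= keep[:, None]
    sub_m = merged[:, regular]
    sub_p = prov[:, regular]
    sub_m[conflict | fill] = wgs_r[conflict | fill]  # (7)+(8) WGS wins / fills
    sub_p[conflict] = "wgs_conflict"
    sub_p[fill] = "wgs_fill"
    merged[:, regular] = sub_m
    prov[:, regular] = sub_p

    prov[masked] = "masked"
    merged[masked] = MISSING
    for idx, s in enumerate(samples):
        if s in excluded:
            merged[idx] = MISSING
            prov[idx] = "excluded"

    counts = {
        code: int((prov == code).sum())
        for code in ("imputed", "wgs_conflict", "wgs_fill", "wgs_only", "masked", "excluded", "missing")
    }
    matrix = GenotypeMatrix(
        sample_ids=samples,
        snp_ids=snps,
        positions=positions,
        contig=imputed.contig,
        dosages=merged,
        provenance=prov,
        excluded_samples=dict(excluded),
    )
    report = ReconciliationReport(
        excluded_samples=dict(excluded),
        wgs_only_snps=wgs_only,
        low_info_snps=[s for s, li in zip(snps, low_info) if li],
        provenance_counts=counts,
        concordance_per_sample=conc_sample,
        concordance_per_snp=conc_snp,
        n_conflicts=int(conflict.sum()),
    )
    return matrix, report
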