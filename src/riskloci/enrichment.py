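"""Chromatin-state annotation and enrichment of risk loci.

The enrichment of chromatin state j at locus i in one sample is

    E_ij = log2( C_ji / C_jB )

where C_ji is the fraction of the locus interval covered by state j and
C_jB the fraction of the background regions covered by j. A zero locus
fraction propagates as NaN, and a zero background fraction with a
positive locus fraction as +inf; neither is replaced by a pseudocount.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import (
    ACTIVE_STATES,
    TXN_STATES,
    WEAK_STATES,
    BackgroundRegions,
    RiskLocus,
    SegmentationTrack,
)
from .stats import TestResult, adjust_pvalues, fisher_exact_2x2, wilcoxon_rank_sum

__all__ = [
    "StateCoverage",
    "EnrichmentProfile",
    "state_coverage",
    "background_coverage",
    "enrichment_score",
    "snp_state_annotation",
    "fraction_active_per_sample",
    "classify_locus_groups",
    "permutation_expected",
    "compare_active_fractions",
]


@dataclass
class StateCoverage:
    region: tuple[int, int]
    sample: str
    fractions: np.ndarray  # per state, sums to 1
    alphabet: tuple[str, ...]

    def fraction_of(self, state: str) -> float:
        return float(self.fractions[self.alphabet.index(state)])


@dataclass
class EnrichmentProfile:
    locus: RiskLocus | None
    sample: str
    E: np.ndarray  # per-state log2 enrichment; NaN / +inf sentinels
    background_fractions: np.ndarray
    alphabet: tuple[str, ...]

    def e_of(self, state: str) -> float:
        return float(self.E[self.alphabet.index(state)])


def _covered_bases(region: tuple[int, int], track: SegmentationTrack) -> np.ndarray:
    start, end = int(region[0]), int(region[1])
    if start < 0 or end > track.extent or end <= start:
        raise ValueError(f"region {region} outside track extent [0, {track.extent})")
    bs = track.bin_size
    b0, b1 = start // bs, (end - 1) // bs
    bins = np.arange(b0, b1 + 1)
    lo = np.maximum(start, bins * bs)
    hi = np.minimum(end, (bins + 1) * bs)
    weights = (hi - lo).astype(float)
    return np.bincount(
        track.states[b0 : b1 + 1], weights=weights, minlength=len(track.alphabet)
    )


def state_coverage(region: tuple[int, int], track: SegmentationTrack) -> StateCoverage:
    """Fraction of a region covered by each chromatin state (sums to 1)."""
    bases = _covered_bases(region, track)
    return StateCoverage(
        region=(int(region[0]), int(region[1])),
        sample=track.sample,
        fractions=bases / bases.sum(),
        alphabet=track.alphabet,
    )


def background_coverage(
    background: BackgroundRegions, track: SegmentationTrack
) -> StateCoverage:
    """Aggregate state fractions over the merged background intervals."""
    if background.intervals.shape[0] == 0:
        raise ValueError("empty background")
    bases = np.zeros(len(track.alphabet))
    for s, e in background.intervals:
        bases += _covered_bases((int(s), int(e)), track)
    span = (int(background.intervals[0, 0]), int(background.intervals[-1, 1]))
    return StateCoverage(
        region=span, sample=track.sample, fractions=bases / bases.sum(), alphabet=track.alphabet
    )


def enrichment_score(
    locus_cov: StateCoverage, background_cov: StateCoverage, locus: RiskLocus | None = None
) -> EnrichmentProfile:
    """Per-state log2 enrichment of a locus over the background."""
    if locus_cov.alphabet != background_cov.alphabet:
        raise ValueError("state alphabets differ between locus and background")
    ci = locus_cov.fractions
    cb = background_cov.fractions
    e = np.full(ci.shape, np.nan)
    both = (ci > 0) & (cb > 0)
    e[both] = np.log2(ci[both] / cb[both])
    e[(ci > 0) & (cb == 0)] = np.inf
    return EnrichmentProfile(
        locus=locus,
        sample=locus_cov.sample,
        E=e,
        background_fractions=cb,
        alphabet=locus_cov.alphabet,
    )


def snp_state_annotation(
    loci: Sequence[RiskLocus], tracks: Sequence[SegmentationTrack]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chromatin state at every proxy SNP in every sample.

    Returns (per-SNP table, per-locus summary). A locus is flagged
    active when at least one proxy SNP lies in an active promoter or
    strong enhancer state in at least one sample; the summary also
    carries the sentinel-only equivalent.
    """
    rows = []
    for locus in loci:
        for snp, row in locus.proxies.iterrows():
            pos = int(row["pos"])
            for track in tracks:
                rows.append(
                    {
                        "locus": locus.sentinel,
                        "snp": snp,
                        "pos": pos,
                        "sample": track.sample,
                        "state": track.state_at(pos),
                        "is_sentinel": snp == locus.sentinel,
                    }
                )
    table = pd.DataFrame(rows)
    table["active"] = table["state"].isin(ACTIVE_STATES)
    summary = (
        table.groupby("locus")
        .agg(
            active=("active", "any"),
            n_active_snps=("active", "sum"),
        )
        .join(
            table[table["is_sentinel"]].groupby("locus")["active"].any().rename("sentinel_active")
        )
    )
    return table, summary


def fraction_active_per_sample(
    loci: Sequence[RiskLocus],
    track: SegmentationTrack,
    background_cov: StateCoverage,
) -> float:
    """Fraction of loci enriched (E > 0) for >=1 active state in this sample."""
    n_active = 0
    for locus in loci:
        prof = enrichment_score(
            state_coverage((locus.start, locus.end), track), background_cov, locus
        )
        es = np.array([prof.e_of(s) for s in ACTIVE_STATES])
        if np.any(es[~np.isnan(es)] > 0):
            n_active += 1
    return n_active / len(loci)


_FAMILIES = {"active": ACTIVE_STATES, "weak": WEAK_STATES, "txn": TXN_STATES}


def classify_locus_groups(profiles: Sequence[EnrichmentProfile]) -> int:
    """Assign a locus to one of five enrichment groups.

    Median E across samples is taken per state (NaN excluded, +inf
    counts as positive). Groups: (1) active regulatory only, (2) active
    + transcribed, (3) weak regulatory only, (4) weak + transcribed,
    (5) neither (poised / inactive).
    """
    if not profiles:
        raise ValueError("no enrichment profiles supplied")
    alphabet = profiles[0].alphabet
    e = np.stack([p.E for p in profiles])  # samples x states
    capped = np.where(np.isposinf(e), np.finfo(float).max, e)
    med = np.full(e.shape[1], np.nan)
    has_data = ~np.all(np.isnan(capped), axis=0)
    med[has_data] = np.nanmedian(capped[:, has_data], axis=0)
    positive = {}
    for fam, states in _FAMILIES.items():
        idx = [alphabet.index(s) for s in states]
        vals = med[idx]
        positive[fam] = bool(np.any(vals[~np.isnan(vals)] > 0))
    if positive["active"]:
        return 2 if positive["txn"] else 1
    if positive["weak"]:
        return 4 if positive["txn"] else 3
    return 5


@dataclass
class PermutationResult:
    expected: float
    empirical_p: float
    observed: int
    fisher: TestResult
    per_permutation: np.ndarray


def permutation_expected(
    observed_count: int,
    counter: Callable[[np.ndarray], int],
    background: BackgroundRegions,
    template: Sequence[RiskLocus],
    total: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Expected count under random placement of length-matched regions.

    Each permutation samples len(template) intervals uniformly from the
    background, matched on the template length multiset, and applies the
    caller's counter. The empirical p uses the +1 correction; the Fisher
    comparison contrasts observed vs rounded-expected out of ``total``.
    """
    rng = np.random.default_rng(seed)
    lengths = np.array([loc.end - loc.start for loc in template], dtype=np.int64)
    bg = background.intervals
    bg_len = bg[:, 1] - bg[:, 0]
    if np.any(lengths.max(initial=0) > bg_len.max(initial=0)):
        raise ValueError("a template interval is longer than every background interval")
    counts = np.empty(n_perm)
    for p in range(n_perm):
        placed = np.empty((lengths.size, 2), dtype=np.int64)
        for i, L in enumerate(lengths):
            ok = np.flatnonzero(bg_len >= L)
            slots = bg_len[ok] - L + 1
            j = ok[rng.choice(slots.size, p=slots / slots.sum())]
            off = rng.integers(0, bg_len[j] - L + 1)
            placed[i] = (bg[j, 0] + off, bg[j, 0] + off + L)
        counts[p] = counter(placed)
    expected = float(counts.mean())
    emp_p = (1 + int((counts >= observed_count).sum())) / (n_perm + 1)
    exp_round = int(round(expected))
    fisher = fisher_exact_2x2(
        [[observed_count, total - observed_count], [exp_round, total - exp_round]]
    )
    return PermutationResult(
        expected=expected,
        empirical_p=emp_p,
        observed=observed_count,
        fisher=fisher,
        per_permutation=counts,
    )


def compare_active_fractions(
    fractions_by_trait: Mapping[str, Sequence[float]]
) -> pd.DataFrame:
    """All pairwise rank-sum comparisons of per-sample active fractions.

    Returns one row per trait pair with the Mann-Whitney W, raw and
    Bonferroni-corrected p (over the number of pairs), group medians and
    their difference.
    """
    traits = list(fractions_by_trait)
    if len(traits) < 2:
        raise ValueError("need at least 2 traits")
    for t in traits:
        if len(fractions_by_trait[t]) < 2:
            raise ValueError(f"trait {t!r} has fewer than 2 samples")
    rows = []
    for i, a in enumerate(traits):
        for b in traits[i + 1 :]:
            xa = np.asarray(fractions_by_trait[a], dtype=float)
            xb = np.asarray(fractions_by_trait[b], dtype=float)
            res = wilcoxon_rank_sum(xa, xb, mode="normal")
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "W": res.statistic,
                    "p_raw": res.p_value,
                    "median_a": float(np.median(xa)),
                    "median_b": float(np.median(xb)),
                    "median_diff": float(np.median(xa) - np.median(xb)),
                }
            )
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = adjust_pvalues(out["p_raw"].to_numpy(), "bonferroni")
    return out
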