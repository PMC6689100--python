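"""Transcription-factor motif disruption scoring at risk SNPs.

Sequences are scored against a position weight matrix with an
information-content-weighted log-likelihood ratio (a relative-entropy
weighting): each position contributes IC_p * log2(q_p(base)/bg(base)),
where q_p carries a 1e-3 pseudocount. Score p-values are tail
probabilities of the score of a background-random sequence, computed
exhaustively for short motifs and by discretized convolution otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

__all__ = [
    "PWM",
    "DisruptionCall",
    "score_sequence",
    "best_window_scores",
    "score_pvalue",
    "classify_disruption",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PSEUDOCOUNT = 1e-3
EXACT_MAX_LENGTH = 8
GRID_STEP = 1e-4


@dataclass
class PWM:
    """Position weight matrix with a background base distribution."""

    motif_id: str
    probs: np.ndarray  # (L, 4) row-stochastic
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4:
            raise ValueError("PWM must be (L, 4)")
        if np.any(self.probs < 0) or not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("PWM rows must be probability vectors")

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def score_matrix(self) -> np.ndarray:
        """(L, 4) per-position, per-base score contributions."""
        q = (self.probs + PSEUDOCOUNT) / (1.0 + 4 * PSEUDOCOUNT)
        with np.errstate(divide="ignore"):
            llr = np.log2(q / self.background)
        ic = (q * llr).sum(axis=1, keepdims=True)  # relative entropy per position
        return ic * llr

    @property
    def max_score(self) -> float:
        return float(self.score_matrix.max(axis=1).sum())

    def reverse_complement(self) -> "PWM":
        return PWM(
            motif_id=self.motif_id,
            probs=self.probs[::-1, ::-1].copy(),
            background=self.background[::-1].copy(),
        )


@dataclass
class DisruptionCall:
    snp: str
    motif_id: str
    score_ref: float  # normalized to [0, 1] by the maximal achievable score
    score_alt: float
    raw_score_ref: float
    raw_score_alt: float
    window_ref: tuple[int, str]  # (window start in context, strand)
    window_alt: tuple[int, str]
    p_ref: float
    p_alt: float
    effect: str | None = None

    @property
    def delta(self) -> float:
        """Normalized score change, alt minus ref."""
        return self.score_alt - self.score_ref


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_BASE_INDEX[b] for b in seq.upper()], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"ambiguous or invalid base {exc.args[0]!r}") from None


def score_sequence(seq: str, pwm: PWM) -> float:
    """Relative-entropy-weighted match score of one L-mer."""
    idx = _encode(seq)
    if idx.size != pwm.length:
        raise ValueError(f"sequence length {idx.size} != motif length {pwm.length}")
    sm = pwm.score_matrix
    return float(sm[np.arange(pwm.length), idx].sum())


def _normalize(score: float, pwm: PWM) -> float:
    m = pwm.max_score
    if m <= 0:
        return 0.0
    return max(0.0, score) / m


def best_window_scores(
    context: str, alt_allele: str, snp_offset: int, pwm: PWM, snp: str = "snp"
) -> DisruptionCall:
    """Best-scoring SNP-covering window per allele, both strands.

    ``context`` is the reference flanking sequence with the SNP base at
    ``snp_offset``; it must extend at least motif-length - 1 bases on
    each side so every window overlapping the SNP can be scored.
    """
    L = pwm.length
    if len(context) < L:
        raise ValueError("context shorter than motif")
    if not (0 <= snp_offset < len(context)):
        raise ValueError("snp_offset outside context")
    lo = snp_offset - L + 1
    hi = snp_offset
    starts = [s for s in range(lo, hi + 1) if 0 <= s and s + L <= len(context)]
    if not starts:
        raise ValueError("no scoring window covers the SNP inside the context")
    pwm_rc = pwm.reverse_complement()
    results = {}
    for allele, label in ((context[snp_offset], "ref"), (alt_allele.upper(), "alt")):
        seq = context[:snp_offset] + allele + context[snp_offset + 1 :]
        best = (-np.inf, None, None)
        for s in starts:
            window = seq[s : s + L]
            for strand, mat in (("+", pwm), ("-", pwm_rc)):
                sc = score_sequence(window, mat)
                if sc > best[0]:
                    best = (sc, s, strand)
        results[label] = best
    raw_ref, start_ref, strand_ref = results["ref"]
    raw_alt, start_alt, strand_alt = results["alt"]
    return DisruptionCall(
        snp=snp,
        motif_id=pwm.motif_id,
        score_ref=_normalize(raw_ref, pwm),
        score_alt=_normalize(raw_alt, pwm),
        raw_score_ref=raw_ref,
        raw_score_alt=raw_alt,
        window_ref=(start_ref, strand_ref),
        window_alt=(start_alt, strand_alt),
        p_ref=score_pvalue(raw_ref, pwm),
        p_alt=score_pvalue(raw_alt, pwm),
    )


def score_pvalue(
    score: float,
    pwm: PWM,
    method: Literal["auto", "exact", "convolution"] = "auto",
    grid_step: float = GRID_STEP,
) -> float:
    """P(S >= score) for the score S of a background-random L-mer.

    Exhaustive over all 4^L sequences for short motifs; otherwise a
    position-wise convolution of the per-position score contributions
    rounded to a lattice of ``grid_step``. The convolution itself is
    exact on that lattice; the only approximation is the per-position
    rounding, bounding the score error by L * grid_step / 2.
    """
    if not np.isfinite(score):
        raise ValueError("score must be finite")
    if method == "auto":
        method = "exact" if pwm.length <= EXACT_MAX_LENGTH else "convolution"
    sm = pwm.score_matrix
    bg = pwm.background
    if method == "exact":
        scores = np.zeros(1)
        probs = np.ones(1)
        for p in range(pwm.length):
            scores = (scores[:, None] + sm[p][None, :]).ravel()
            probs = (probs[:, None] * bg[None, :]).ravel()
        return float(probs[scores >= score - 1e-12].sum())
    if method != "convolution":
        raise ValueError(f"unknown method {method!r}")
    offsets = np.rint(sm / grid_step).astype(np.int64)
    dist = np.ones(1)
    cur_lo = 0
    for p in range(pwm.length):
        o = offsets[p]
        new_lo = cur_lo + int(o.min())
        new_hi = cur_lo + dist.size - 1 + int(o.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            start = cur_lo + int(o[b]) - new_lo
            new[start : start + dist.size] += bg[b] * dist
        dist, cur_lo = new, new_lo
    threshold = int(np.rint(score / grid_step))
    idx = np.arange(cur_lo, cur_lo + dist.size)
    return float(dist[idx >= threshold].sum())


def classify_disruption(
    call: DisruptionCall, strong_delta: float = 0.7, weak_delta: float = 0.4
) -> str:
    """Label a call strong / weak / neutral by its normalized |delta|.

    Boundary values take the stronger label (>= comparisons).
    """
    d = abs(call.delta)
    if d >= strong_delta:
        effect = "strong"
    elif d >= weak_delta:
        effect = "weak"
    else:
        effect = "neutral"
    call.effect = effect
    return effect
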