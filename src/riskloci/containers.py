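"""In-memory containers shared across pipeline stages.

Coordinates are 0-based half-open throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1  # missing genotype sentinel in dosage matrices

#: 12-state chromatin alphabet (promoter / enhancer / transcription /
#: repressed families) used by the segmentation tracks.
STATE_ALPHABET = (
    "ActProm",
    "WkProm",
    "PoisProm",
    "StrEnh1",
    "StrEnh2",
    "WkEnh",
    "Txn_Trans",
    "Txn_Elong",
    "Wk_Txn",
    "H3K9me3_Repr",
    "H3K27me3_Repr",
    "Het;LowSign",
)

ACTIVE_STATES = ("ActProm", "StrEnh1", "StrEnh2")
WEAK_STATES = ("WkProm", "WkEnh")
TXN_STATES = ("Txn_Trans", "Txn_Elong", "Wk_Txn")


@dataclass
class HaplotypePanel:
    """Phased biallelic haplotypes on a single linear contig."""

    contig: str
    snp_ids: list[str]
    positions: np.ndarray  # int64, ascending
    haplotypes: np.ndarray  # (n_haplotypes, n_snps) in {0, 1}
    block_ids: np.ndarray  # LD-block index per SNP

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.block_ids = np.asarray(self.block_ids, dtype=np.int64)
        if self.haplotypes.shape[1] != len(self.snp_ids):
            raise ValueError("haplotype matrix width != number of SNPs")
        if np.any(np.diff(self.positions) < 0):
            raise ValueError("SNP positions must be ascending")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in panel") from None

    def allele_freq(self, snp_id: str) -> float:
        return float(self.haplotypes[:, self.snp_index(snp_id)].mean())


@dataclass
class GenotypeMatrix:
    """Samples x SNPs dosage calls in {0, 1, 2, MISSING} with provenance."""

    sample_ids: list[str]
    snp_ids: list[str]
    positions: np.ndarray
    contig: str
    dosages: np.ndarray  # (n_samples, n_snps) int8, MISSING = -1
    provenance: np.ndarray | None = None  # same shape, small string codes
    excluded_samples: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError("dosage matrix shape mismatch")
        valid = np.isin(self.dosages, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2, -1}")

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"SNP {snp_id!r} not in genotype matrix") from None

    def dosage_of(self, snp_id: str) -> np.ndarray:
        return self.dosages[:, self.snp_index(snp_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=self.sample_ids, columns=self.snp_ids)


@dataclass
class SegmentationTrack:
    """Per-sample partition of the contig into fixed-width state bins."""

    sample: str
    contig: str
    bin_size: int
    states: np.ndarray  # int codes into alphabet, one per bin
    alphabet: tuple[str, ...] = STATE_ALPHABET

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int16)
        if self.states.min(initial=0) < 0 or self.states.max(initial=0) >= len(self.alphabet):
            raise ValueError("state codes outside alphabet")

    @property
    def extent(self) -> int:
        return self.states.size * self.bin_size

    def state_at(self, position: int) -> str:
        if not (0 <= position < self.extent):
            raise ValueError(f"position {position} outside track extent {self.extent}")
        return self.alphabet[self.states[position // self.bin_size]]


@dataclass
class FeatureMatrix:
    """One molecular layer: samples x features with intervals and presence."""

    layer: str  # accessibility | h3k27ac | methylation | expression
    sample_ids: list[str]
    feature_ids: list[str]
    starts: np.ndarray
    ends: np.ndarray
    contig: str
    values: np.ndarray  # (n_samples, n_features) float
    presence: np.ndarray  # (n_samples, n_features) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.presence = np.asarray(self.presence, dtype=bool)
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        shape = (len(self.sample_ids), len(self.feature_ids))
        if self.values.shape != shape or self.presence.shape != shape:
            raise ValueError("value/presence matrix shape mismatch")

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)


@dataclass
class AlleleCountTable:
    """Per SNP x sample reference/alternative read counts plus annotations.

    counts: DataFrame with columns snp, sample, ref_count, alt_count.
    snps:   DataFrame indexed by snp with columns contig, pos, in_peak,
            ld_proxy, background.
    """

    counts: pd.DataFrame
    snps: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"snp", "sample", "ref_count", "alt_count"}
        if not need.issubset(self.counts.columns):
            raise ValueError(f"counts missing columns {need - set(self.counts.columns)}")
        if (self.counts[["ref_count", "alt_count"]] < 0).any().any():
            raise ValueError("negative read counts")
        both = self.snps["ld_proxy"] & self.snps["background"]
        if both.any():
            raise ValueError("ld_proxy and background flags are mutually exclusive")


@dataclass
class RiskLocus:
    """A sentinel SNP, its LD proxies, and the spanning interval."""

    sentinel: str
    sentinel_pos: int
    contig: str
    proxies: pd.DataFrame  # indexed by snp id: pos, r2
    start: int
    end: int  # half-open

    def __post_init__(self) -> None:
        if self.sentinel not in self.proxies.index:
            raise ValueError("sentinel must be among its own proxies")
        pos = self.proxies["pos"].to_numpy()
        if pos.min() < self.start or pos.max() >= self.end:
            raise ValueError("proxy positions outside locus interval")

    @property
    def size_kb(self) -> float:
        return (self.end - self.start) / 1000.0


@dataclass
class BackgroundRegions:
    """Merged LD-region background with its exclusion record."""

    intervals: np.ndarray  # (k, 2) sorted, non-overlapping
    excluded: np.ndarray  # (m, 2) intervals subtracted out

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        self.excluded = np.asarray(self.excluded, dtype=np.int64).reshape(-1, 2)

    @property
    def total_length(self) -> int:
        if self.intervals.size == 0:
            return 0
        return int((self.intervals[:, 1] - self.intervals[:, 0]).sum())
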