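"""Seeded synthetic fixtures with the statistical structure of the study.

One linear contig carries LD-blocked haplotypes with sentinel SNPs and
proxies; per-sample 12-state segmentations in 200-bp bins with planted
active loci; per-layer feature matrices with planted dosage effects and
latent confounders; and beta-binomially overdispersed allele-specific
read counts with planted imbalance. All randomness flows from one root
seed through named substreams, so identical configs reproduce identical
bundles.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    ACTIVE_STATES,
    STATE_ALPHABET,
    AlleleCountTable,
    BackgroundRegions,
    FeatureMatrix,
    GenotypeMatrix,
    HaplotypePanel,
    RiskLocus,
    SegmentationTrack,
)
from .ld import build_background_regions, define_ld_region
from .motifs import PWM
from .qtl import TADMap

__all__ = ["SimulationConfig", "FixtureBundle", "make_haplotype_panel",
           "make_genotypes", "define_loci", "sentinel_ids", "locus_activity_classes",
           "planted_qtl_loci", "make_segmentations", "make_feature_layers",
           "make_allele_counts", "make_tad_map", "make_motif_fixtures",
           "make_bundle"]

LAYERS = ("accessibility", "h3k27ac", "methylation", "expression")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults emulate the study design."""

    seed: int = 0
    n_samples: int = 99
    n_loci: int = 42
    snps_per_block: int = 25
    haplotypes_per_block: int = 400
    block_r2_decay: float = 0.9
    qtl_effect_size: float = 1.0
    overdispersion_alpha: float = 20.5
    overdispersion_beta: float = 20.3
    n_latent_factors: int = 3
    fraction_imbalanced_snps: float = 9 / 189
    state_alphabet: tuple[str, ...] = STATE_ALPHABET
    genome_length: int = 10_000_000
    bin_size: int = 200
    snp_spacing: int = 400
    n_background_blocks: int = 20
    n_background_snps: int = 2000
    mean_reads: float = 40.0
    noise_sd: float = 1.0
    imbalance_ratio: float = 0.8
    seq_error: float = 0.005
    n_strong_active_loci: int = 34
    n_weak_active_loci: int = 5
    n_null_features: int = 40
    planted_qtl_counts: Mapping[str, int] = field(
        default_factory=lambda: {
            "accessibility": 14,
            "h3k27ac": 9,
            "methylation": 28,
            "expression": 23,
        }
    )

    def __post_init__(self) -> None:
        for name in ("block_r2_decay", "fraction_imbalanced_snps", "seq_error"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("overdispersion_alpha", "overdispersion_beta"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v}")
        if not np.isfinite(self.qtl_effect_size):
            raise ValueError(f"qtl_effect_size must be finite, got {self.qtl_effect_size}")
        if self.haplotypes_per_block < 4:
            raise ValueError(
                f"haplotypes_per_block must be >= 4, got {self.haplotypes_per_block}"
            )
        if len(self.state_alphabet) != 12:
            raise ValueError("state_alphabet must list 12 states")
        if self.genome_length % self.bin_size != 0:
            raise ValueError("genome_length must be a multiple of bin_size")
        if self.n_strong_active_loci + self.n_weak_active_loci > self.n_loci:
            raise ValueError("active locus counts exceed n_loci")

    def rng(self, *names: object) -> np.random.Generator:
        """Named substream of the root seed (stage-level reproducibility)."""
        keys = [zlib.crc32(str(n).encode()) for n in names]
        return np.random.default_rng(np.random.SeedSequence([self.seed, *keys]))


@dataclass
class FixtureBundle:
    config: SimulationConfig
    panel: HaplotypePanel
    genotypes: GenotypeMatrix
    loci: list[RiskLocus]
    background: BackgroundRegions
    tracks: list[SegmentationTrack]
    layers: dict[str, FeatureMatrix]
    tad_map: TADMap
    allele_counts: AlleleCountTable
    ai_genotypes: GenotypeMatrix
    pwms: list[PWM]
    snp_contexts: pd.DataFrame
    truth: dict[str, pd.DataFrame]


# ---------------------------------------------------------------------------
# haplotype panel and genotypes
# ---------------------------------------------------------------------------

def make_haplotype_panel(config: SimulationConfig) -> HaplotypePanel:
    """LD-blocked haplotype panel with one designated sentinel per risk block.

    Within a block, SNP t+1 copies SNP t per haplotype with probability
    sqrt(decay) and is otherwise redrawn from the block allele
    frequency, which makes the expected lag-1 r^2 equal the configured
    decay; blocks are mutually independent.
    """
    rng = config.rng("panel")
    n_blocks = config.n_loci + config.n_background_blocks
    m = config.snps_per_block
    H = config.haplotypes_per_block
    pitch = config.genome_length // n_blocks
    if m * config.snp_spacing > pitch:
        raise ValueError("snps_per_block * snp_spacing exceeds block pitch")
    copy_prob = float(np.sqrt(config.block_r2_decay))
    haps = np.empty((H, n_blocks * m), dtype=np.int8)
    positions = np.empty(n_blocks * m, dtype=np.int64)
    snp_ids: list[str] = []
    block_ids = np.repeat(np.arange(n_blocks), m)
    for b in range(n_blocks):
        p = rng.uniform(0.3, 0.7)
        col = rng.random(H) < p
        start = b * pitch + pitch // 4
        for j in range(m):
            idx = b * m + j
            if j > 0:
                redraw = rng.random(H) >= copy_prob
                col = np.where(redraw, rng.random(H) < p, col)
            # guarantee polymorphism so r^2 is defined everywhere
            if col.all() or not col.any():
                col = col.copy()
                col[rng.integers(H)] ^= True
            haps[:, idx] = col
            positions[idx] = start + j * config.snp_spacing
            if b < config.n_loci and j == m // 2:
                snp_ids.append(f"rs{b:03d}")
            else:
                snp_ids.append(f"snp_b{b:03d}_{j:02d}")
    return HaplotypePanel(
        contig="chrS",
        snp_ids=snp_ids,
        positions=positions,
        haplotypes=haps,
        block_ids=block_ids,
    )


def sentinel_ids(config: SimulationConfig) -> list[str]:
    return [f"rs{b:03d}" for b in range(config.n_loci)]


def make_genotypes(panel: HaplotypePanel, config: SimulationConfig) -> GenotypeMatrix:
    """Diploid cohort drawn by random union of panel haplotypes."""
    rng = config.rng("genotypes")
    n = config.n_samples
    i1 = rng.integers(0, panel.haplotypes.shape[0], size=n)
    i2 = rng.integers(0, panel.haplotypes.shape[0], size=n)
    dosages = (panel.haplotypes[i1] + panel.haplotypes[i2]).astype(np.int8)
    return GenotypeMatrix(
        sample_ids=[f"S{i:03d}" for i in range(n)],
        snp_ids=list(panel.snp_ids),
        positions=panel.positions,
        contig=panel.contig,
        dosages=dosages,
    )


def define_loci(panel: HaplotypePanel, config: SimulationConfig) -> list[RiskLocus]:
    return [define_ld_region(panel, s) for s in sentinel_ids(config)]


# ---------------------------------------------------------------------------
# segmentation tracks
# ---------------------------------------------------------------------------

#: genome-wide background state frequencies (low-signal heterochromatin
#: dominates, active states are rare), indexed like STATE_ALPHABET
BACKGROUND_STATE_FREQS = np.array(
    [0.02, 0.04, 0.03, 0.02, 0.02, 0.04, 0.05, 0.05, 0.05, 0.05, 0.05, 0.58]
)


def locus_activity_classes(config: SimulationConfig) -> pd.DataFrame:
    """Planted per-locus activity class: strong / weak / inactive."""
    classes = (
        ["strong"] * config.n_strong_active_loci
        + ["weak"] * config.n_weak_active_loci
        + ["inactive"] * (config.n_loci - config.n_strong_active_loci - config.n_weak_active_loci)
    )
    return pd.DataFrame({"sentinel": sentinel_ids(config), "activity": classes}).set_index(
        "sentinel"
    )


def make_segmentations(
    panel: HaplotypePanel,
    loci: list[RiskLocus],
    config: SimulationConfig,
    sample_ids: list[str] | None = None,
) -> list[SegmentationTrack]:
    """Per-sample chromatin-state tracks with planted locus activity.

    Background bins follow the genome-wide state frequencies. Inside
    planted strongly active loci, bins are drawn from the three active
    states with probability 0.8 in every sample; weakly active loci get
    a single active bin at one proxy SNP in the first sample only;
    inside weak/inactive loci the active states are suppressed so that
    the planted activity partition is recoverable.
    """
    if config.genome_length % config.bin_size != 0:
        raise ValueError("genome length must be a multiple of the bin size")
    if sample_ids is None:
        sample_ids = [f"S{i:03d}" for i in range(config.n_samples)]
    alphabet = config.state_alphabet
    n_bins = config.genome_length // config.bin_size
    active_idx = np.array([alphabet.index(s) for s in ACTIVE_STATES])
    nonactive_idx = np.array([i for i in range(12) if i not in set(active_idx)])
    nonactive_freqs = BACKGROUND_STATE_FREQS[nonactive_idx]
    nonactive_freqs = nonactive_freqs / nonactive_freqs.sum()
    classes = locus_activity_classes(config)

    tracks = []
    for s_idx, sid in enumerate(sample_ids):
        rng = config.rng("segmentation", sid)
        states = rng.choice(12, size=n_bins, p=BACKGROUND_STATE_FREQS).astype(np.int16)
        for locus in loci:
            b0, b1 = locus.start // config.bin_size, (locus.end - 1) // config.bin_size
            width = b1 - b0 + 1
            activity = classes.loc[locus.sentinel, "activity"]
            if activity == "strong":
                act = rng.random(width) < 0.8
                fill = np.where(
                    act,
                    rng.choice(active_idx, size=width),
                    rng.choice(nonactive_idx, size=width, p=nonactive_freqs),
                )
            else:
                fill = rng.choice(nonactive_idx, size=width, p=nonactive_freqs)
                if activity == "weak" and s_idx == 0:
                    snp_pos = int(locus.proxies["pos"].iloc[0])
                    fill[snp_pos // config.bin_size - b0] = active_idx[1]  # StrEnh1
            states[b0 : b1 + 1] = fill
        tracks.append(
            SegmentationTrack(
                sample=sid,
                contig=panel.contig,
                bin_size=config.bin_size,
                states=states,
                alphabet=alphabet,
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# feature layers
# ---------------------------------------------------------------------------

def planted_qtl_loci(config: SimulationConfig) -> dict[str, list[str]]:
    """Deterministic per-layer planted-QTL locus assignment.

    Windows over the locus list are chosen so the layer counts match the
    configured values and the layers overlap the way the study design
    implies (methylation broad, accessibility/H3K27ac nested, union
    covering most but not all loci).
    """
    sent = sentinel_ids(config)
    n = config.n_loci
    c = config.planted_qtl_counts
    meth = sent[: min(c.get("methylation", 0), n)]
    expr_hi = min(n, 13 + c.get("expression", 0)) if n > 13 else n
    expr = sent[min(13, n - 1) : expr_hi]
    acc_lo = max(0, min(n, 36) - c.get("accessibility", 0))
    acc = sent[acc_lo : min(n, 36)]
    h3_lo = max(0, min(n, 36) - c.get("h3k27ac", 0))
    h3 = sent[h3_lo : min(n, 36)]
    return {"methylation": meth, "expression": expr, "accessibility": acc, "h3k27ac": h3}


_LAYER_SIGN = {"accessibility": 1.0, "h3k27ac": 1.0, "expression": 1.0, "methylation": -1.0}
_LAYER_INTERCEPT = {"accessibility": 5.0, "h3k27ac": 5.0, "expression": 7.0, "methylation": 0.0}


def make_feature_layers(
    panel: HaplotypePanel,
    loci: list[RiskLocus],
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    """Samples x features per layer with planted dosage effects.

    Each locus carries one feature per layer centered at its sentinel;
    null features sit in the non-risk half of the genome. Planted
    effects follow feature = intercept + beta * dosage + latent-factor
    contribution + Gaussian noise, with accessibility/H3K27ac/expression
    sharing the effect sign and methylation opposing it.
    """
    if not np.isfinite(config.qtl_effect_size):
        raise ValueError("qtl_effect_size must be finite")
    rng = config.rng("features")
    n = config.n_samples
    factors = rng.normal(size=(n, config.n_latent_factors))
    planted = planted_qtl_loci(config) if config.qtl_effect_size != 0 else {
        layer: [] for layer in LAYERS
    }
    layers: dict[str, FeatureMatrix] = {}
    truth_rows = []
    null_start = (config.n_loci + config.n_background_blocks // 2) * (
        config.genome_length // (config.n_loci + config.n_background_blocks)
    )
    for layer in LAYERS:
        fids, starts, ends = [], [], []
        betas = []
        for locus in loci:
            fids.append(f"{layer[:3]}_{locus.sentinel}")
            starts.append(locus.sentinel_pos - 300)
            ends.append(locus.sentinel_pos + 300)
            if locus.sentinel in planted[layer]:
                betas.append(_LAYER_SIGN[layer] * config.qtl_effect_size)
            else:
                betas.append(0.0)
        for k in range(config.n_null_features):
            fids.append(f"{layer[:3]}_null{k:03d}")
            s = null_start + 1000 * k
            starts.append(s)
            ends.append(s + 600)
            betas.append(0.0)
        n_feat = len(fids)
        loadings = rng.normal(scale=0.5, size=(config.n_latent_factors, n_feat))
        noise = rng.normal(scale=config.noise_sd, size=(n, n_feat))
        dosage = np.zeros((n, n_feat))
        for j, locus in enumerate(loci):
            dosage[:, j] = genotypes.dosage_of(locus.sentinel)
        values = (
            _LAYER_INTERCEPT[layer]
            + dosage * np.asarray(betas)
            + factors @ loadings
            + noise
        )
        presence = rng.random((n, n_feat)) < 0.95
        layers[layer] = FeatureMatrix(
            layer=layer,
            sample_ids=list(genotypes.sample_ids),
            feature_ids=fids,
            starts=np.asarray(starts),
            ends=np.asarray(ends),
            contig=panel.contig,
            values=values,
            presence=presence,
        )
        for j, locus in enumerate(loci):
            if betas[j] != 0.0:
                truth_rows.append(
                    {
                        "layer": layer,
                        "sentinel": locus.sentinel,
                        "feature": fids[j],
                        "beta": betas[j],
                    }
                )
    truth = pd.DataFrame(truth_rows, columns=["layer", "sentinel", "feature", "beta"])
    return layers, truth


def make_tad_map(config: SimulationConfig) -> TADMap:
    """TADs tiling the genome at the LD-block pitch, one gene per locus."""
    n_blocks = config.n_loci + config.n_background_blocks
    pitch = config.genome_length // n_blocks
    tads = pd.DataFrame(
        {
            "start": np.arange(n_blocks) * pitch,
            "end": np.arange(1, n_blocks + 1) * pitch,
        },
        index=pd.Index([f"tad{b:03d}" for b in range(n_blocks)], name="tad_id"),
    )
    m = config.snps_per_block
    gene_pos = [
        b * pitch + pitch // 4 + (m // 2) * config.snp_spacing for b in range(config.n_loci)
    ]
    genes = pd.DataFrame(
        {
            "start": [p + 1000 for p in gene_pos],
            "end": [p + 3000 for p in gene_pos],
        },
        index=pd.Index([f"gene{b:03d}" for b in range(config.n_loci)], name="gene_id"),
    )
    return TADMap(tads=tads, genes=genes)


# ---------------------------------------------------------------------------
# allele counts
# ---------------------------------------------------------------------------

def _snp_level_ratios(
    rng: np.random.Generator, n_snps: int, alpha: float, beta: float
) -> np.ndarray:
    """Latent per-SNP reference-read ratio, shared by all carriers.

    Allelic imbalance is a property of the variant (a cis effect), so
    one Beta draw per SNP; pooled heterozygote counts are then exactly
    beta-binomial with the same shapes.
    """
    return rng.beta(alpha, beta, size=n_snps)


def make_allele_counts(
    panel: HaplotypePanel,
    loci: list[RiskLocus],
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
) -> tuple[AlleleCountTable, GenotypeMatrix, pd.DataFrame]:
    """Allele-specific read counts at risk-locus and background SNPs.

    Risk-locus candidates are proxy SNPs inside accessibility peaks
    (about 4-5 per locus); the background set is drawn fresh in
    Hardy-Weinberg proportions. Heterozygote reference counts are
    beta-binomial under the null and mean-shifted at planted imbalanced
    SNPs; homozygote counts carry a small sequencing-error allele.
    """
    rng = config.rng("allele_counts")
    a0, b0 = config.overdispersion_alpha, config.overdispersion_beta
    r = config.imbalance_ratio

    cand_ids, cand_pos, cand_locus = [], [], []
    for i, locus in enumerate(loci):
        per = 5 if i % 2 == 0 else 4
        prox = locus.proxies.sort_values("pos")
        take = prox.iloc[: min(per, len(prox))]
        for snp, row in take.iterrows():
            cand_ids.append(snp)
            cand_pos.append(int(row["pos"]))
            cand_locus.append(locus.sentinel)
    n_bg = config.n_background_snps
    bg_ids = [f"bg{i:05d}" for i in range(n_bg)]
    bg_pos = (config.genome_length - 100 * np.arange(1, n_bg + 1)).astype(np.int64)

    # planted imbalanced SNPs, preferentially at accessibility-QTL loci
    acc_loci = set(planted_qtl_loci(config)["accessibility"])
    cand = pd.DataFrame({"snp": cand_ids, "pos": cand_pos, "locus": cand_locus})
    n_imb = int(round(config.fraction_imbalanced_snps * len(cand)))
    in_acc = cand.index[cand["locus"].isin(acc_loci)].to_numpy()
    out_acc = cand.index[~cand["locus"].isin(acc_loci)].to_numpy()
    n_in = min(max(n_imb - 1, 0), in_acc.size) if out_acc.size and n_imb else min(n_imb, in_acc.size)
    picked = list(rng.choice(in_acc, size=n_in, replace=False))
    remaining = n_imb - len(picked)
    if remaining > 0 and out_acc.size:
        picked += list(rng.choice(out_acc, size=min(remaining, out_acc.size), replace=False))
    imbalanced = set(cand.loc[picked, "snp"])

    # genotype matrix over candidate + background SNPs
    samples = list(genotypes.sample_ids)
    n_s = len(samples)
    cand_dos = np.column_stack([genotypes.dosage_of(s) for s in cand_ids]).astype(np.int8)
    bg_freq = rng.uniform(0.2, 0.8, size=n_bg)
    bg_dos = rng.binomial(2, bg_freq, size=(n_s, n_bg)).astype(np.int8)
    ai_geno = GenotypeMatrix(
        sample_ids=samples,
        snp_ids=cand_ids + bg_ids,
        positions=np.concatenate([np.asarray(cand_pos, dtype=np.int64), bg_pos]),
        contig=panel.contig,
        dosages=np.concatenate([cand_dos, bg_dos], axis=1),
    )

    all_ids = cand_ids + bg_ids
    dosages = ai_geno.dosages
    totals = rng.poisson(config.mean_reads, size=dosages.shape) + 1
    ref = np.empty_like(totals)
    het = dosages == 1
    imb_col = np.array([s in imbalanced for s in all_ids])
    p_snp = _snp_level_ratios(rng, len(all_ids), a0, b0)
    # planted SNPs carry exactly the configured ratio so the truth table
    # states the true generating value
    p_snp = np.where(imb_col, r, p_snp)
    het_k = rng.binomial(totals, np.broadcast_to(p_snp, dosages.shape))
    ref[het] = het_k[het]
    err = rng.binomial(totals, config.seq_error)
    hom_ref = dosages == 0
    hom_alt = dosages == 2
    ref[hom_ref] = (totals - err)[hom_ref]
    ref[hom_alt] = err[hom_alt]

    counts = pd.DataFrame(
        {
            "snp": np.repeat(all_ids, n_s),
            "sample": np.tile(samples, len(all_ids)),
            "ref_count": ref.T.ravel(),
            "alt_count": (totals - ref).T.ravel(),
        }
    )
    snps = pd.DataFrame(
        {
            "contig": panel.contig,
            "pos": np.concatenate([np.asarray(cand_pos, dtype=np.int64), bg_pos]),
            "in_peak": True,
            "ld_proxy": [True] * len(cand_ids) + [False] * n_bg,
            "background": [False] * len(cand_ids) + [True] * n_bg,
        },
        index=pd.Index(all_ids, name="snp"),
    )
    truth = pd.DataFrame(
        {
            "snp": sorted(imbalanced),
            "ratio": config.imbalance_ratio,
        }
    )
    truth["locus"] = truth["snp"].map(cand.set_index("snp")["locus"])
    return AlleleCountTable(counts=counts, snps=snps), ai_geno, truth


# ---------------------------------------------------------------------------
# motif fixtures
# ---------------------------------------------------------------------------

def make_motif_fixtures(
    config: SimulationConfig, n_snps: int = 8
) -> tuple[list[PWM], pd.DataFrame]:
    """Synthetic PWMs plus SNP flanking contexts with planted disruptions.

    One sharp (high-information) motif and one diffuse motif; half the
    SNP contexts embed the sharp motif's consensus with the alternative
    allele destroying a high-information position.
    """
    rng = config.rng("motifs")
    sharp = np.full((5, 4), 0.001)
    consensus = rng.integers(0, 4, size=5)
    sharp[np.arange(5), consensus] = 0.997
    diffuse = rng.dirichlet(np.full(4, 5.0), size=10)
    pwms = [PWM("SHARP01", sharp), PWM("DIFFUSE01", diffuse)]
    bases = "ACGT"
    cons_seq = "".join(bases[i] for i in consensus)
    rows = []
    for i in range(n_snps):
        flank_l = "".join(rng.choice(list(bases), size=20))
        flank_r = "".join(rng.choice(list(bases), size=20))
        if i % 2 == 0:
            core = cons_seq
            offset = 20 + 2  # SNP at consensus position 2
            ref = core[2]
            alt = bases[(consensus[2] + 2) % 4]
            context = (flank_l + core + flank_r)[:48]
            planted = True
        else:
            context = (flank_l + "".join(rng.choice(list(bases), size=8)) + flank_r)[:48]
            offset = 24
            ref = context[offset]
            alt = bases[(bases.index(ref) + 1) % 4]
            planted = False
        rows.append(
            {
                "snp": f"msnp{i:02d}",
                "context": context,
                "offset": offset,
                "ref": ref,
                "alt": alt,
                "planted_disruption": planted,
            }
        )
    return pwms, pd.DataFrame(rows).set_index("snp")


# ---------------------------------------------------------------------------
# whole-bundle assembly
# ---------------------------------------------------------------------------

def make_bundle(config: SimulationConfig) -> FixtureBundle:
    """Generate every layer of a coherent synthetic study."""
    panel = make_haplotype_panel(config)
    genotypes = make_genotypes(panel, config)
    loci = define_loci(panel, config)
    background = build_background_regions(panel, loci)
    tracks = make_segmentations(panel, loci, config, list(genotypes.sample_ids))
    layers, qtl_truth = make_feature_layers(panel, loci, genotypes, config)
    tad_map = make_tad_map(config)
    counts, ai_geno, ai_truth = make_allele_counts(panel, loci, genotypes, config)
    pwms, contexts = make_motif_fixtures(config)
    truth = {
        "qtl": qtl_truth,
        "imbalanced": ai_truth,
        "locus_activity": locus_activity_classes(config).reset_index(),
    }
    return FixtureBundle(
        config=config,
        panel=panel,
        genotypes=genotypes,
        loci=loci,
        background=background,
        tracks=tracks,
        layers=layers,
        tad_map=tad_map,
        allele_counts=counts,
        ai_genotypes=ai_geno,
        pwms=pwms,
        snp_contexts=contexts,
        truth=truth,
    )
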