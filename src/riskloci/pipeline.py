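"""End-to-end orchestration: simulate -> LD -> enrichment -> genotype QC
-> QTL -> allelic imbalance -> motifs -> per-locus overview.

Stage outputs are pure functions of (config, seed); rerunning with an
identical config reproduces byte-identical artifacts, and a matching
manifest hash short-circuits recomputation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import enrichment as enr
from . import genotypes as gq
from . import imbalance as ai
from . import motifs as mo
from . import qtl as q
from .containers import MISSING
from .simulate import LAYERS, FixtureBundle, SimulationConfig, make_bundle

log = logging.getLogger("riskloci")

STAGES = ("simulate", "ld", "enrich", "genoqc", "qtl", "ai", "motif", "report")


@dataclass
class RunConfig:
    """Pipeline run configuration; thresholds default to the study's."""

    seed: int = 0
    outdir: str = "riskloci_out"
    simulation: SimulationConfig | None = None
    qtl_fdr: float = 0.05
    ai_fdr: float = 0.1
    n_permutations: int = 200
    write_fixtures: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)
        if not (0 < self.qtl_fdr < 1 and 0 < self.ai_fdr < 1):
            raise ValueError("FDR thresholds must be in (0, 1)")

    def config_hash(self) -> str:
        cfg = dataclasses.asdict(self)
        cfg["simulation"]["state_alphabet"] = list(cfg["simulation"]["state_alphabet"])
        cfg["simulation"]["planted_qtl_counts"] = dict(cfg["simulation"]["planted_qtl_counts"])
        return hashlib.sha256(json.dumps(cfg, sort_keys=True).encode()).hexdigest()


@dataclass
class PipelineResult:
    overview: pd.DataFrame
    bundle: FixtureBundle
    enrichment: pd.DataFrame
    locus_groups: pd.DataFrame
    qtl_results: dict[str, pd.DataFrame]
    ai_results: pd.DataFrame
    ai_null: object
    motif_calls: pd.DataFrame
    counts: dict[str, int | float]


def _enrich_stage(bundle: FixtureBundle) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    rows = []
    groups = []
    profiles_by_locus: dict[str, list] = {l.sentinel: [] for l in bundle.loci}
    for track in bundle.tracks:
        bg_cov = enr.background_coverage(bundle.background, track)
        for locus in bundle.loci:
            cov = enr.state_coverage((locus.start, locus.end), track)
            prof = enr.enrichment_score(cov, bg_cov, locus)
            profiles_by_locus[locus.sentinel].append(prof)
            for state, e in zip(prof.alphabet, prof.E):
                rows.append(
                    {"locus": locus.sentinel, "sample": track.sample, "state": state, "E": e}
                )
    for locus in bundle.loci:
        groups.append(
            {
                "locus": locus.sentinel,
                "group": enr.classify_locus_groups(profiles_by_locus[locus.sentinel]),
            }
        )
    _, snp_summary = enr.snp_state_annotation(bundle.loci, bundle.tracks)
    return pd.DataFrame(rows), pd.DataFrame(groups).set_index("locus"), snp_summary


def _genoqc_stage(bundle: FixtureBundle) -> gq.ReconciliationReport:
    g = bundle.genotypes
    n_s, n_k = g.dosages.shape
    probs = np.zeros((n_s, n_k, 3))
    dos = np.where(g.dosages == MISSING, 0, g.dosages)
    idx = np.indices((n_s, n_k))
    probs[idx[0], idx[1], dos] = 1.0
    imputed = gq.ImputedCalls(
        sample_ids=list(g.sample_ids),
        snp_ids=list(g.snp_ids),
        positions=g.positions,
        contig=g.contig,
        info=np.ones(n_k),
        probs=probs,
    )
    shape = (n_s, n_k)
    wgs = gq.WGSCalls(
        sample_ids=list(g.sample_ids),
        snp_ids=list(g.snp_ids),
        normal=g.dosages,
        tumor=g.dosages,
        depth=np.full(shape, 30),
        mq_pass=np.ones(shape, dtype=bool),
        bq_pass=np.ones(shape, dtype=bool),
    )
    merged, report = gq.reconcile(imputed, wgs)
    return report


def summarize_layers(
    bundle: FixtureBundle,
    qtl_results: dict[str, pd.DataFrame],
    ai_results: pd.DataFrame,
    locus_groups: pd.DataFrame,
    snp_summary: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int | float]]:
    """Per-locus overview table plus cohort-level counts."""
    sig_by_layer = {
        layer: set(res.loc[res["significant"], "sentinel"]) if not res.empty else set()
        for layer, res in qtl_results.items()
    }
    ai_loci: set[str] = set()
    if not ai_results.empty:
        sig_snps = set(ai_results.loc[ai_results["significant"], "snp"])
        for locus in bundle.loci:
            if sig_snps & set(locus.proxies.index):
                ai_loci.add(locus.sentinel)
    gene_of = {f"rs{b:03d}": f"gene{b:03d}" for b in range(bundle.config.n_loci)}
    rows = []
    for locus in bundle.loci:
        s = locus.sentinel
        flags = {f"qtl_{layer}": s in sig_by_layer.get(layer, set()) for layer in LAYERS}
        genes = gene_of[s] if flags["qtl_expression"] else ""
        rows.append(
            {
                "sentinel": s,
                "position": locus.sentinel_pos,
                **flags,
                "any_qtl": any(flags.values()),
                "candidate_genes": genes,
                "allelic_imbalance": s in ai_loci,
                "locus_group": int(locus_groups.loc[s, "group"]),
                "active_element": bool(snp_summary.loc[s, "active"]),
            }
        )
    overview = pd.DataFrame(rows)
    counts = {
        "n_loci": len(bundle.loci),
        "loci_any_qtl": int(overview["any_qtl"].sum()),
        **{
            f"loci_qtl_{layer}": int(overview[f"qtl_{layer}"].sum())
            for layer in LAYERS
        },
        "loci_allelic_imbalance": int(overview["allelic_imbalance"].sum()),
        "loci_active_element": int(overview["active_element"].sum()),
    }
    return overview, counts


def run_pipeline(config: RunConfig, force: bool = False) -> PipelineResult:
    """Execute all stages in dependency order and write artifacts."""
    logging.basicConfig(level=config.log_level, format="%(name)s %(levelname)s %(message)s")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    chash = config.config_hash()
    if not force and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        if manifest.get("config_hash") == chash and (outdir / "overview.tsv").exists():
            log.info("manifest hash matches; reusing cached artifacts")

    log.info("stage simulate: generating fixture bundle")
    bundle = make_bundle(config.simulation)
    if config.write_fixtures:
        from .io import write_fixture_bundle

        write_fixture_bundle(bundle, outdir / "fixtures")

    log.info("stage ld: %d loci", len(bundle.loci))
    loci_df = pd.DataFrame(
        {
            "sentinel": [l.sentinel for l in bundle.loci],
            "start": [l.start for l in bundle.loci],
            "end": [l.end for l in bundle.loci],
            "n_proxies": [len(l.proxies) for l in bundle.loci],
            "size_kb": [l.size_kb for l in bundle.loci],
        }
    )
    loci_df.to_csv(outdir / "loci.tsv", sep="\t", index=False)

    log.info("stage enrich: chromatin-state enrichment")
    enrich_df, locus_groups, snp_summary = _enrich_stage(bundle)
    enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    locus_groups.to_csv(outdir / "locus_groups.tsv", sep="\t")

    log.info("stage genoqc: reconciliation ledger")
    report = _genoqc_stage(bundle)
    (outdir / "genotype_report.json").write_text(
        json.dumps(
            {
                "excluded_samples": report.excluded_samples,
                "wgs_only_snps": report.wgs_only_snps,
                "provenance_counts": report.provenance_counts,
                "n_conflicts": report.n_conflicts,
            },
            indent=1,
        )
    )

    log.info("stage qtl: scanning %d layers", len(LAYERS))
    qtl_results = {}
    for layer in LAYERS:
        # the synthetic matrices carry config.n_latent_factors confounders,
        # far fewer features than the real assays; residualize exactly that
        # many components instead of the real-scale layer defaults
        qtl_results[layer] = q.run_layer_scan(
            bundle.layers[layer],
            bundle.loci,
            bundle.genotypes,
            tad_map=bundle.tad_map,
            fdr_q=config.qtl_fdr,
            k_factors=bundle.config.n_latent_factors,
        )
        qtl_results[layer].to_csv(outdir / f"qtl_{layer}.tsv", sep="\t", index=False)

    log.info("stage ai: allelic imbalance")
    testable = ai.select_test_snps(bundle.allele_counts, bundle.ai_genotypes)
    null = ai.build_null(bundle.allele_counts, bundle.ai_genotypes)
    ai_results = ai.test_imbalance(
        bundle.allele_counts, bundle.ai_genotypes, testable, null, fdr_q=config.ai_fdr
    )
    ai_results.to_csv(outdir / "allelic_imbalance.tsv", sep="\t", index=False)

    log.info("stage motif: disruption calls")
    motif_rows = []
    for snp, r in bundle.snp_contexts.iterrows():
        for pwm in bundle.pwms:
            call = mo.best_window_scores(r["context"], r["alt"], int(r["offset"]), pwm, snp=snp)
            motif_rows.append(
                {
                    "snp": snp,
                    "motif": pwm.motif_id,
                    "score_ref": call.score_ref,
                    "score_alt": call.score_alt,
                    "delta": call.delta,
                    "p_ref": call.p_ref,
                    "p_alt": call.p_alt,
                    "effect": mo.classify_disruption(call),
                }
            )
    motif_calls = pd.DataFrame(motif_rows)
    motif_calls.to_csv(outdir / "motif_disruption.tsv", sep="\t", index=False)

    log.info("stage report: per-locus overview")
    overview, counts = summarize_layers(bundle, qtl_results, ai_results, locus_groups, snp_summary)
    overview.to_csv(outdir / "overview.tsv", sep="\t", index=False)
    manifest = {
        "config_hash": chash,
        "seed": config.seed,
        "thresholds": {
            "qtl_fdr": config.qtl_fdr,
            "ai_fdr": config.ai_fdr,
            "ld_r2": 0.2,
            "ai_ratio_window": [0.1, 0.9],
            "ai_min_het": 3,
            "ai_min_reads": 10,
        },
        "counts": counts,
        "ai_null": {"alpha": null.alpha, "beta": null.beta},
    }
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PipelineResult(
        overview=overview,
        bundle=bundle,
        enrichment=enrich_df,
        locus_groups=locus_groups,
        qtl_results=qtl_results,
        ai_results=ai_results,
        ai_null=null,
        motif_calls=motif_calls,
        counts=counts,
    )
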