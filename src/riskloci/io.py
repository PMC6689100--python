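"""Fixture-bundle serialization: BED, TSV, VCF, FASTA, JASPAR.

All interval output is 0-based half-open BED; genotype matrices go to
minimal VCF 4.2 with a GT field; feature matrices to TSV with a
``feature_id`` header column followed by sample IDs. Re-reading a
written bundle reproduces it (floats to serialization precision).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .containers import (
    MISSING,
    AlleleCountTable,
    BackgroundRegions,
    FeatureMatrix,
    GenotypeMatrix,
    HaplotypePanel,
    RiskLocus,
    SegmentationTrack,
)
from .motifs import PWM
from .qtl import TADMap
from .simulate import FixtureBundle, SimulationConfig

__all__ = ["write_fixture_bundle", "read_fixture_bundle",
           "write_genotypes_vcf", "read_genotypes_vcf"]

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
_DOSAGE = {v: k for k, v in _GT.items()}


def write_genotypes_vcf(matrix: GenotypeMatrix, path: Path) -> None:
    """Minimal VCF 4.2 with GT-only genotypes (synthetic A/G alleles)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={matrix.contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j, snp in enumerate(matrix.snp_ids):
            gts = "\t".join(_GT[int(g)] for g in matrix.dosages[:, j])
            fh.write(
                f"{matrix.contig}\t{matrix.positions[j] + 1}\t{snp}\tA\tG\t.\t.\t.\tGT\t{gts}\n"
            )


def read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    snp_ids, positions, rows = [], [], []
    contig = "chr"
    for rec in vf:
        contig = rec.chrom
        snp_ids.append(rec.id)
        positions.append(rec.pos - 1)
        row = []
        for s in samples:
            alleles = rec.samples[s]["GT"]
            if alleles is None or any(a is None for a in alleles):
                row.append(MISSING)
            else:
                row.append(sum(alleles))
        rows.append(row)
    vf.close()
    return GenotypeMatrix(
        sample_ids=samples,
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=np.int64),
        contig=contig,
        dosages=np.asarray(rows, dtype=np.int8).T,
    )


def _write_bed(path: Path, rows: list[tuple]) -> None:
    with open(path, "w") as fh:
        for row in sorted(rows, key=lambda r: (r[0], r[1], r[2])):
            fh.write("\t".join(str(x) for x in row) + "\n")


def _track_to_bed(track: SegmentationTrack) -> list[tuple]:
    rows = []
    states = track.states
    run_start = 0
    for i in range(1, states.size + 1):
        if i == states.size or states[i] != states[run_start]:
            rows.append(
                (
                    track.contig,
                    run_start * track.bin_size,
                    i * track.bin_size,
                    track.alphabet[states[run_start]],
                )
            )
            run_start = i
    return rows


def _bed_to_track(path: Path, sample: str, bin_size: int, alphabet: tuple[str, ...]) -> SegmentationTrack:
    bed = pd.read_csv(path, sep="\t", header=None, names=["contig", "start", "end", "state"])
    n_bins = int(bed["end"].max()) // bin_size
    states = np.empty(n_bins, dtype=np.int16)
    code = {s: i for i, s in enumerate(alphabet)}
    for _, r in bed.iterrows():
        states[r["start"] // bin_size : r["end"] // bin_size] = code[r["state"]]
    return SegmentationTrack(
        sample=sample, contig=str(bed["contig"].iloc[0]), bin_size=bin_size,
        states=states, alphabet=alphabet,
    )


def _write_matrix_tsv(path: Path, ids: list[str], columns: list[str], data: np.ndarray, fmt: str) -> None:
    df = pd.DataFrame(data.T, index=pd.Index(ids, name="feature_id"), columns=columns)
    df.to_csv(path, sep="\t", float_format=fmt)


def write_fixture_bundle(bundle: FixtureBundle, directory: str | Path) -> Path:
    """Serialize a bundle to plain-text files under ``directory``."""
    d = Path(directory)
    try:
        d.mkdir(parents=True, exist_ok=True)
        (d / "segmentations").mkdir(exist_ok=True)

        cfg = dataclasses.asdict(bundle.config)
        cfg["state_alphabet"] = list(cfg["state_alphabet"])
        cfg["planted_qtl_counts"] = dict(cfg["planted_qtl_counts"])
        (d / "config.json").write_text(json.dumps(cfg, indent=1))

        pd.DataFrame(
            {
                "snp": bundle.panel.snp_ids,
                "pos": bundle.panel.positions,
                "block": bundle.panel.block_ids,
            }
        ).to_csv(d / "panel_snps.tsv", sep="\t", index=False)
        np.savetxt(d / "panel_haplotypes.tsv", bundle.panel.haplotypes, fmt="%d", delimiter="\t")

        write_genotypes_vcf(bundle.genotypes, d / "genotypes.vcf")
        write_genotypes_vcf(bundle.ai_genotypes, d / "ai_genotypes.vcf")

        _write_bed(
            d / "loci.bed",
            [(l.contig, l.start, l.end, l.sentinel) for l in bundle.loci],
        )
        prox_rows = []
        for l in bundle.loci:
            for snp, r in l.proxies.iterrows():
                prox_rows.append(
                    {"locus": l.sentinel, "snp": snp, "pos": int(r["pos"]),
                     "r2": r["r2"], "sentinel_pos": l.sentinel_pos}
                )
        pd.DataFrame(prox_rows).to_csv(d / "loci_proxies.tsv", sep="\t", index=False)
        _write_bed(
            d / "background.bed",
            [("chrS", int(s), int(e)) for s, e in bundle.background.intervals],
        )
        _write_bed(
            d / "background_excluded.bed",
            [("chrS", int(s), int(e)) for s, e in bundle.background.excluded],
        )

        for track in bundle.tracks:
            _write_bed(d / "segmentations" / f"{track.sample}.bed", _track_to_bed(track))

        for layer, fm in bundle.layers.items():
            _write_bed(
                d / f"peaks_{layer}.bed",
                [
                    (fm.contig, int(s), int(e), f)
                    for f, s, e in zip(fm.feature_ids, fm.starts, fm.ends)
                ],
            )
            _write_matrix_tsv(
                d / f"{layer}_values.tsv", fm.feature_ids, fm.sample_ids, fm.values, "%.10g"
            )
            _write_matrix_tsv(
                d / f"{layer}_presence.tsv", fm.feature_ids, fm.sample_ids,
                fm.presence.astype(int), "%d",
            )

        t = bundle.tad_map
        _write_bed(d / "tads.bed", [("chrS", r["start"], r["end"], i) for i, r in t.tads.iterrows()])
        _write_bed(d / "genes.bed", [("chrS", r["start"], r["end"], i) for i, r in t.genes.iterrows()])

        bundle.allele_counts.counts.to_csv(d / "allele_counts.tsv", sep="\t", index=False)
        bundle.allele_counts.snps.to_csv(d / "snp_annotations.tsv", sep="\t")

        records = [
            SeqRecord(
                Seq(r["context"]),
                id=str(snp),
                description=f"offset={r['offset']} ref={r['ref']} alt={r['alt']} planted={int(r['planted_disruption'])}",
            )
            for snp, r in bundle.snp_contexts.iterrows()
        ]
        SeqIO.write(records, d / "snp_contexts.fasta", "fasta")

        with open(d / "pwms.jaspar", "w") as fh:
            for pwm in bundle.pwms:
                fh.write(f">{pwm.motif_id}\t{pwm.motif_id}\n")
                for b, base in enumerate("ACGT"):
                    vals = " ".join(f"{v:.10g}" for v in pwm.probs[:, b])
                    fh.write(f"{base}  [ {vals} ]\n")

        for name, df in bundle.truth.items():
            df.to_csv(d / f"truth_{name}.tsv", sep="\t", index=False)
    except OSError as exc:
        raise OSError(f"failed writing fixture bundle under {d}: {exc}") from exc
    return d


def read_fixture_bundle(directory: str | Path) -> FixtureBundle:
    """Reconstruct a bundle written by :func:`write_fixture_bundle`."""
    d = Path(directory)
    cfg = json.loads((d / "config.json").read_text())
    cfg["state_alphabet"] = tuple(cfg["state_alphabet"])
    config = SimulationConfig(**cfg)

    snps = pd.read_csv(d / "panel_snps.tsv", sep="\t")
    haps = np.loadtxt(d / "panel_haplotypes.tsv", dtype=np.int8, delimiter="\t")
    panel = HaplotypePanel(
        contig="chrS",
        snp_ids=snps["snp"].tolist(),
        positions=snps["pos"].to_numpy(),
        haplotypes=np.atleast_2d(haps),
        block_ids=snps["block"].to_numpy(),
    )
    genotypes = read_genotypes_vcf(d / "genotypes.vcf")
    ai_genotypes = read_genotypes_vcf(d / "ai_genotypes.vcf")

    prox = pd.read_csv(d / "loci_proxies.tsv", sep="\t")
    loci = []
    for sentinel, grp in prox.groupby("locus", sort=False):
        proxies = grp.set_index("snp")[["pos", "r2"]]
        loci.append(
            RiskLocus(
                sentinel=sentinel,
                sentinel_pos=int(grp["sentinel_pos"].iloc[0]),
                contig="chrS",
                proxies=proxies,
                start=int(proxies["pos"].min()),
                end=int(proxies["pos"].max()) + 1,
            )
        )
    loci.sort(key=lambda l: l.sentinel)

    def _read_bed3(path: Path) -> np.ndarray:
        if path.stat().st_size == 0:
            return np.empty((0, 2), dtype=np.int64)
        bed = pd.read_csv(path, sep="\t", header=None)
        return bed.iloc[:, 1:3].to_numpy(dtype=np.int64)

    background = BackgroundRegions(
        intervals=_read_bed3(d / "background.bed"),
        excluded=_read_bed3(d / "background_excluded.bed"),
    )

    tracks = [
        _bed_to_track(p, p.stem, config.bin_size, config.state_alphabet)
        for p in sorted((d / "segmentations").glob("*.bed"))
    ]

    layers = {}
    for layer in ("accessibility", "h3k27ac", "methylation", "expression"):
        vals = pd.read_csv(d / f"{layer}_values.tsv", sep="\t", index_col="feature_id")
        pres = pd.read_csv(d / f"{layer}_presence.tsv", sep="\t", index_col="feature_id")
        peaks = pd.read_csv(
            d / f"peaks_{layer}.bed", sep="\t", header=None,
            names=["contig", "start", "end", "feature_id"],
        ).set_index("feature_id").loc[vals.index]
        layers[layer] = FeatureMatrix(
            layer=layer,
            sample_ids=vals.columns.tolist(),
            feature_ids=vals.index.tolist(),
            starts=peaks["start"].to_numpy(),
            ends=peaks["end"].to_numpy(),
            contig="chrS",
            values=vals.to_numpy().T,
            presence=pres.to_numpy().T.astype(bool),
        )

    tads = pd.read_csv(d / "tads.bed", sep="\t", header=None,
                       names=["contig", "start", "end", "tad_id"]).set_index("tad_id")[["start", "end"]]
    genes = pd.read_csv(d / "genes.bed", sep="\t", header=None,
                        names=["contig", "start", "end", "gene_id"]).set_index("gene_id")[["start", "end"]]
    tad_map = TADMap(tads=tads, genes=genes)

    counts = pd.read_csv(d / "allele_counts.tsv", sep="\t")
    snp_ann = pd.read_csv(d / "snp_annotations.tsv", sep="\t", index_col="snp")
    allele_counts = AlleleCountTable(counts=counts, snps=snp_ann)

    rows = []
    for rec in SeqIO.parse(d / "snp_contexts.fasta", "fasta"):
        fields = dict(kv.split("=") for kv in rec.description.split()[1:])
        rows.append(
            {
                "snp": rec.id,
                "context": str(rec.seq),
                "offset": int(fields["offset"]),
                "ref": fields["ref"],
                "alt": fields["alt"],
                "planted_disruption": bool(int(fields["planted"])),
            }
        )
    snp_contexts = pd.DataFrame(rows).set_index("snp")

    with open(d / "pwms.jaspar") as fh:
        parsed = motifs.parse(fh, "jaspar")
    pwms = []
    for m in parsed:
        mat = np.array([[m.counts[b][i] for b in "ACGT"] for i in range(m.length)])
        pwms.append(PWM(m.matrix_id or m.name, mat / mat.sum(axis=1, keepdims=True)))

    truth = {}
    for p in sorted(d.glob("truth_*.tsv")):
        truth[p.stem.removeprefix("truth_")] = pd.read_csv(p, sep="\t")

    return FixtureBundle(
        config=config,
        panel=panel,
        genotypes=genotypes,
        loci=loci,
        background=background,
        tracks=tracks,
        layers=layers,
        tad_map=tad_map,
        allele_counts=allele_counts,
        ai_genotypes=ai_genotypes,
        pwms=pwms,
        snp_contexts=snp_contexts,
        truth=truth,
    )
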