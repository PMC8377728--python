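"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order over one dataset (genome + annotation +
aligned reads + sample sheet): count -> normalize -> DEG/waves;
assemble -> CPS -> filter -> locus class; tails -> priming filter ->
PAS clusters -> direction; junctions -> AS events -> stats;
correlations last.  Outputs are deterministic TSV/BED/GFF3 files plus a
run manifest with parameters and input checksums.
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

from . import core, coexpr, expression, lncrna, polya, splicing

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    alignments: str
    sample_sheet: str
    outdir: str
    seed: int = 0
    # stage toggles
    run_expression: bool = True
    run_lncrna: bool = True
    run_polya: bool = True
    run_splicing: bool = True
    run_coexpression: bool = True
    # expression
    rpkm_threshold: float = 0.1
    deg_mode: str = "fdr"
    fallback_dispersion: float = 0.1
    # lncRNA
    single_exon_threshold: int = 500
    min_depth: int = 3
    min_junction: int = 2
    cps_cutoff: float = 0.5
    min_sex_samples: int = 2
    # poly(A)
    min_tail: int = 10
    tail_error_rate: float = 0.1
    pas_max_gap: int = 20
    priming_window: int = 10
    priming_min_bases: int = 7
    direction_max_distance: int = 200
    # splicing
    min_flank: int = 8
    ir_min_boundary_reads: int = 2
    # coexpression
    pcc_threshold: float = 0.5
    pcc_p_threshold: float = 0.05

    def validate(self) -> None:
        for key in ("genome", "annotation", "alignments", "sample_sheet"):
            p = Path(getattr(self, key))
            if not p.exists():
                raise FileNotFoundError(f"{key} path does not exist: {p}")
        if self.deg_mode not in ("fdr", "rawp"):
            raise ValueError(f"invalid deg_mode {self.deg_mode!r}")
        if self.single_exon_threshold <= 0:
            raise ValueError("single_exon_threshold must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    counts: pd.DataFrame | None = None
    matrix: expression.ExpressionMatrix | None = None
    size_factors: pd.Series | None = None
    deg: dict = field(default_factory=dict)  # (sex, contrast) -> DataFrame
    waves: dict = field(default_factory=dict)  # sex -> Series
    candidates: list = field(default_factory=list)  # LncRNACandidate
    candidates_alt_threshold: list = field(default_factory=list)
    lnc_matrix: expression.ExpressionMatrix | None = None
    lnc_deg: dict = field(default_factory=dict)
    lnc_waves: dict = field(default_factory=dict)
    tails: list = field(default_factory=list)
    tails_kept: list = field(default_factory=list)
    pas_clusters: list = field(default_factory=list)
    directions: dict = field(default_factory=dict)  # candidate id -> strand
    junctions: list = field(default_factory=list)
    ase_events: list = field(default_factory=list)
    splicing_stats: pd.DataFrame | None = None
    host_pairs: pd.DataFrame | None = None
    sample_pcc: pd.DataFrame | None = None
    tail_summary: pd.DataFrame | None = None
    tail_anova: dict = field(default_factory=dict)


def _checksum(path: str | Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _hours_contrasts(hours: list[int]) -> list[tuple[int, int]]:
    hs = sorted(hours)
    out = [(hs[i], hs[i + 1]) for i in range(len(hs) - 1)]
    if len(hs) >= 3:
        out.append((hs[0], hs[-1]))
    return out


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all enabled stages; returns in-memory results and writes files."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = core.read_fasta(config.genome)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    annotation = core.read_annotation(config.annotation)
    samples = pd.read_csv(config.sample_sheet, sep="\t", index_col=0)
    log.info("loading alignments from %s", config.alignments)
    records = list(core.read_alignments(config.alignments, unique_only=True))
    log.info("%d unique alignments", len(records))

    result = PipelineResult(config=config)
    hours = sorted(samples["hours"].unique())

    if config.run_expression:
        counts = expression.count_reads(records, annotation, chrom_lengths)
        counts = counts.reindex(columns=samples.index, fill_value=0)
        lengths = pd.Series(
            {g: annotation.exonic_length(g) for g in annotation.genes}
        )
        matrix = expression.ExpressionMatrix(counts, lengths, samples)
        result.counts, result.matrix = counts, matrix
        result.size_factors = expression.deseq_size_factors(counts)
        rpkm_layer = matrix.rpkm_layer()
        counts.to_csv(outdir / "counts.tsv", sep="\t")
        rpkm_layer.to_csv(outdir / "rpkm.tsv", sep="\t")
        matrix.tpm_layer().to_csv(outdir / "tpm.tsv", sep="\t")
        for sex in sorted(samples["sex"].unique()):
            degs = {}
            for lo, hi in _hours_contrasts(hours):
                a = matrix.samples_where(sex=sex, hours=lo)
                b = matrix.samples_where(sex=sex, hours=hi)
                table = expression.deg_table(
                    matrix, a, b,
                    size_factors=result.size_factors,
                    fallback_dispersion=config.fallback_dispersion,
                )
                called = expression.call_degs(table, mode=config.deg_mode)
                degs[(hi, lo)] = called
                called.to_csv(
                    outdir / f"deg_{sex}_{hi}_vs_{lo}.tsv", sep="\t"
                )
            result.deg[sex] = degs
            if len(hours) >= 3:
                waves = expression.assign_waves(
                    degs[(hours[1], hours[0])],
                    degs[(hours[2], hours[1])],
                    degs[(hours[2], hours[0])],
                )
                result.waves[sex] = waves
        if result.waves:
            pd.DataFrame(result.waves).to_csv(outdir / "waves.tsv", sep="\t")

    if config.run_lncrna:
        assembled = lncrna.assemble_candidates(
            records, annotation, chrom_lengths, genome,
            min_depth=config.min_depth, min_junction=config.min_junction,
        )
        cps_model = lncrna.train_cps_from_annotation(
            genome, annotation, seed=config.seed, cutoff=config.cps_cutoff
        )
        result.candidates = lncrna.filter_lncrnas(
            assembled, cps_model, genome,
            single_exon_threshold=config.single_exon_threshold,
        )
        alt = 1000 if config.single_exon_threshold == 500 else 500
        result.candidates_alt_threshold = lncrna.filter_lncrnas(
            assembled, cps_model, genome, single_exon_threshold=alt
        )
        for cand in result.candidates:
            lncrna.classify_locus(cand, annotation)

    if config.run_polya:
        for rec in records:
            tail = polya.detect_tail(
                rec, min_tail=config.min_tail, max_error=config.tail_error_rate
            )
            if tail is not None:
                result.tails.append(tail)
        result.tails_kept = [
            t
            for t in result.tails
            if polya.internal_priming_filter(
                t, genome, config.priming_window, config.priming_min_bases
            )
        ]
        result.pas_clusters = polya.cluster_pas(
            result.tails_kept, max_gap=config.pas_max_gap
        )
        polya.tails_to_frame(result.tails_kept).to_csv(
            outdir / "tails.tsv", sep="\t", index=False
        )
        core.write_bed6(
            [
                core.GenomicInterval(c.chrom, c.start, c.end + 1, c.inferred_strand)
                for c in result.pas_clusters
            ],
            outdir / "pas_clusters.bed",
            names=[f"PAS{i + 1:05d}_{c.kind}" for i, c in
                   enumerate(result.pas_clusters)],
            scores=[c.support for c in result.pas_clusters],
        )
        result.tail_summary, result.tail_anova = polya.mean_tail_length_by_group(
            result.tails_kept, samples
        )
        result.tail_summary.to_csv(outdir / "tail_lengths.tsv", sep="\t")
        if config.run_lncrna and result.candidates:
            for cand in result.candidates:
                strand = polya.assign_direction(
                    cand.transcript.span,
                    result.pas_clusters,
                    max_distance=config.direction_max_distance,
                )
                result.directions[cand.id] = strand
                if strand != ".":
                    cand.strand = strand
                    cand.transcript = core.TranscriptModel(
                        cand.transcript.id,
                        cand.transcript.gene_id,
                        [
                            core.GenomicInterval(e.chrom, e.start, e.end, strand)
                            for e in cand.transcript.exons
                        ],
                        biotype="lncRNA",
                    )
                    # strand knowledge can refine the locus class
                    lncrna.classify_locus(cand, annotation)
            pd.Series(result.directions, name="strand").to_csv(
                outdir / "directions.tsv", sep="\t"
            )

    # lncRNA expression layers need candidates (and their final strands)
    if config.run_lncrna and result.candidates:
        cand_ann = core.Annotation([c.transcript for c in result.candidates])
        lnc_counts = expression.count_reads(records, cand_ann, chrom_lengths)
        lnc_counts = lnc_counts.reindex(columns=samples.index, fill_value=0)
        lnc_lengths = pd.Series({c.id: c.length for c in result.candidates})
        result.lnc_matrix = expression.ExpressionMatrix(
            lnc_counts, lnc_lengths, samples
        )
        lnc_rpkm = result.lnc_matrix.rpkm_layer()
        detected, _ = expression.detect_expressed(
            lnc_rpkm, threshold=config.rpkm_threshold
        )
        summary = lncrna.sex_specificity(
            result.candidates, detected, samples,
            min_samples=config.min_sex_samples,
        )
        summary.to_csv(outdir / "lncrna_summary.tsv", sep="\t", index=False)
        core.write_gff3(
            cand_ann,
            outdir / "lncrna_candidates.gff3",
            extra_attrs={
                c.id: {
                    "locus_class": c.locus_class,
                    "CPS": f"{c.cps:.4f}",
                    "host_gene": c.host_gene or "NA",
                    "sex_specificity": c.sex_specificity,
                }
                for c in result.candidates
            },
        )
        if config.run_expression and len(hours) >= 3:
            for sex in sorted(samples["sex"].unique()):
                degs = {}
                for lo, hi in _hours_contrasts(hours):
                    a = result.lnc_matrix.samples_where(sex=sex, hours=lo)
                    b = result.lnc_matrix.samples_where(sex=sex, hours=hi)
                    table = expression.deg_table(
                        result.lnc_matrix, a, b,
                        size_factors=result.size_factors,
                        fallback_dispersion=config.fallback_dispersion,
                    )
                    degs[(hi, lo)] = expression.call_degs(
                        table, mode=config.deg_mode
                    )
                result.lnc_deg[sex] = degs
                result.lnc_waves[sex] = expression.assign_waves(
                    degs[(hours[1], hours[0])],
                    degs[(hours[2], hours[1])],
                    degs[(hours[2], hours[0])],
                )

    if config.run_splicing:
        result.junctions = splicing.extract_junctions(
            records, min_flank=config.min_flank
        )
        splicing.annotate_junctions(result.junctions, annotation)
        for sj in result.junctions:
            sj.strand = splicing.infer_junction_strand(sj, genome, annotation)
        ir = splicing.detect_intron_retention(
            records, annotation,
            junction_counts={
                sj.key: sj.total_count for sj in result.junctions
            },
            min_flank=config.min_flank,
            min_boundary_reads=config.ir_min_boundary_reads,
        )
        result.ase_events = splicing.classify_ase(
            result.junctions, annotation, genome, ir_events=ir
        )
        eff = splicing.splicing_efficiency(records, min_flank=config.min_flank)
        per_sample_sj = {
            s: sum(1 for sj in result.junctions if sj.read_count.get(s))
            for s in samples.index
        }
        result.splicing_stats = pd.DataFrame(
            {
                "spliced_read_fraction": pd.Series(eff),
                "n_junctions": pd.Series(per_sample_sj),
            }
        ).join(samples)
        result.splicing_stats.to_csv(outdir / "splicing_stats.tsv", sep="\t")
        pd.DataFrame(
            [
                (sj.chrom, sj.donor, sj.acceptor, sj.strand, sj.status,
                 sj.total_count)
                for sj in result.junctions
            ],
            columns=["chrom", "donor", "acceptor", "strand", "status", "count"],
        ).to_csv(outdir / "junctions.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (e.gene, e.type, json.dumps(e.junctions), e.inclusion_count,
                 e.exclusion_count,
                 "" if e.retention_ratio is None else f"{e.retention_ratio:.4f}")
                for e in result.ase_events
            ],
            columns=["gene", "type", "junctions", "inclusion", "exclusion",
                     "retention_ratio"],
        ).to_csv(outdir / "ase_events.tsv", sep="\t", index=False)

    if config.run_coexpression and result.matrix is not None:
        rpkm_layer = result.matrix.rpkm_layer()
        result.sample_pcc = coexpr.sample_similarity(rpkm_layer)
        result.sample_pcc.to_csv(outdir / "sample_pcc.tsv", sep="\t")
        if result.lnc_matrix is not None:
            pairs = [
                (c.id, c.host_gene)
                for c in result.candidates
                if c.locus_class == "intronic" and c.host_gene
            ]
            if pairs:
                combined = np.log2(
                    pd.concat([rpkm_layer, result.lnc_matrix.rpkm_layer()]) + 1
                )
                result.host_pairs = coexpr.host_relation_table(
                    pairs, combined,
                    r_threshold=config.pcc_threshold,
                    p_threshold=config.pcc_p_threshold,
                )
                result.host_pairs.to_csv(
                    outdir / "host_pairs.tsv", sep="\t", index=False
                )

    manifest = {
        "parameters": dataclasses.asdict(config),
        "inputs": {
            k: _checksum(getattr(config, k))
            for k in ("genome", "annotation", "alignments", "sample_sheet")
        },
        "n_unique_alignments": len(records),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


def make_demo(
    seed: int = 0,
    outdir: str | Path = "demo_out",
    sim_config=None,
    pipeline_overrides: dict | None = None,
):
    """Simulate a default dataset, run the full pipeline, score recovery.

    Returns (dataset, result, report); the truth-vs-called report is
    also written to ``<outdir>/recovery_report.json``.
    """
    from .evaluate import recovery_report
    from .simulate import SimulationConfig, simulate_dataset

    outdir = Path(outdir)
    if sim_config is None:
        sim_config = SimulationConfig(seed=seed)
    dataset = simulate_dataset(sim_config, outdir / "data")
    cfg = PipelineConfig(
        genome=str(dataset.paths["genome"]),
        annotation=str(dataset.paths["annotation"]),
        alignments=str(dataset.paths["reads"]),
        sample_sheet=str(dataset.paths["sample_sheet"]),
        outdir=str(outdir / "pipeline"),
        seed=seed,
        **(pipeline_overrides or {}),
    )
    result = run_pipeline(cfg)
    report = recovery_report(dataset, result)
    (outdir / "recovery_report.json").write_text(
        json.dumps(report, indent=1, default=float)
    )
    return dataset, result, report
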