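"""End-to-end orchestration: simulate → call → annotate → enrich → diff.

The library entry point is :func:`run_full`, which executes the whole
dependency graph in memory and optionally writes every artefact (FASTA,
GFF3, per-line SAM/VCF/BED, TSV reports, manifest) to an output directory.
The ``sorgvar`` command-line interface wraps it with stage subcommands.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import alignio, effects, enrich, indelcall, simdata, snpcall, svcall, traitdiff
from .models import CnvCall, GeneModel, IndelCall, PavCall, SnpCall, TruthSet, VariantEffect

log = logging.getLogger(__name__)

EXIT_VALIDATION = 2
EXIT_MISSING_INPUT = 3


@dataclass
class Thresholds:
    """Every caller/report threshold, with the analysis defaults."""

    snp: snpcall.SnpFilterConfig = field(default_factory=snpcall.SnpFilterConfig)
    indel: indelcall.IndelCallConfig = field(default_factory=indelcall.IndelCallConfig)
    cnv: svcall.CnvConfig = field(default_factory=svcall.CnvConfig)
    pav_candidate_min: int = 3
    pav_final_min: int = 6
    pathway_p: float = 0.1
    family_p: float = 0.01
    chisq_min_snps: int = 30
    window: int = 1_000_000
    window_step: int = 100_000
    min_genes_gt: int = 3
    pav_min_reciprocal: float = 0.5

    def asdict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class PipelineResult:
    config: simdata.SimConfig
    thresholds: Thresholds
    genome: dict[str, str]
    genes: list[GeneModel]
    truth: TruthSet
    alignments: dict[str, list]
    snps: dict[str, list[SnpCall]] = field(default_factory=dict)
    indels: dict[str, list[IndelCall]] = field(default_factory=dict)
    pavs: dict[str, list[PavCall]] = field(default_factory=dict)
    cnvs: dict[str, list[CnvCall]] = field(default_factory=dict)
    depth: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    snp_effects: list[VariantEffect] = field(default_factory=list)
    indel_effects: list[VariantEffect] = field(default_factory=list)
    sv_gene_table: pd.DataFrame | None = None
    ratio_table: pd.DataFrame | None = None
    family_report: pd.DataFrame | None = None
    large_effect_families: list = field(default_factory=list)
    pathway_results: list = field(default_factory=list)
    sweet: traitdiff.SweetGeneSet | None = None
    sweet_regions: list = field(default_factory=list)

    @property
    def all_snp_calls(self) -> list[SnpCall]:
        return [c for calls in self.snps.values() for c in calls]


def simulate(config: simdata.SimConfig):
    """Stage 1: genome, gene models, planted truth, per-line alignments."""
    genome0 = simdata.simulate_genome(config)
    genes, genome = simdata.simulate_gene_models(config, genome0)
    truth = simdata.plant_variants(config, genome, genes)
    alignments = simdata.simulate_alignments(config, genome, truth)
    for records in alignments.values():
        alignio.mark_duplicates(records)
    return genome, genes, truth, alignments


def call_line(
    records,
    genome: dict[str, str],
    line: str,
    thresholds: Thresholds,
    insert_model: svcall.InsertModel | None = None,
):
    """Stage 2 for one line: SNPs, indels, PAVs, CNVs and the depth track."""
    snps: list[SnpCall] = []
    depth: dict[str, np.ndarray] = {}
    for chrom in sorted({r.chrom for r in records}):
        pa = alignio.pileup_arrays(records, chrom, len(genome[chrom]))
        snps.extend(
            snpcall.call_snps_from_arrays(pa, chrom, genome[chrom], line, thresholds.snp)
        )
        depth[chrom] = pa.depth.astype(np.float64)
    indels = indelcall.call_indels_from_alignments(
        records, genome, line, thresholds.indel
    )
    pavs = svcall.call_pavs(
        records,
        line,
        insert_model=insert_model,
        candidate_min=thresholds.pav_candidate_min,
        final_min=thresholds.pav_final_min,
    )
    cnvs = svcall.call_cnvs_from_depth(depth, line, thresholds.cnv)
    return snps, indels, pavs, cnvs, depth


def run_full(
    config: simdata.SimConfig,
    thresholds: Thresholds | None = None,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run every stage; optionally write all artefacts under ``outdir``."""
    thr = thresholds or Thresholds()
    log.info("simulating genome and reads (seed=%d)", config.seed)
    genome, genes, truth, alignments = simulate(config)
    result = PipelineResult(
        config=config,
        thresholds=thr,
        genome=genome,
        genes=genes,
        truth=truth,
        alignments=alignments,
    )

    for line, records in alignments.items():
        log.info("calling variants for %s (%d records)", line, len(records))
        snps, indels, pavs, cnvs, depth = call_line(records, genome, line, thr)
        result.snps[line] = snps
        result.indels[line] = indels
        result.pavs[line] = pavs
        result.cnvs[line] = cnvs
        result.depth[line] = depth

    index = effects.GeneIndex(genes)
    result.snp_effects = effects.annotate_snps(result.all_snp_calls, index, genome)
    all_indels = [c for calls in result.indels.values() for c in calls]
    result.indel_effects = effects.annotate_indels(all_indels, index)
    all_pavs = [c for calls in result.pavs.values() for c in calls]
    all_cnvs = [c for calls in result.cnvs.values() for c in calls]
    result.sv_gene_table = effects.annotate_sv_genes(all_pavs, all_cnvs, genes)

    lines = list(config.lines)
    result.ratio_table = enrich.ratio_table(result.snp_effects, lines)
    family_map = {g.gene_id: g.pfam for g in genes}
    result.family_report = enrich.family_chisq_report(
        result.snp_effects, family_map, thr.chisq_min_snps
    )
    large_genes = {
        e.gene_id for e in result.snp_effects if e.is_large_effect and e.gene_id
    }
    result.large_effect_families = enrich.large_effect_family_test(
        large_genes, family_map, [g.gene_id for g in genes], thr.family_p
    )

    design = traitdiff.LineDesign(
        sweet_lines=tuple(config.sweet_lines),
        grain_lines=tuple(config.grain_lines),
    )
    result.sweet = traitdiff.select_sweet_genes(
        result.snp_effects,
        result.indels,
        result.pavs,
        index,
        design,
        min_reciprocal=thr.pav_min_reciprocal,
    )
    pathway_map = {g.gene_id: g.pathways for g in genes}
    result.pathway_results = enrich.pathway_test(
        result.sweet.union, pathway_map, [g.gene_id for g in genes], thr.pathway_p
    )
    gene_by_id = {g.gene_id: g for g in genes}
    mids: dict[str, list[int]] = {}
    for gid in result.sweet.union:
        g = gene_by_id[gid]
        mids.setdefault(g.chrom, []).append(g.midpoint)
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    result.sweet_regions = enrich.sliding_windows(
        mids, chrom_lengths, thr.window, thr.window_step, thr.min_genes_gt
    )

    if outdir is not None:
        write_outputs(result, Path(outdir))
    return result


# ---------------------------------------------------------------------------
# Output bundle + manifest
# ---------------------------------------------------------------------------


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    genome = result.genome
    alignio.write_reference(genome, outdir / "reference.fa")
    alignio.write_gene_models(result.genes, outdir / "genes.gff3")
    cfg.to_yaml(outdir / "sim_config.yaml")
    simdata.write_truth(result.truth, outdir / "truth")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    for line, records in result.alignments.items():
        alignio.write_sam(records, chrom_lengths, outdir / f"{line}.sam")
    for line in cfg.lines:
        alignio.write_snp_vcf(result.snps[line], genome, outdir / f"{line}.snps.vcf", line)
        alignio.write_indel_vcf(
            result.indels[line], genome, outdir / f"{line}.indels.vcf", line
        )
        alignio.write_sv_bed(
            result.pavs[line], result.cnvs[line], outdir / f"{line}.sv.bed"
        )
        for chrom, depth in result.depth[line].items():
            alignio.write_bedgraph(
                depth.astype(np.int64), chrom, outdir / f"{line}.{chrom}.depth.bedgraph"
            )
    result.ratio_table.to_csv(outdir / "ratio_table.tsv", sep="\t")
    result.family_report.to_csv(outdir / "family_chisq.tsv", sep="\t", index=False)
    result.sv_gene_table.to_csv(outdir / "sv_genes.tsv", sep="\t", index=False)
    pd.DataFrame([dataclasses.asdict(r) for r in result.large_effect_families]).to_csv(
        outdir / "large_effect_families.tsv", sep="\t", index=False
    )
    pd.DataFrame([dataclasses.asdict(r) for r in result.pathway_results]).to_csv(
        outdir / "pathway_enrichment.tsv", sep="\t", index=False
    )
    prov = result.sweet.provenance()
    pd.DataFrame(
        [{"gene_id": g, "channels": ",".join(c)} for g, c in prov.items()]
    ).to_csv(outdir / "sweet_genes.tsv", sep="\t", index=False)
    with open(outdir / "sweet_regions.bed", "w") as fh:
        for chrom, s, e, n in result.sweet_regions:
            fh.write(f"{chrom}\t{s}\t{e}\tsweet_region\t{n}\t+\n")
    write_manifest(result, outdir)


def write_manifest(result: PipelineResult, outdir: Path) -> None:
    files = sorted(
        p for p in outdir.rglob("*") if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "seed": result.config.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(result.config).items()
        },
        "thresholds": result.thresholds.asdict(),
        "outputs": {str(p.relative_to(outdir)): _sha256(p) for p in files},
        "counts": {
            "snps": {l: len(v) for l, v in result.snps.items()},
            "indels": {l: len(v) for l, v in result.indels.items()},
            "pavs": {l: len(v) for l, v in result.pavs.items()},
            "cnvs": {l: len(v) for l, v in result.cnvs.items()},
            "sweet_genes": sorted(result.sweet.union) if result.sweet else [],
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------


def _load_config(config_path: str | None, seed: int | None) -> simdata.SimConfig:
    if config_path:
        p = Path(config_path)
        if not p.exists():
            click.echo(f"missing config file: {p}", err=True)
            sys.exit(EXIT_MISSING_INPUT)
        cfg = simdata.SimConfig.from_yaml(p)
    else:
        cfg = simdata.SimConfig()
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
        log.info("seed override: %d", seed)
    return cfg


@click.group()
@click.option("-v", "--verbose", is_flag=True, help="Debug logging.")
def cli(verbose: bool) -> None:
    """Resequencing variation discovery on simulated sorghum-like lines."""
    logging.basicConfig(
        level=logging.DEBUG if verbose else logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


def _common(f):
    f = click.option("--config", "config_path", default=None, help="SimConfig YAML.")(f)
    f = click.option("--seed", type=int, default=None, help="Seed override.")(f)
    f = click.option("--out", "outdir", required=True, help="Output directory.")(f)
    return f


@cli.command("simulate")
@_common
def cmd_simulate(config_path, seed, outdir):
    """Simulate genome, gene models, truth and per-line alignments."""
    try:
        cfg = _load_config(config_path, seed)
        cfg.validate()
    except ValueError as exc:
        click.echo(f"invalid configuration: {exc}", err=True)
        sys.exit(EXIT_VALIDATION)
    genome, genes, truth, alignments = simulate(cfg)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    alignio.write_reference(genome, out / "reference.fa")
    alignio.write_gene_models(genes, out / "genes.gff3")
    cfg.to_yaml(out / "sim_config.yaml")
    simdata.write_truth(truth, out / "truth")
    chrom_lengths = {c: len(s) for c, s in genome.items()}
    for line, records in alignments.items():
        alignio.write_sam(records, chrom_lengths, out / f"{line}.sam")
    click.echo(f"simulated {len(genes)} genes over {sum(chrom_lengths.values())} bases")


def _load_stage_inputs(outdir: str):
    out = Path(outdir)
    ref = out / "reference.fa"
    cfgp = out / "sim_config.yaml"
    if not ref.exists() or not cfgp.exists():
        click.echo(f"missing simulate outputs under {out}", err=True)
        sys.exit(EXIT_MISSING_INPUT)
    cfg = simdata.SimConfig.from_yaml(cfgp)
    genome = alignio.load_reference(ref)
    genes = alignio.load_gene_models(out / "genes.gff3")
    return out, cfg, genome, genes


def _line_records(out: Path, cfg: simdata.SimConfig, line: str):
    sam = out / f"{line}.sam"
    if not sam.exists():
        click.echo(f"missing alignments for line {line}: {sam}", err=True)
        sys.exit(EXIT_MISSING_INPUT)
    records = alignio.load_sam(sam)
    alignio.mark_duplicates(records)
    return records


@cli.command("snp")
@_common
def cmd_snp(config_path, seed, outdir):
    """Call filtered SNPs per line from simulated alignments."""
    out, cfg, genome, _ = _load_stage_inputs(outdir)
    thr = Thresholds()
    for line in cfg.lines:
        records = _line_records(out, cfg, line)
        calls = snpcall.call_snps(records, genome, line, thr.snp)
        alignio.write_snp_vcf(calls, genome, out / f"{line}.snps.vcf", line)
        click.echo(f"{line}: {len(calls)} SNPs")


@cli.command("indel")
@_common
def cmd_indel(config_path, seed, outdir):
    """Call 1-10 bp indels per line."""
    out, cfg, genome, _ = _load_stage_inputs(outdir)
    thr = Thresholds()
    for line in cfg.lines:
        records = _line_records(out, cfg, line)
        calls = indelcall.call_indels_from_alignments(records, genome, line, thr.indel)
        alignio.write_indel_vcf(calls, genome, out / f"{line}.indels.vcf", line)
        click.echo(f"{line}: {len(calls)} indels")


@cli.command("sv")
@_common
def cmd_sv(config_path, seed, outdir):
    """Call PAVs and CNVs per line."""
    out, cfg, genome, _ = _load_stage_inputs(outdir)
    thr = Thresholds()
    for line in cfg.lines:
        records = _line_records(out, cfg, line)
        depth = {
            chrom: alignio.pileup_arrays(records, chrom, len(genome[chrom])).depth.astype(float)
            for chrom in genome
        }
        pavs = svcall.call_pavs(
            records, line, candidate_min=thr.pav_candidate_min, final_min=thr.pav_final_min
        )
        cnvs = svcall.call_cnvs_from_depth(depth, line, thr.cnv)
        alignio.write_sv_bed(pavs, cnvs, out / f"{line}.sv.bed")
        click.echo(f"{line}: {len(pavs)} PAVs, {len(cnvs)} CNVs")


@cli.command("all")
@_common
def cmd_all(config_path, seed, outdir):
    """Run the full pipeline and write every artefact plus a manifest."""
    try:
        cfg = _load_config(config_path, seed)
        cfg.validate()
    except ValueError as exc:
        click.echo(f"invalid configuration: {exc}", err=True)
        sys.exit(EXIT_VALIDATION)
    result = run_full(cfg, outdir=outdir)
    n = {k: sum(len(v) for v in getattr(result, k).values()) for k in ("snps", "indels", "pavs", "cnvs")}
    click.echo(
        f"calls: {n['snps']} SNPs, {n['indels']} indels, {n['pavs']} PAVs, "
        f"{n['cnvs']} CNVs; sweet genes: {sorted(result.sweet.union)}"
    )


@cli.command("annotate")
@_common
def cmd_annotate(config_path, seed, outdir):
    """Annotate called variants against the gene models."""
    out, cfg, genome, genes = _load_stage_inputs(outdir)
    index = effects.GeneIndex(genes)
    all_effects = []
    for line in cfg.lines:
        vcf = out / f"{line}.snps.vcf"
        if not vcf.exists():
            click.echo(f"missing SNP calls for {line}: {vcf}", err=True)
            sys.exit(EXIT_MISSING_INPUT)
        calls = alignio.read_snp_vcf(vcf)
        all_effects.extend(effects.annotate_snps(calls, index, genome))
    table = enrich.ratio_table(all_effects, list(cfg.lines))
    table.to_csv(out / "ratio_table.tsv", sep="\t")
    click.echo(table.to_string())


@cli.command("enrich")
@_common
def cmd_enrich(config_path, seed, outdir):
    """Family chi-square and large-effect enrichment reports."""
    out, cfg, genome, genes = _load_stage_inputs(outdir)
    index = effects.GeneIndex(genes)
    all_effects = []
    for line in cfg.lines:
        calls = alignio.read_snp_vcf(out / f"{line}.snps.vcf")
        all_effects.extend(effects.annotate_snps(calls, index, genome))
    family_map = {g.gene_id: g.pfam for g in genes}
    report = enrich.family_chisq_report(all_effects, family_map)
    report.to_csv(out / "family_chisq.tsv", sep="\t", index=False)
    click.echo(f"{len(report)} families tested")


@cli.command("diff")
@_common
def cmd_diff(config_path, seed, outdir):
    """Sweet-vs-grain differentiating gene selection."""
    out, cfg, genome, genes = _load_stage_inputs(outdir)
    index = effects.GeneIndex(genes)
    all_effects = []
    indels = {}
    pavs = {}
    for line in cfg.lines:
        calls = alignio.read_snp_vcf(out / f"{line}.snps.vcf")
        all_effects.extend(effects.annotate_snps(calls, index, genome))
        indels[line] = alignio.read_indel_vcf(out / f"{line}.indels.vcf")
        p, _ = alignio.read_sv_bed(out / f"{line}.sv.bed")
        pavs[line] = p
    design = traitdiff.LineDesign(tuple(cfg.sweet_lines), tuple(cfg.grain_lines))
    sweet = traitdiff.select_sweet_genes(all_effects, indels, pavs, index, design)
    for gene, channels in sweet.provenance().items():
        click.echo(f"{gene}\t{','.join(channels)}")


if __name__ == "__main__":
    cli()
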