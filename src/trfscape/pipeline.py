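"""End-to-end pipeline: simulate/load -> catalog -> filter -> call ->
classify -> profile, with a run manifest and a summary report."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
from Bio import SeqIO

from . import __version__
from .config import ConfigError, RunConfig
from .expression_profiles import (
    HeatmapMatrix,
    cluster_rows,
    coverage_frame,
    dendrogram_newick,
    expression_trend,
    heatmap_matrix,
    normalization_factors,
    positional_coverage,
    spike_counts_from_unique_reads,
)
from .read_filtering import FilterTally, UniqueRead, filter_stage_libraries
from .synthetic_data import GenomeBundle, SimulationConfig, generate_genome, simulate_reads
from .trf_classification import classify_region, main_region, top_variants, variant_alignment
from .trf_mapping import TRFCallResult, call_trfs
from .trna_catalog import (
    TRNACatalog,
    build_catalog,
    parse_annotation,
    region_map,
    select_eukaryotic,
)

__all__ = ["run_pipeline", "summary_report", "PipelineResult", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineResult:
    config: RunConfig
    bundle: GenomeBundle | None
    mito_catalog: TRNACatalog
    nuclear_catalog: TRNACatalog
    unique_reads: list[UniqueRead]
    all_unique_reads: list[UniqueRead]
    tallies: dict[str, FilterTally]
    calls: TRFCallResult
    anticodon_summary: pd.DataFrame
    factors: pd.Series
    heatmap: HeatmapMatrix
    row_order: list[int]
    trends: pd.DataFrame
    outputs: dict[str, Path] = field(default_factory=dict)


def _read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the whole pipeline for one configuration.

    Deterministic given the config (including the seed): identical runs
    produce byte-identical text outputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages = list(config.stage_names)

    # ---- stage 0: inputs (simulated or loaded) -----------------------
    bundle = None
    try:
        config.validate_inputs()
        if config.simulate is not None:
            sim_kwargs = dict(config.simulate)
            sim_kwargs.setdefault("seed", config.seed)
            sim_kwargs.setdefault("stage_names", tuple(stages))
            sim = SimulationConfig(**sim_kwargs)
            bundle = generate_genome(sim)
            input_dir = outdir / "input"
            input_dir.mkdir(exist_ok=True)
            reads = simulate_reads(bundle, sim, input_dir)
            bundle.write_fasta(input_dir / "mito.fa", input_dir / "nuclear.fa")
            bundle.write_annotation(input_dir / "mito_trnas.tsv", compartment="mitochondrial")
            bundle.write_annotation(input_dir / "nuclear_trnas.tsv", compartment="nuclear")
            bundle.write_spikes(input_dir / "spikes.fa")
            config.fastq = {s: str(p) for s, p in reads.fastq_paths.items()}
            config.mito_fasta = str(input_dir / "mito.fa")
            config.nuclear_fasta = str(input_dir / "nuclear.fa")
            config.mito_annotation = str(input_dir / "mito_trnas.tsv")
            config.nuclear_annotation = str(input_dir / "nuclear_trnas.tsv")
            config.spike_fasta = str(input_dir / "spikes.fa")
    except (ConfigError, OSError) as exc:
        raise PipelineError("inputs", exc) from exc

    # ---- stage 1: catalogs -------------------------------------------
    try:
        mito_contigs = _read_fasta(config.mito_fasta)
        nuclear_contigs = _read_fasta(config.nuclear_fasta)
        mito_genes = parse_annotation(config.mito_annotation)
        nuclear_genes = parse_annotation(config.nuclear_annotation)
        if config.nuclear_annotation_bacterial:
            bac_genes = parse_annotation(config.nuclear_annotation_bacterial)
            nuclear_genes = select_eukaryotic(nuclear_genes, bac_genes)
        mito_catalog = build_catalog(
            mito_genes, mito_contigs, compartment="mitochondrial",
            edge_margin=config.edge_margin,
            default_anticodon_hint=config.anticodon_position,
        )
        nuclear_catalog = build_catalog(
            nuclear_genes, nuclear_contigs, compartment="nuclear",
            edge_margin=config.edge_margin,
            default_anticodon_hint=config.anticodon_position,
        )
    except Exception as exc:
        raise PipelineError("catalog", exc) from exc

    # ---- stage 2: read filtering -------------------------------------
    try:
        unique_reads, all_unique, tallies = filter_stage_libraries(
            config.fastq, stages,
            min_quality=config.min_quality, quality_mode=config.quality_mode,
            min_count=config.min_count,
            per_stage_abundance=config.per_stage_abundance,
            min_length=config.min_length, max_length=config.max_length,
        )
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    # ---- stage 3: tRF calling ----------------------------------------
    try:
        calls = call_trfs(
            unique_reads, mito_catalog, nuclear_catalog,
            stage_order=stages,
            mito_other_genomic_filter=config.mito_other_genomic_filter,
        )
    except Exception as exc:
        raise PipelineError("call", exc) from exc

    # ---- stage 4: region classification ------------------------------
    try:
        matures = {**mito_catalog.matures, **nuclear_catalog.matures}
        rmaps = {
            gid: region_map(m, stem_width=config.stem_width)
            for gid, m in matures.items()
        }
        for rec in calls.records:
            hit = rec.hits[0]
            call = classify_region(
                hit.span, rmaps[hit.gene_id],
                t5=config.anchor_tolerance_5p, t3=config.anchor_tolerance_3p,
                window_slack=config.stem_loop_slack,
            )
            rec.region = call.category
        anticodon_summary = _summarize_anticodons(calls, config)
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    # ---- stage 5: expression profiling -------------------------------
    try:
        spikes = [str(r.seq).upper() for r in SeqIO.parse(config.spike_fasta, "fasta")]
        spike_counts = spike_counts_from_unique_reads(all_unique, spikes, stages)
        factors = normalization_factors(spike_counts)
        groups = _group_by_anticodon(calls)
        variants, labels = [], []
        for key in sorted(groups):
            for v in top_variants(groups[key], config.top_k_variants):
                variants.append(v)
                labels.append(
                    f"{v.isotype}({v.anticodon})|{v.hits[0].gene_id}"
                    f":{v.span[0]}-{v.span[1]}"
                )
        heatmap = heatmap_matrix(variants, factors, stages, labels)
        row_order, tree = cluster_rows(heatmap)
        trend_rows = []
        for v, label in zip(variants, labels):
            normalized = [
                v.counts[i] * factors[s] for i, s in enumerate(stages)
            ]
            trend_rows.append(
                {
                    "variant": label,
                    "sequence": v.sequence,
                    "pooled_count": v.pooled_count,
                    "trend": expression_trend(
                        normalized,
                        rho_threshold=config.trend_rho_threshold,
                        egg_share=config.trend_egg_share,
                    ),
                }
            )
        trends = pd.DataFrame(
            trend_rows, columns=["variant", "sequence", "pooled_count", "trend"]
        )
    except Exception as exc:
        raise PipelineError("profile", exc) from exc

    # ---- stage 6: outputs --------------------------------------------
    try:
        outputs = _write_outputs(
            outdir, config, calls, anticodon_summary, tallies, unique_reads,
            factors, heatmap, row_order, tree, labels, trends, matures, groups,
        )
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    return PipelineResult(
        config=config, bundle=bundle,
        mito_catalog=mito_catalog, nuclear_catalog=nuclear_catalog,
        unique_reads=unique_reads, all_unique_reads=all_unique,
        tallies=tallies, calls=calls, anticodon_summary=anticodon_summary,
        factors=factors, heatmap=heatmap, row_order=row_order, trends=trends,
        outputs=outputs,
    )


def _group_by_anticodon(calls: TRFCallResult) -> dict[tuple[str, str, str], list]:
    groups: dict[tuple[str, str, str], list] = {}
    for rec in calls.records:
        groups.setdefault((rec.compartment, rec.isotype, rec.anticodon), []).append(rec)
    return groups


def _summarize_anticodons(calls: TRFCallResult, config: RunConfig) -> pd.DataFrame:
    """Per-anticodon totals with the dominant-region label, Table-style."""
    groups = _group_by_anticodon(calls)
    rows = []
    for (compartment, isotype, anticodon), recs in sorted(groups.items()):
        category_counts: dict[str, int] = {}
        for rec in recs:
            category_counts[rec.region] = (
                category_counts.get(rec.region, 0) + rec.pooled_count
            )
        rows.append(
            {
                "compartment": compartment,
                "isotype": isotype,
                "anticodon": anticodon,
                "total_reads": sum(r.pooled_count for r in recs),
                "n_unique_reads": len(recs),
                "main_region": main_region(
                    category_counts, min_fraction=config.main_region_fraction
                ),
            }
        )
    cols = [
        "compartment", "isotype", "anticodon", "total_reads",
        "n_unique_reads", "main_region",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values(
            ["compartment", "total_reads", "anticodon"],
            ascending=[True, False, True],
        )
        .reset_index(drop=True)
    )


def summary_report(anticodon_summary: pd.DataFrame) -> str:
    """Two-section text summary (mitochondrial, nuclear) sorted by total
    read count, mirroring the usual deep-sequencing tRF table layout."""
    lines = ["Summary of tRF calls", "====================", ""]
    for compartment in ("mitochondrial", "nuclear"):
        sub = anticodon_summary[anticodon_summary.compartment == compartment]
        total = int(sub.total_reads.sum()) if len(sub) else 0
        lines.append(f"{compartment.capitalize()} tRFs (total reads: {total})")
        lines.append("-" * 50)
        if len(sub) == 0:
            lines.append("(none)")
        else:
            for _, row in sub.iterrows():
                lines.append(
                    f"{row.isotype} ({row.anticodon})".ljust(14)
                    + f"{int(row.total_reads):>10}  {row.main_region}"
                )
        lines.append("")
    return "\n".join(lines)


def _write_outputs(
    outdir: Path,
    config: RunConfig,
    calls: TRFCallResult,
    anticodon_summary: pd.DataFrame,
    tallies: dict[str, FilterTally],
    unique_reads: Sequence[UniqueRead],
    factors: pd.Series,
    heatmap: HeatmapMatrix,
    row_order: list[int],
    tree,
    labels: Sequence[str],
    trends: pd.DataFrame,
    matures: dict,
    groups: dict,
) -> dict[str, Path]:
    stages = list(config.stage_names)
    outputs: dict[str, Path] = {}

    def register(name: str, path: Path) -> Path:
        outputs[name] = path
        return path

    # tRF table
    trf_rows = []
    for rec in calls.records:
        trf_rows.append(
            {
                "sequence": rec.sequence,
                "compartment": rec.compartment,
                "isotype": rec.isotype,
                "anticodon": rec.anticodon,
                "parents": ",".join(rec.parent_ids),
                "span": f"{rec.span[0]}-{rec.span[1]}",
                "cca_masked": int(rec.cca_masked),
                "region": rec.region,
                **{f"reads_{s}": c for s, c in zip(stages, rec.counts)},
                "total_reads": rec.pooled_count,
            }
        )
    trf_cols = [
        "sequence", "compartment", "isotype", "anticodon", "parents", "span",
        "cca_masked", "region",
        *[f"reads_{s}" for s in stages], "total_reads",
    ]
    trf_df = pd.DataFrame(trf_rows, columns=trf_cols)
    trf_df.to_csv(register("trf_table", outdir / "trf_table.tsv"), sep="\t", index=False)

    anticodon_summary.to_csv(
        register("anticodon_summary", outdir / "anticodon_summary.tsv"),
        sep="\t", index=False,
    )

    # unique reads + filter report
    with open(register("unique_reads", outdir / "unique_reads.tsv"), "w") as fh:
        fh.write("sequence\t" + "\t".join(stages) + "\tpooled\n")
        for r in unique_reads:
            fh.write(
                r.sequence + "\t" + "\t".join(map(str, r.counts)) + f"\t{r.pooled_count}\n"
            )
    with open(register("filter_report", outdir / "filter_report.tsv"), "w") as fh:
        fh.write("step\tinput_reads\tpassed_reads\treason\trejected_reads\n")
        for step in ("quality", "abundance", "length"):
            t = tallies[step]
            if not t.rejected:
                fh.write(f"{step}\t{t.input}\t{t.passed}\t-\t0\n")
            for reason in sorted(t.rejected):
                fh.write(
                    f"{step}\t{t.input}\t{t.passed}\t{reason}\t{t.rejected[reason]}\n"
                )
        for reason in sorted(calls.dropped):
            d = calls.dropped[reason]
            fh.write(f"mapping\t-\t-\t{reason}\t{d['reads']}\n")

    # expression outputs
    factors.round(6).to_csv(
        register("factors", outdir / "normalization_factors.tsv"), sep="\t",
        header=["factor"], index_label="stage",
    )
    hm = heatmap.to_frame().round(6)
    hm = hm.iloc[row_order]
    hm.to_csv(register("heatmap", outdir / "heatmap.tsv"), sep="\t", index_label="variant")
    with open(register("dendrogram", outdir / "dendrogram.nwk"), "w") as fh:
        fh.write(dendrogram_newick(tree, list(labels)) + "\n")
    trends.to_csv(register("trends", outdir / "trends.tsv"), sep="\t", index=False)

    cov_dir = outdir / "coverage"
    cov_dir.mkdir(exist_ok=True)
    aln_dir = outdir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for key in sorted(groups):
        recs = groups[key]
        parent_ids = sorted({h.gene_id for r in recs for h in r.hits})
        for gid in parent_ids:
            profiles = positional_coverage(recs, matures[gid], factors, stages)
            coverage_frame(profiles).round(6).to_csv(cov_dir / f"{gid}.tsv", sep="\t")
            rows = variant_alignment(
                [r for r in recs if r.span_on(gid) is not None],
                matures[gid],
                min_count=config.alignment_min_count,
            )
            with open(aln_dir / f"{gid}.txt", "w") as fh:
                fh.write("\n".join(rows) + "\n")
    register("coverage_dir", cov_dir)
    register("alignments_dir", aln_dir)

    if config.make_plots:
        from .plotting import plot_coverage, plot_heatmap

        plot_dir = outdir / "plots"
        plot_dir.mkdir(exist_ok=True)
        plot_heatmap(heatmap, row_order, plot_dir / "heatmap.png")
        for key in sorted(groups):
            recs = groups[key]
            for gid in sorted({h.gene_id for r in recs for h in r.hits}):
                profiles = positional_coverage(recs, matures[gid], factors, stages)
                plot_coverage(profiles, plot_dir / f"{gid}.png")
        register("plots_dir", plot_dir)

    with open(register("report", outdir / "report.txt"), "w") as fh:
        fh.write(summary_report(anticodon_summary))

    manifest = {
        "package": "trfscape",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": stages,
        "n_unique_reads_final": len(unique_reads),
        "n_trf_records": len(calls.records),
        "outputs": {
            k: str(Path(v).relative_to(outdir)) for k, v in sorted(outputs.items())
        },
    }
    with open(register("manifest", outdir / "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outputs
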