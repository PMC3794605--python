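"""End-to-end orchestration: simulate -> T-DMRs -> annotation ->
conservation -> splicing -> integration -> motifs, over a working
directory of stage outputs with stable filenames.

Each stage reads its inputs from disk and writes its outputs back, so
stages can be rerun individually from the CLI; ``run_pipeline`` chains
them and renders a markdown report in which every number is taken from a
stage output.  All randomness flows from the root seed in the simulation
config through named substreams, so a rerun with the same configuration
reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import conservation as cons
from . import integration as integ
from . import io as msio
from . import motifs as mot
from . import splicing as spl
from . import tdmr as tdmr_mod
from .synthetic_data import SimConfig, simulate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis plus the simulation design."""

    sim: SimConfig = field(default_factory=SimConfig)
    probe_p_cutoff: float = 0.005
    tdmr_min_probes: int = 3
    tdmr_max_gap: int = 300
    as_p_cutoff: float = 0.01
    as_si_cutoff: float = math.log2(1.25)
    flank: int = 1000
    upstream_window: int = 4000
    shore_bp: int = 3000
    shelf_bp: int = 4000
    motif_fdr: float = 0.01
    n_background_exons: int = 10000
    n_shuffles: int = 100
    conservation_cutoffs: tuple = (0.1, 0.3, 0.5, 0.7, 0.9)

    def validate(self) -> None:
        for name in ("probe_p_cutoff", "as_p_cutoff", "as_si_cutoff", "motif_fdr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.sim.validate()

    @classmethod
    def from_yaml(cls, path: Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**payload.pop("sim", {}))
        cfg = cls(sim=sim, **payload)
        cfg.validate()
        return cfg

    def to_yaml(self, path: Path) -> None:
        payload = dataclasses.asdict(self)
        payload["conservation_cutoffs"] = list(self.conservation_cutoffs)
        sim = payload["sim"]
        for key in ("exons_per_gene", "exon_length", "intron_length", "intergenic_gap",
                    "cpg_island_length", "tdmr_length", "tissues"):
            sim[key] = list(sim[key])
        sim["planted_motifs"] = [list(m) for m in sim["planted_motifs"]]
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# --- stages ------------------------------------------------------------------

def stage_simulate(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(config.sim)
    msio.write_bundle(ds.bundle, workdir)
    msio.write_probe_table(ds.probe_table, workdir)
    msio.write_expression(ds.expression, workdir / "expression.tsv")
    msio.write_truth(ds.truth, workdir / "truth.json")
    log.info(
        "simulate: %d genes, %d probes, %d planted T-DMRs, %d couplings",
        len(ds.bundle.genes), len(ds.probe_table.probes), len(ds.truth.tdmrs), len(ds.truth.couplings),
    )


def stage_tdmr(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    table = msio.read_probe_table(workdir)
    table = tdmr_mod.normalize(table)
    table = tdmr_mod.filter_background(table)
    m = tdmr_mod.relative_methylation(table)
    calls = tdmr_mod.call_tdmrs(
        m,
        table.probes,
        table.sample_tissue,
        table.tissues,
        p_cutoff=config.probe_p_cutoff,
        min_probes=config.tdmr_min_probes,
        max_gap=config.tdmr_max_gap,
    )
    msio.write_tdmrs_bed(tdmr_mod.tdmrs_to_frame(calls), workdir / "tdmrs.bed")
    retained = table.probes.loc[~table.probes["is_control"], ["probe_id", "chrom", "start", "end", "is_control"]]
    retained.to_csv(workdir / "probes_retained.tsv", sep="\t", index=False)
    log.info("tdmr: %d probes retained, %d T-DMRs called", len(retained), len(calls))


def stage_annotate(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    bundle = msio.read_bundle(workdir)
    tdmrs = msio.read_tdmrs_bed(workdir / "tdmrs.bed")
    probes = pd.read_csv(workdir / "probes_retained.tsv", sep="\t")
    annotation = ann.GenomeAnnotation(
        bundle.genes, upstream_window=config.upstream_window, chroms=bundle.sequences
    )
    tdmr_probe_ids = set(pid for t in tdmrs for pid in t.probe_ids)
    enrich = ann.region_enrichment(tdmr_probe_ids, probes, annotation)
    enrich.to_csv(workdir / "region_enrichment.tsv", sep="\t", index=False)
    islands = ann.build_island_index(bundle.cpg_islands)
    ctx_rows = [
        dataclasses.asdict(
            ann.cpg_context(
                t.chrom, t.start, t.end, islands, t.tdmr_id,
                shore_bp=config.shore_bp, shelf_bp=config.shelf_bp,
            )
        )
        for t in tdmrs
    ]
    pd.DataFrame(ctx_rows, columns=["target_id", "cls", "distance_to_nearest_island"]).to_csv(
        workdir / "tdmr_cpg_context.tsv", sep="\t", index=False
    )
    log.info("annotate: %d T-DMR probes across %d categories", len(tdmr_probe_ids), len(enrich))


def stage_conservation(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    cons_path = workdir / "conservation.bedgraph"
    if not cons_path.exists():
        log.warning("conservation track missing; stage skipped")
        return
    bundle = msio.read_bundle(workdir)
    track = cons.track_from_bundle(bundle.conservation)
    tdmrs = msio.read_tdmrs_bed(workdir / "tdmrs.bed")
    probes = pd.read_csv(workdir / "probes_retained.tsv", sep="\t")
    sets = {
        "tdmrs": [t.interval for t in tdmrs],
        "all_probes": list(zip(probes["chrom"], probes["start"], probes["end"])),
    }
    sets = {k: v for k, v in sets.items() if v}
    fractions, comparisons = cons.conservation_profile(sets, track, config.conservation_cutoffs)
    fractions.to_csv(workdir / "conservation_profile.tsv", sep="\t", index=False)
    comparisons.to_csv(workdir / "conservation_comparisons.tsv", sep="\t", index=False)
    log.info("conservation: %d sets profiled at %d cutoffs", len(sets), len(config.conservation_cutoffs))


def stage_splice(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    expression = msio.read_expression(workdir / "expression.tsv")
    table = msio.read_probe_table(workdir)
    bundle = msio.read_bundle(workdir)
    ni = spl.compute_ni(expression)
    calls = spl.call_as_exons(
        ni, table.sample_tissue, table.tissues,
        p_cutoff=config.as_p_cutoff, si_cutoff=config.as_si_cutoff,
    )
    calls.to_csv(workdir / "as_calls.tsv", sep="\t", index=False, float_format="%.6g")
    alt = spl.alternative_start_genes(bundle.genes, calls)
    (workdir / "alt_start_genes.txt").write_text("\n".join(alt) + ("\n" if alt else ""))
    log.info("splice: %d AS exons, %d alternative-start genes", int(calls["is_AS"].sum()), len(alt))


def stage_integrate(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    bundle = msio.read_bundle(workdir)
    tdmrs = msio.read_tdmrs_bed(workdir / "tdmrs.bed")
    calls = pd.read_csv(workdir / "as_calls.tsv", sep="\t")
    genes_by_id = bundle.genes_by_id()
    universe = set(calls["gene_id"])

    annotation = ann.GenomeAnnotation(
        bundle.genes, upstream_window=config.upstream_window, chroms=bundle.sequences
    )
    tdmr_genes = set()
    for t in tdmrs:
        a = annotation.assign(t.chrom, t.start, t.end, t.tdmr_id)
        if a.gene_id is not None:
            tdmr_genes.add(a.gene_id)
    as_genes = set(calls.loc[calls["is_AS"], "gene_id"])
    overlap = integ.gene_overlap_enrichment(tdmr_genes & universe, as_genes, universe)

    links_1kb = integ.exon_level_association(
        calls, tdmrs, genes_by_id, mode="1kb", flank=config.flank
    )
    links_introns = integ.exon_level_association(
        calls, tdmrs, genes_by_id, mode="flanking_introns"
    )
    regulation = integ.classify_links(links_1kb, tdmrs, calls)
    links_1kb.to_csv(workdir / "links_1kb.tsv", sep="\t", index=False)
    links_introns.to_csv(workdir / "links_flanking.tsv", sep="\t", index=False)
    regulation.to_csv(workdir / "regulation.tsv", sep="\t", index=False)

    def keys(df: pd.DataFrame) -> list:
        return [(r.gene_id, int(r.exon_id.rsplit(":", 1)[1])) for r in df.itertuples()]

    coverage = integ.coverage_comparison(
        keys(calls.loc[calls["is_AS"]]), keys(calls.loc[~calls["is_AS"]]), tdmrs, genes_by_id
    )
    summary = {
        "n_tdmrs": len(tdmrs),
        "n_as_exons": int(calls["is_AS"].sum()),
        "n_expressed_genes": len(universe),
        "n_tdmr_genes": len(tdmr_genes & universe),
        "n_as_genes": len(as_genes),
        "n_overlap_genes": overlap.n_overlap,
        "pct_tdmr_genes_as": overlap.pct_tdmr_genes_as,
        "pct_as_genes_with_tdmr": overlap.pct_as_genes_with_tdmr,
        "overlap_p": overlap.test.p_value,
        "n_links_1kb": len(links_1kb),
        "n_links_flanking": len(links_introns),
        "position_counts": regulation["position"].value_counts().to_dict(),
        "regulation_counts": regulation["regulation"].value_counts().to_dict(),
        "coverage_as_fraction": coverage["as_fraction"],
        "coverage_non_as_fraction": coverage["non_as_fraction"],
        "coverage_p": coverage["test"].p_value if "test" in coverage else None,
    }
    (workdir / "integration_summary.json").write_text(json.dumps(summary, indent=1))
    log.info(
        "integrate: %d/%d T-DMR genes AS (p=%.3g), %d regulation links",
        overlap.n_overlap, len(tdmr_genes & universe), overlap.test.p_value, len(regulation),
    )


def stage_motifs(config: PipelineConfig, workdir: Path) -> None:
    workdir = Path(workdir)
    bundle = msio.read_bundle(workdir)
    tdmrs = msio.read_tdmrs_bed(workdir / "tdmrs.bed")
    regulation = pd.read_csv(workdir / "regulation.tsv", sep="\t")
    genes_by_id = bundle.genes_by_id()
    tdmr_iv = {t.tdmr_id: t.interval for t in tdmrs}
    seed = config.sim.seed

    groups = mot.extract_group_sequences(
        regulation, tdmr_iv, genes_by_id, bundle.sequences, flank=config.flank
    )
    stats_by_group = {}
    for (position, reg), seqs in sorted(groups.items()):
        side_bg = mot.build_background(
            bundle.genes, bundle.sequences,
            n_exons=config.n_background_exons, side=position,
            flank=config.flank, seed=seed,
        )
        stats = mot.count_and_test([g.seq for g in seqs], side_bg, fdr=config.motif_fdr)
        stats_by_group[(position, reg)] = stats
        stats.loc[stats["significant"]].to_csv(
            workdir / f"motif_stats_{position}_{reg}.tsv", sep="\t", index=False, float_format="%.6g"
        )

    up_roles = mot.position_roles(
        stats_by_group.get(("upstream", "positive")), stats_by_group.get(("upstream", "negative"))
    )
    down_roles = mot.position_roles(
        stats_by_group.get(("downstream", "positive")), stats_by_group.get(("downstream", "negative"))
    )
    roles_df, counts = mot.positional_comparison(up_roles, down_roles)
    roles_df.to_csv(workdir / "positional_roles.tsv", sep="\t")
    (workdir / "positional_counts.json").write_text(json.dumps(counts, indent=1))

    significant = sorted(
        set().union(*(set(s.loc[s["significant"], "kmer"]) for s in stats_by_group.values()))
    ) if stats_by_group else []
    results: dict = {"n_significant_union": len(significant)}
    tdmr_seqs = [bytes(bundle.sequences[c][s:e]) for c, s, e in tdmr_iv.values()]
    if significant:
        cpg = mot.cpg_content(significant, tdmr_seqs)
        results["cpg_content"] = {
            k: (v if not isinstance(v, mot.TestResult) else {"z": v.statistic, "p": v.p_value})
            for k, v in cpg.items()
        }
        clusters = mot.cluster_consensus(significant)
        _write_meme_minimal(clusters, workdir / "motif_clusters.meme")
        results["n_clusters"] = len(clusters)
        if config.sim.planted_motifs:
            pwm = mot.pwm_from_consensus(config.sim.planted_motifs[0][0])
            scores, _, shift = mot.pwm_similarity(significant, pwm)
            results["pwm_similarity"] = {
                "median_score": float(scores.median()),
                "shift_p": shift.p_value,
            }
        all_group_seqs = [g for seqs in groups.values() for g in seqs]
        dist = mot.pair_distance_test(
            mot.motif_instances(all_group_seqs, significant),
            n_shuffles=config.n_shuffles, seed=seed,
        )
        results["pair_distance"] = {
            "empty": dist.empty,
            "observed_mean": dist.observed_mean,
            "shuffled_mean": dist.shuffled_mean,
            "p_smaller": dist.p_smaller,
            "n_pairs": dist.n_pairs,
        }
        cons_path = workdir / "conservation.bedgraph"
        if cons_path.exists():
            track = cons.track_from_bundle(bundle.conservation)
            motif_ivs = _significant_instance_intervals(groups, significant)
            if motif_ivs:
                sets = {
                    "motifs": motif_ivs,
                    "tdmrs": list(tdmr_iv.values()),
                }
                fr, _ = cons.conservation_profile(sets, track, config.conservation_cutoffs)
                fr.to_csv(workdir / "motif_conservation.tsv", sep="\t", index=False)
    (workdir / "motif_summary.json").write_text(json.dumps(results, indent=1))
    log.info("motifs: %d groups, %d significant 6mers", len(groups), len(significant))


def _significant_instance_intervals(groups, significant) -> list:
    all_seqs = [g for seqs in groups.values() for g in seqs]
    inst = mot.motif_instances(all_seqs, significant)
    chrom_of = {}
    for g in all_seqs:
        chrom_of[(g.exon_id, g.position)] = g.chrom
    return [
        (chrom_of[row.group], int(row.pos), int(row.pos) + mot.K)
        for row in inst.itertuples()
    ]


def _write_meme_minimal(clusters: Sequence[mot.MotifCluster], path: Path) -> None:
    lines = ["MEME version 4", "", "ALPHABET= ACGT", "", "strands: +", ""]
    for i, cl in enumerate(clusters):
        lines.append(f"MOTIF cluster_{i + 1} {cl.consensus}")
        lines.append(f"letter-probability matrix: alength= 4 w= {cl.pfm.shape[0]} nsites= {len(cl.kmers)}")
        for row in cl.pfm:
            lines.append(" ".join(f"{x:.6f}" for x in row))
        lines.append("")
    Path(path).write_text("\n".join(lines))


STAGES = [
    ("simulate", stage_simulate),
    ("tdmr", stage_tdmr),
    ("annotate", stage_annotate),
    ("conservation", stage_conservation),
    ("splice", stage_splice),
    ("integrate", stage_integrate),
    ("motifs", stage_motifs),
]


def run_pipeline(config: PipelineConfig, workdir: Path) -> Path:
    """Run every stage in order and render ``report.md``.

    A stage failure aborts with the stage name; outputs of completed
    stages stay on disk.
    """
    config.validate()
    workdir = Path(workdir)
    for name, fn in STAGES:
        log.info("stage %s", name)
        try:
            fn(config, workdir)
        except Exception as exc:  # surface the failing stage, keep partial outputs
            raise StageError(name, exc) from exc
    report = render_report(workdir)
    (workdir / "report.md").write_text(report)
    return workdir / "report.md"


def render_report(workdir: Path) -> str:
    """Markdown report assembled purely from stage output files."""
    workdir = Path(workdir)
    parts = ["# methylsplice pipeline report", ""]

    def table(path: Path, title: str) -> None:
        if path.exists():
            df = pd.read_csv(path, sep="\t")
            parts.append(f"## {title}")
            parts.append("")
            parts.append("```")
            parts.append(df.to_string(index=False))
            parts.append("```")
            parts.append("")

    def js(path: Path, title: str) -> None:
        if path.exists():
            parts.append(f"## {title}")
            parts.append("")
            parts.append("```json")
            parts.append(path.read_text().strip())
            parts.append("```")
            parts.append("")

    tdmr_path = workdir / "tdmrs.bed"
    if tdmr_path.exists():
        tdmrs = msio.read_tdmrs_bed(tdmr_path)
        parts += [f"T-DMRs called: **{len(tdmrs)}**", ""]
    table(workdir / "region_enrichment.tsv", "T-DMR probe distribution by genomic category")
    ctx = workdir / "tdmr_cpg_context.tsv"
    if ctx.exists():
        df = pd.read_csv(ctx, sep="\t")
        counts = df["cls"].value_counts().reindex(["island", "shore", "shelf", "open_sea"]).fillna(0)
        parts.append("## T-DMR CpG-island context")
        parts.append("")
        parts.append("```")
        parts.append(counts.to_frame("n").to_string())
        parts.append("```")
        parts.append("")
    table(workdir / "conservation_profile.tsv", "Conserved-nucleotide fractions")
    table(workdir / "motif_conservation.tsv", "Motif vs T-DMR conservation")
    js(workdir / "integration_summary.json", "T-DMR / AS integration")
    js(workdir / "positional_counts.json", "Motif positional-role classes")
    js(workdir / "motif_summary.json", "Motif discovery summary")
    return "\n".join(parts)
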