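"""Readers and writers for the pipeline's on-disk formats.

All coordinates on disk are 0-based, half-open (BED conventions):
FASTA sequences, BED12 gene models with a TSS sidecar for multi-start
genes, BED4 CpG islands, bedGraph conservation, TSV probe tables and
intensity matrices, TSV exon expression, JSON truth sets and BED6+
T-DMRs.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotation import GeneModel
from .conservation import ConservationTrack
from .synthetic_data import GenomeBundle, TruthASExon, TruthCoupling, TruthSet, TruthTDMR
from .tdmr import TDMR, ProbeTable


# --- FASTA ------------------------------------------------------------------

def write_fasta(sequences: Mapping[str, bytes | bytearray], path: Path) -> None:
    records = [
        SeqRecord(Seq(bytes(seq).decode()), id=chrom, description="")
        for chrom, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: Path) -> Dict[str, bytearray]:
    return {rec.id: bytearray(str(rec.seq).encode()) for rec in SeqIO.parse(str(path), "fasta")}


# --- genes: BED12 + TSS sidecar --------------------------------------------

def write_genes_bed12(genes: Sequence[GeneModel], bed_path: Path, tss_path: Path) -> None:
    lines = []
    for g in genes:
        if g.gene_class == "coding" and g.utr5 and g.utr3:
            coding = sorted([g.utr5, g.utr3], key=lambda iv: iv[0])
            thick_start, thick_end = coding[0][1], coding[1][0]
        else:
            thick_start = thick_end = g.start
        sizes = ",".join(str(e - s) for s, e in g.exons)
        offsets = ",".join(str(s - g.start) for s, e in g.exons)
        lines.append(
            "\t".join(
                map(
                    str,
                    [
                        g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                        thick_start, thick_end, 0, len(g.exons), sizes, offsets,
                    ],
                )
            )
        )
    bed_path.write_text("\n".join(lines) + ("\n" if lines else ""))
    with open(tss_path, "w") as fh:
        fh.write("gene_id\ttss_list\n")
        for g in genes:
            if len(g.tss_list) > 1:
                fh.write(f"{g.gene_id}\t{','.join(map(str, g.tss_list))}\n")


def read_genes_bed12(bed_path: Path, tss_path: Path | None = None) -> List[GeneModel]:
    tss_map: Dict[str, list[int]] = {}
    if tss_path is not None and Path(tss_path).exists():
        df = pd.read_csv(tss_path, sep="\t")
        for row in df.itertuples():
            tss_map[row.gene_id] = [int(x) for x in str(row.tss_list).split(",")]
    genes = []
    for line in Path(bed_path).read_text().splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        chrom, start, end, name, _, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        offsets = [int(x) for x in f[11].rstrip(",").split(",")]
        exons = [(start + o, start + o + s) for o, s in zip(offsets, sizes)]
        if thick_start == thick_end:
            gene_class, utr5, utr3 = "ncRNA", None, None
        else:
            gene_class = "coding"
            left = (start, thick_start)
            right = (thick_end, end)
            utr5, utr3 = (left, right) if strand == "+" else (right, left)
        genes.append(
            GeneModel(
                gene_id=name,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
                tss_list=tss_map.get(name, []),
                gene_class=gene_class,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return genes


# --- BED4 islands -----------------------------------------------------------

def write_islands_bed(islands: Sequence[tuple[str, int, int]], path: Path) -> None:
    lines = [f"{c}\t{s}\t{e}\tcpg_{i + 1}" for i, (c, s, e) in enumerate(islands)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_islands_bed(path: Path) -> List[tuple[str, int, int]]:
    out = []
    for line in Path(path).read_text().splitlines():
        if line.strip():
            f = line.split("\t")
            out.append((f[0], int(f[1]), int(f[2])))
    return out


# --- bedGraph conservation --------------------------------------------------

def write_bedgraph(conservation: Mapping[str, np.ndarray], path: Path, decimals: int = 4) -> None:
    with open(path, "w") as fh:
        for chrom in conservation:
            vals = np.round(np.asarray(conservation[chrom], dtype=float), decimals)
            if vals.size == 0:
                continue
            # run-length encode equal consecutive scores
            change = np.flatnonzero(np.diff(vals) != 0) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [vals.size]])
            for s, e in zip(starts, ends):
                if np.isfinite(vals[s]):
                    fh.write(f"{chrom}\t{s}\t{e}\t{vals[s]:.{decimals}f}\n")


def read_bedgraph(path: Path, chrom_lengths: Mapping[str, int]) -> ConservationTrack:
    scores = {c: np.full(n, np.nan) for c, n in chrom_lengths.items()}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith(("track", "#")):
            continue
        chrom, s, e, v = line.split("\t")
        if chrom in scores:
            scores[chrom][int(s) : int(e)] = float(v)
    return ConservationTrack(scores)


# --- probe table & intensities ----------------------------------------------

def write_probe_table(table: ProbeTable, outdir: Path) -> None:
    outdir = Path(outdir)
    table.probes.to_csv(outdir / "probes.tsv", sep="\t", index=False)
    table.input.to_csv(outdir / "input.tsv", sep="\t", float_format="%.6f")
    table.enriched.to_csv(outdir / "enriched.tsv", sep="\t", float_format="%.6f")
    meta = {"tissues": list(table.tissues), "sample_tissue": table.sample_tissue}
    (outdir / "samples.json").write_text(json.dumps(meta, indent=1))


def read_probe_table(outdir: Path) -> ProbeTable:
    outdir = Path(outdir)
    probes = pd.read_csv(outdir / "probes.tsv", sep="\t")
    inp = pd.read_csv(outdir / "input.tsv", sep="\t", index_col=0)
    enr = pd.read_csv(outdir / "enriched.tsv", sep="\t", index_col=0)
    meta = json.loads((outdir / "samples.json").read_text())
    return ProbeTable(
        probes=probes,
        input=inp,
        enriched=enr,
        tissues=tuple(meta["tissues"]),
        sample_tissue=meta["sample_tissue"],
    )


# --- expression --------------------------------------------------------------

def write_expression(expression: pd.DataFrame, path: Path) -> None:
    expression.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_expression(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- truth -------------------------------------------------------------------

def write_truth(truth: TruthSet, path: Path) -> None:
    payload = {
        "tdmrs": [dataclasses.asdict(t) for t in truth.tdmrs],
        "as_exons": [dataclasses.asdict(a) for a in truth.as_exons],
        "couplings": [dataclasses.asdict(c) for c in truth.couplings],
        "planted_motif_sites": [list(s) for s in truth.planted_motif_sites],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path: Path) -> TruthSet:
    payload = json.loads(Path(path).read_text())
    return TruthSet(
        tdmrs=[TruthTDMR(**t) for t in payload["tdmrs"]],
        as_exons=[TruthASExon(**a) for a in payload["as_exons"]],
        couplings=[TruthCoupling(**c) for c in payload["couplings"]],
        planted_motif_sites=[tuple(s) for s in payload["planted_motif_sites"]],
    )


# --- T-DMRs (BED6+) ----------------------------------------------------------

TDMR_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "mean_delta", "n_probes", "direction", "probe_ids",
]


def write_tdmrs_bed(tdmrs_frame: pd.DataFrame, path: Path) -> None:
    tdmrs_frame.to_csv(path, sep="\t", index=False, header=False, float_format="%.6g")


def read_tdmrs_bed(path: Path) -> List[TDMR]:
    text = Path(path).read_text().strip()
    if not text:
        return []
    df = pd.read_csv(path, sep="\t", header=None, names=TDMR_COLUMNS)
    out = []
    for row in df.itertuples():
        out.append(
            TDMR(
                tdmr_id=str(row.name),
                chrom=str(row.chrom),
                start=int(row.start),
                end=int(row.end),
                probe_ids=str(row.probe_ids).split(","),
                direction=str(row.direction),
                mean_delta=float(row.mean_delta),
                min_probe_p=float(10 ** (-float(row.score))),
            )
        )
    return out


# --- bundle convenience -------------------------------------------------------

def write_bundle(bundle: GenomeBundle, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle.sequences, outdir / "genome.fa")
    write_genes_bed12(bundle.genes, outdir / "genes.bed12", outdir / "tss.tsv")
    write_islands_bed(bundle.cpg_islands, outdir / "cpg_islands.bed")
    write_bedgraph(bundle.conservation, outdir / "conservation.bedgraph")


def read_bundle(outdir: Path) -> GenomeBundle:
    outdir = Path(outdir)
    sequences = read_fasta(outdir / "genome.fa")
    genes = read_genes_bed12(outdir / "genes.bed12", outdir / "tss.tsv")
    islands = read_islands_bed(outdir / "cpg_islands.bed")
    lengths = {c: len(s) for c, s in sequences.items()}
    cons_path = outdir / "conservation.bedgraph"
    conservation = (
        {c: a for c, a in read_bedgraph(cons_path, lengths).scores.items()}
        if cons_path.exists()
        else {c: np.full(n, np.nan) for c, n in lengths.items()}
    )
    return GenomeBundle(
        sequences=sequences, genes=genes, cpg_islands=islands, conservation=conservation
    )
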