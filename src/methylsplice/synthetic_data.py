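"""Synthetic genomes, tiling arrays and exon expression with planted truth.

The generator emulates the study design the pipeline analyses: a small
multi-chromosome genome with protein-coding and non-coding genes, CpG
islands, a per-base conservation track, a dense 50-bp tiling array with
two channels (input and methylation-enriched) over two tissues in
triplicate, and an exon-level expression matrix.  Truth is planted at
three levels -- differentially methylated regions, alternatively spliced
exons coupled to them under positive or negative regulation, and 6mer
motifs written into T-DMR sequence at a chosen enrichment fold -- and
recorded in a machine-readable truth set so every downstream caller can be
scored against it.

All randomness flows from one root seed through named substreams, so a
fixed configuration reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .motifs import K as KMER_K
from .motifs import count_kmers, kmer_to_index, revcomp
from .tdmr import ProbeTable

BASE_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream tags hashed together with the root seed
_STREAMS = {"genome": 0, "truth": 1, "methylation": 2, "expression": 3, "motifs": 4}


class ConfigError(ValueError):
    pass


class SizingError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for one synthetic data set.

    Array geometry follows the dense-tiling design the pipeline targets
    (50 bp probes, overlapping 40 bp spacing, non-genomic control probes,
    three replicates per tissue).  ``planted_delta`` is the between-tissue
    difference in relative methylation (log2 enriched/input) inside a
    planted T-DMR; ``as_effect`` is the planted splicing-index magnitude of
    a coupled exon; ``coupling_table`` gives the fraction of planted T-DMRs
    coupled to an AS exon under positive / negative regulation (the rest
    are uncoupled).
    """

    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 90
    n_ncrna: int = 6
    exons_per_gene: Tuple[int, int] = (4, 8)
    exon_length: Tuple[int, int] = (150, 240)
    intron_length: Tuple[int, int] = (1200, 2800)
    utr5_length: int = 60
    utr3_length: int = 80
    multi_tss_fraction: float = 0.2
    intergenic_gap: Tuple[int, int] = (6000, 9000)
    n_cpg_islands_per_chrom: int = 8
    cpg_island_length: Tuple[int, int] = (600, 1200)
    conservation_block: int = 20
    probe_length: int = 50
    probe_spacing: int = 40
    n_control_probes: int = 1000
    n_replicates_per_tissue: int = 3
    tissues: Tuple[str, str] = ("tissueA", "tissueB")
    base_input: float = 10.0
    base_methylation: float = 1.0
    control_level_offset: float = -5.0
    control_sd: float = 0.4
    dead_probe_fraction: float = 0.005
    methyl_noise_sd: float = 0.1
    planted_tdmr_count: int = 100
    planted_delta: float = 0.3
    tdmr_length: Tuple[int, int] = (300, 900)
    coupling_table: Dict[str, float] = field(
        default_factory=lambda: {"positive": 0.35, "negative": 0.35, "none": 0.30}
    )
    coupling_positions: Dict[str, float] = field(
        default_factory=lambda: {"upstream": 0.4, "within_exon": 0.2, "downstream": 0.4}
    )
    planted_motifs: List[Tuple[str, str, float]] = field(default_factory=list)
    as_effect: float = 0.8
    expr_noise_sd: float = 0.15
    gene_expr_mean: float = 8.0
    gene_expr_sd: float = 1.0
    exon_offset_sd: float = 0.3
    flank: int = 1000

    def validate(self) -> None:
        if self.probe_length <= 0 or self.probe_spacing <= 0:
            raise ConfigError("probe geometry must be positive")
        if self.planted_delta <= 0:
            raise ConfigError("planted_delta must be > 0")
        bad = set(self.coupling_table) - {"positive", "negative", "none"}
        if bad:
            raise ConfigError(f"unknown coupling labels: {sorted(bad)}")
        if sum(self.coupling_table.values()) > 1 + 1e-9:
            raise ConfigError("coupling_table fractions must sum to <= 1")
        badpos = set(self.coupling_positions) - {"upstream", "within_exon", "downstream"}
        if badpos:
            raise ConfigError(f"unknown coupling positions: {sorted(badpos)}")
        for kmer, group, fold in self.planted_motifs:
            _validate_motif(kmer, group, fold)
        if self.n_replicates_per_tissue < 2:
            raise ConfigError("need >= 2 replicates per tissue")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), _STREAMS[stream]])


def _validate_motif(kmer: str, group: str, fold: float) -> None:
    if len(kmer) != KMER_K or set(kmer) - set("ACGT"):
        raise ConfigError(f"planted motif must be a 6-letter ACGT string: {kmer!r}")
    pos, _, reg = group.partition("_")
    if pos not in ("upstream", "downstream") or reg not in ("positive", "negative"):
        raise ConfigError(f"motif group must be <position>_<regulation>, got {group!r}")
    if fold < 1:
        raise ConfigError(f"motif enrichment fold must be >= 1, got {fold}")


@dataclass
class TruthTDMR:
    tdmr_id: str
    chrom: str
    start: int
    end: int
    direction: str  # hypermethylated tissue


@dataclass
class TruthCoupling:
    tdmr_id: str
    gene_id: str
    exon_index: int
    regulation: str  # positive | negative
    position: str    # upstream | within_exon | downstream (gene-sense)


@dataclass
class TruthASExon:
    gene_id: str
    exon_index: int
    si_sign: int  # +1: higher inclusion in tissues[0]

    @property
    def exon_id(self) -> str:
        return f"{self.gene_id}:{self.exon_index}"


@dataclass
class TruthSet:
    tdmrs: List[TruthTDMR]
    as_exons: List[TruthASExon]
    couplings: List[TruthCoupling]
    planted_motif_sites: List[Tuple[str, str, int]] = field(default_factory=list)


@dataclass
class GenomeBundle:
    """Sequences, gene models, CpG islands and conservation for one genome."""

    sequences: Dict[str, bytearray]
    genes: List[GeneModel]
    cpg_islands: List[Tuple[str, int, int]]
    conservation: Dict[str, np.ndarray]

    @property
    def chrom_lengths(self) -> Dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def genes_by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}


# --- genome ----------------------------------------------------------------

def generate_genome(config: SimConfig) -> GenomeBundle:
    """Generate sequences, gene annotation, CpG islands and conservation.

    Genes are laid out non-overlapping with wide intergenic gaps, strands
    alternating at random; coding genes carry 5'/3'UTRs inside their
    terminal exons, a subset gets a second annotated start site, and
    non-coding genes follow the same exon structure without UTRs.  CpG
    islands are GC/CpG-rich rewrites of the background sequence, spaced so
    island, shore, shelf and open-sea territory all exist.  Conservation is
    a blockwise score in [0, 1].
    """
    config.validate()
    rng = config.rng("genome")
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    sequences = {
        c: _random_sequence(rng, config.chrom_length, p=(0.29, 0.21, 0.21, 0.29)) for c in chroms
    }
    islands = _place_islands(rng, config, chroms, sequences)
    genes = _place_genes(rng, config, chroms)
    conservation = {}
    for c in chroms:
        n_blocks = -(-config.chrom_length // config.conservation_block)
        block_scores = rng.beta(1.2, 3.5, size=n_blocks).astype(np.float32)
        conservation[c] = np.repeat(block_scores, config.conservation_block)[: config.chrom_length]
    return GenomeBundle(sequences=sequences, genes=genes, cpg_islands=islands, conservation=conservation)


def _random_sequence(rng: np.random.Generator, length: int, p: tuple) -> bytearray:
    codes = rng.choice(4, size=length, p=p).astype(np.uint8)
    return bytearray(BASE_LOOKUP[codes].tobytes())


def _place_islands(rng, config: SimConfig, chroms, sequences) -> List[Tuple[str, int, int]]:
    islands = []
    min_sep = 25_000
    for c in chroms:
        starts: list[int] = []
        attempts = 0
        while len(starts) < config.n_cpg_islands_per_chrom and attempts < 10_000:
            attempts += 1
            pos = int(rng.integers(5000, config.chrom_length - 5000))
            if all(abs(pos - s) >= min_sep for s in starts):
                starts.append(pos)
        for s in sorted(starts):
            length = int(rng.integers(*config.cpg_island_length))
            e = min(s + length, config.chrom_length)
            # GC- and CpG-rich rewrite: alternate CG dinucleotides with GC-rich filler
            piece = _random_sequence(rng, e - s, p=(0.13, 0.37, 0.37, 0.13))
            cg_positions = rng.choice(max(1, len(piece) - 2), size=max(1, len(piece) // 12), replace=False)
            for cp in cg_positions:
                piece[cp : cp + 2] = b"CG"
            sequences[c][s:e] = piece
            islands.append((c, s, e))
    return islands


def _place_genes(rng, config: SimConfig, chroms) -> List[GeneModel]:
    genes: List[GeneModel] = []
    total = config.n_genes + config.n_ncrna
    chrom_iter = iter(chroms)
    chrom = next(chrom_iter)
    cursor = 0
    for gi in range(total):
        is_ncrna = gi >= config.n_genes
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_exons)
        intron_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=n_exons - 1)
        gap = int(rng.integers(*config.intergenic_gap))
        strand = "+" if rng.random() < 0.5 else "-"
        length = int(exon_lens.sum() + intron_lens.sum())
        start = cursor + gap
        while start + length + 5000 > config.chrom_length:
            try:
                chrom = next(chrom_iter)
            except StopIteration:
                raise SizingError(
                    f"chromosomes too short for {total} genes "
                    f"(placed {len(genes)}; increase chrom_length or n_chromosomes)"
                )
            cursor = 0
            start = cursor + gap
        exons = []
        pos = start
        for i in range(n_exons):
            exons.append((pos, pos + int(exon_lens[i])))
            pos += int(exon_lens[i])
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        end = pos
        gene_id = ("nc" if is_ncrna else "g") + f"{gi + 1:04d}"
        tss_list = [start if strand == "+" else end]
        if not is_ncrna and n_exons >= 4 and rng.random() < config.multi_tss_fraction:
            # second annotated start at the 5' end of the third gene-sense exon
            if strand == "+":
                tss_list.append(exons[2][0])
            else:
                tss_list.append(exons[-3][1])
        utr5 = utr3 = None
        if not is_ncrna:
            if strand == "+":
                utr5 = (exons[0][0], exons[0][0] + config.utr5_length)
                utr3 = (exons[-1][1] - config.utr3_length, exons[-1][1])
            else:
                utr5 = (exons[-1][1] - config.utr5_length, exons[-1][1])
                utr3 = (exons[0][0], exons[0][0] + config.utr3_length)
        genes.append(
            GeneModel(
                gene_id=gene_id,
                chrom=chrom,
                start=start,
                end=end,
                strand=strand,
                exons=exons,
                tss_list=sorted(tss_list),
                gene_class="ncRNA" if is_ncrna else "coding",
                utr5=utr5,
                utr3=utr3,
            )
        )
        cursor = end
    return genes


# --- truth -----------------------------------------------------------------

def plant_truth(bundle: GenomeBundle, config: SimConfig) -> TruthSet:
    """Choose planted T-DMRs, couple a configured fraction of them to AS
    exons, and elevate conservation within T-DMRs.

    Coupled T-DMRs are placed relative to an internal exon of a coding
    gene: overlapping it (within_exon) or in the flanking intron within
    the 1 kb gene-sense window (upstream/downstream).  Uncoupled T-DMRs go
    to random territory away from coupled exons.  Directions
    (hypermethylated tissue) are drawn at random; the coupled exon's
    inclusion tissue follows from the regulation label.
    """
    config.validate()
    rng = config.rng("truth")
    genes_by_id = bundle.genes_by_id()
    candidates = [
        (g.gene_id, i)
        for g in bundle.genes
        if g.gene_class == "coding" and g.n_exons >= 3
        for i in range(1, g.n_exons - 1)
    ]
    rng.shuffle(candidates)

    n = config.planted_tdmr_count
    n_pos = int(round(config.coupling_table.get("positive", 0.0) * n))
    n_neg = int(round(config.coupling_table.get("negative", 0.0) * n))
    labels = ["positive"] * n_pos + ["negative"] * n_neg + ["none"] * (n - n_pos - n_neg)
    pos_names = list(config.coupling_positions)
    pos_weights = np.array([config.coupling_positions[k] for k in pos_names], dtype=float)
    pos_weights = pos_weights / pos_weights.sum()

    used: Dict[str, list] = {c: [] for c in bundle.sequences}
    coupled_exons: set = set()
    tdmrs: List[TruthTDMR] = []
    as_exons: List[TruthASExon] = []
    couplings: List[TruthCoupling] = []
    cand_iter = iter(candidates)

    for label in labels:
        tdmr_id = f"D{len(tdmrs) + 1:04d}"
        direction = config.tissues[int(rng.integers(2))]
        if label in ("positive", "negative"):
            placed = None
            for gene_id, ei in cand_iter:
                if (gene_id, ei) in coupled_exons or any(
                    (g, e) in coupled_exons for g, e in [(gene_id, ei - 1), (gene_id, ei + 1)]
                ):
                    continue
                gene = genes_by_id[gene_id]
                position = str(rng.choice(pos_names, p=pos_weights))
                iv = _coupled_interval(rng, gene, ei, position, config)
                if iv is not None and _free(used[gene.chrom], iv):
                    placed = (gene, ei, position, iv)
                    break
            if placed is None:
                raise SizingError("ran out of candidate exons for coupled T-DMRs")
            gene, ei, position, (s, e) = placed
            coupled_exons.add((gene.gene_id, ei))
            used[gene.chrom].append((s, e))
            tdmrs.append(TruthTDMR(tdmr_id, gene.chrom, s, e, direction))
            included = direction if label == "positive" else _other(config.tissues, direction)
            si_sign = 1 if included == config.tissues[0] else -1
            as_exons.append(TruthASExon(gene.gene_id, ei, si_sign))
            couplings.append(TruthCoupling(tdmr_id, gene.gene_id, ei, label, position))
        else:
            for _ in range(10_000):
                chrom = f"chr{int(rng.integers(len(bundle.sequences))) + 1}"
                length = int(rng.integers(*config.tdmr_length))
                s = int(rng.integers(0, len(bundle.sequences[chrom]) - length))
                iv = (s, s + length)
                if _free(used[chrom], iv, pad=2000):
                    used[chrom].append(iv)
                    tdmrs.append(TruthTDMR(tdmr_id, chrom, iv[0], iv[1], direction))
                    break
            else:
                raise SizingError("could not place an uncoupled T-DMR")

    for t in tdmrs:
        cons = bundle.conservation[t.chrom]
        block = config.conservation_block
        lo, hi = t.start // block * block, -(-t.end // block) * block
        n_blocks = (min(hi, len(cons)) - lo) // block
        cons[lo : lo + n_blocks * block] = np.repeat(
            rng.beta(6.0, 2.0, size=n_blocks).astype(np.float32), block
        )
    validate_truth(bundle, TruthSet(tdmrs, as_exons, couplings))
    return TruthSet(tdmrs, as_exons, couplings)


def _other(tissues: Tuple[str, str], t: str) -> str:
    return tissues[1] if t == tissues[0] else tissues[0]


def _free(intervals, iv, pad: int = 500) -> bool:
    return all(iv[1] + pad <= s or e + pad <= iv[0] for s, e in intervals)


def _coupled_interval(rng, gene: GeneModel, exon_index: int, position: str, config: SimConfig):
    s, e = gene.exons[exon_index]
    if position == "within_exon":
        return (s, e)
    gap = 20
    max_len = min(config.tdmr_length[1], config.flank - gap - 20)
    min_len = min(config.tdmr_length[0], max_len)
    length = int(rng.integers(min_len, max_len + 1))
    before = (position == "upstream") == (gene.strand == "+")
    if before:
        iv = (s - gap - length, s - gap)
        prev_end = gene.exons[exon_index - 1][1]
        if iv[0] < prev_end + 10:
            return None
    else:
        iv = (e + gap, e + gap + length)
        next_start = gene.exons[exon_index + 1][0]
        if iv[1] > next_start - 10:
            return None
    return iv


def validate_truth(bundle: GenomeBundle, truth: TruthSet) -> None:
    """Referential integrity: couplings point at existing T-DMRs and exons,
    intervals stay within chromosome bounds."""
    lengths = bundle.chrom_lengths
    tdmr_ids = {t.tdmr_id for t in truth.tdmrs}
    genes_by_id = bundle.genes_by_id()
    for t in truth.tdmrs:
        if not (0 <= t.start < t.end <= lengths[t.chrom]):
            raise ValueError(f"T-DMR {t.tdmr_id} outside chromosome bounds")
    for c in truth.couplings:
        if c.tdmr_id not in tdmr_ids:
            raise ValueError(f"coupling references unknown T-DMR {c.tdmr_id}")
        gene = genes_by_id.get(c.gene_id)
        if gene is None or not 0 <= c.exon_index < gene.n_exons:
            raise ValueError(f"coupling references unknown exon {c.gene_id}:{c.exon_index}")
        if c.regulation not in ("positive", "negative"):
            raise ConfigError(f"unknown regulation label {c.regulation!r}")
    for a in truth.as_exons:
        gene = genes_by_id.get(a.gene_id)
        if gene is None or not 0 <= a.exon_index < gene.n_exons:
            raise ValueError(f"truth AS exon {a.gene_id}:{a.exon_index} not in annotation")
    for kmer, chrom, pos in truth.planted_motif_sites:
        if not 0 <= pos <= lengths[chrom] - KMER_K:
            raise ValueError("planted motif site outside chromosome bounds")


# --- methylation array -----------------------------------------------------

def simulate_methylation(bundle: GenomeBundle, truth: TruthSet, config: SimConfig) -> ProbeTable:
    """Tiling-array intensities with the planted methylation differences.

    Probes tile every chromosome at ``probe_spacing``; per sample the input
    channel sits at ``base_input`` and the enriched channel at input plus
    ``base_methylation``, plus/minus half the planted delta for probes
    inside a T-DMR (so the between-tissue difference in M equals
    ``planted_delta`` exactly in the noise-free limit).  Gaussian noise of
    ``methyl_noise_sd`` is added independently per channel.  Non-genomic
    control probes sit at background level; a small fraction of genomic
    probes is "dead" (background-level input) and should be removed by
    background filtering.
    """
    config.validate()
    if config.planted_delta <= 0:
        raise ConfigError("planted_delta must be > 0")
    rng = config.rng("methylation")
    rows = []
    for chrom, seq in bundle.sequences.items():
        starts = np.arange(0, len(seq) - config.probe_length + 1, config.probe_spacing)
        for s in starts:
            rows.append((chrom, int(s), int(s) + config.probe_length, False))
    for _ in range(config.n_control_probes):
        rows.append(("*", -1, -1, True))
    probes = pd.DataFrame(rows, columns=["chrom", "start", "end", "is_control"])
    probes.insert(0, "probe_id", [f"p{i + 1:06d}" for i in range(len(probes))])

    samples = [f"{t}_{r + 1}" for t in config.tissues for r in range(config.n_replicates_per_tissue)]
    sample_tissue = {s: s.rsplit("_", 1)[0] for s in samples}
    n_probes = len(probes)
    genomic = ~probes["is_control"].to_numpy()

    # probe-level tissue effect from planted T-DMRs
    effect = np.zeros(n_probes)  # +delta/2 toward tissues[0] when hyper there
    by_chrom: Dict[str, list] = {}
    for t in truth.tdmrs:
        by_chrom.setdefault(t.chrom, []).append(t)
    chrom_arr = probes["chrom"].to_numpy()
    start_arr = probes["start"].to_numpy()
    end_arr = probes["end"].to_numpy()
    for chrom, tlist in by_chrom.items():
        mask_c = (chrom_arr == chrom) & genomic
        for t in tlist:
            inside = mask_c & (start_arr < t.end) & (end_arr > t.start)
            sign = 1.0 if t.direction == config.tissues[0] else -1.0
            effect[inside] = sign * config.planted_delta / 2.0

    dead = genomic & (rng.random(n_probes) < config.dead_probe_fraction)
    control_center = config.base_input + config.control_level_offset

    inp = np.empty((n_probes, len(samples)))
    enr = np.empty((n_probes, len(samples)))
    for j, s in enumerate(samples):
        tissue_sign = 1.0 if sample_tissue[s] == config.tissues[0] else -1.0
        inp[:, j] = config.base_input + rng.normal(0.0, config.methyl_noise_sd, n_probes)
        enr[:, j] = (
            config.base_input
            + config.base_methylation
            + tissue_sign * effect
            + rng.normal(0.0, config.methyl_noise_sd, n_probes)
        )
        ctrl = probes["is_control"].to_numpy() | dead
        n_ctrl = int(ctrl.sum())
        inp[ctrl, j] = control_center + rng.normal(0.0, config.control_sd, n_ctrl)
        enr[ctrl, j] = control_center + rng.normal(0.0, config.control_sd, n_ctrl)
        inp[dead, j] -= 2.0  # dead probes fall below the control background

    idx = pd.Index(probes["probe_id"])
    return ProbeTable(
        probes=probes,
        input=pd.DataFrame(inp, index=idx, columns=samples),
        enriched=pd.DataFrame(enr, index=idx, columns=samples),
        tissues=config.tissues,
        sample_tissue=sample_tissue,
    )


# --- exon expression -------------------------------------------------------

def simulate_exon_expression(bundle: GenomeBundle, truth: TruthSet, config: SimConfig) -> pd.DataFrame:
    """Exon-level log2 intensities per tissue replicate (coding genes).

    Every exon sits at its gene's baseline plus a fixed exon offset; a
    truth AS exon additionally gets a symmetric between-tissue shift scaled
    by n_exons/(n_exons - 1) so its expected splicing index is exactly
    ``as_effect`` after the within-gene normalization (which subtracts the
    gene-mean shift).  Returns a frame with gene_id, exon_id and one column
    per sample.
    """
    config.validate()
    rng = config.rng("expression")
    samples = [f"{t}_{r + 1}" for t in config.tissues for r in range(config.n_replicates_per_tissue)]
    as_map = {(a.gene_id, a.exon_index): a.si_sign for a in truth.as_exons}
    rows = []
    values = []
    for gene in bundle.genes:
        if gene.gene_class != "coding":
            continue
        base = rng.normal(config.gene_expr_mean, config.gene_expr_sd)
        offsets = rng.normal(0.0, config.exon_offset_sd, gene.n_exons)
        noise = rng.normal(0.0, config.expr_noise_sd, (gene.n_exons, len(samples)))
        for i in range(gene.n_exons):
            level = np.full(len(samples), base + offsets[i]) + noise[i]
            sign = as_map.get((gene.gene_id, i))
            if sign is not None and gene.n_exons > 1:
                shift = sign * config.as_effect * gene.n_exons / (gene.n_exons - 1) / 2.0
                for j, s in enumerate(samples):
                    level[j] += shift if s.rsplit("_", 1)[0] == config.tissues[0] else -shift
            rows.append((gene.gene_id, gene.exon_id(i)))
            values.append(level)
    df = pd.DataFrame(values, columns=samples)
    df.insert(0, "exon_id", [r[1] for r in rows])
    df.insert(0, "gene_id", [r[0] for r in rows])
    return df


# --- motif planting --------------------------------------------------------

def plant_motifs(bundle: GenomeBundle, truth: TruthSet, config: SimConfig) -> GenomeBundle:
    """Write planted 6mers into coupled T-DMR sequence at an enrichment fold.

    For each (kmer, group, fold) the target regions are the T-DMR pieces
    inside the 1 kb gene-sense flank of coupled exons whose position and
    regulation match the group.  The number of insertions per region is
    Poisson with mean (fold - 1) x genome background frequency x windows,
    so the expected occurrence frequency in the group is fold x background
    while fold = 1 plants nothing.  Motifs are written in gene-sense
    orientation (reverse complement on minus-strand genes) at
    non-overlapping positions; sites are recorded in the truth set.
    """
    config.validate()
    rng = config.rng("motifs")
    if not config.planted_motifs:
        return bundle
    counts, total = count_kmers(bundle.sequences.values())
    genes_by_id = bundle.genes_by_id()
    tdmr_by_id = {t.tdmr_id: t for t in truth.tdmrs}
    from .motifs import flank_window  # late import to keep module init light

    for kmer, group, fold in config.planted_motifs:
        _validate_motif(kmer, group, fold)
        position, _, regulation = group.partition("_")
        f_bg = counts[kmer_to_index(kmer)] / total if total else 0.0
        regions = []
        for c in truth.couplings:
            if c.position != position or c.regulation != regulation:
                continue
            gene = genes_by_id[c.gene_id]
            t = tdmr_by_id[c.tdmr_id]
            win = flank_window(gene, c.exon_index, position, config.flank, len(bundle.sequences[t.chrom]))
            s, e = max(t.start, win[0]), min(t.end, win[1])
            if e - s >= KMER_K:
                regions.append((t.chrom, s, e, gene.strand))
        written = kmer.encode()
        for chrom, s, e, strand in regions:
            windows = e - s - KMER_K + 1
            lam = max(0.0, (fold - 1.0)) * f_bg * windows
            n_insert = int(rng.poisson(lam))
            taken: list[int] = []
            tries = 0
            while len(taken) < n_insert and tries < 50 * max(1, n_insert):
                tries += 1
                pos = int(rng.integers(s, e - KMER_K + 1))
                if all(abs(pos - q) >= KMER_K for q in taken):
                    taken.append(pos)
            for pos in taken:
                payload = written if strand == "+" else revcomp(written)
                bundle.sequences[chrom][pos : pos + KMER_K] = payload
                truth.planted_motif_sites.append((kmer, chrom, pos))
    return bundle


# --- convenience -----------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SimConfig
    bundle: GenomeBundle
    truth: TruthSet
    probe_table: ProbeTable
    expression: pd.DataFrame


def simulate_dataset(config: SimConfig) -> SyntheticDataset:
    """Full synthetic data set: genome, truth, motifs, array, expression."""
    bundle = generate_genome(config)
    truth = plant_truth(bundle, config)
    plant_motifs(bundle, truth, config)
    probe_table = simulate_methylation(bundle, truth, config)
    expression = simulate_exon_expression(bundle, truth, config)
    return SyntheticDataset(config, bundle, truth, probe_table, expression)
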