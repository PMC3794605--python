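"""Gene models, genomic-category assignment and enrichment.

Coordinates are 0-based, half-open throughout.  A target interval (probe or
T-DMR) gets exactly one genomic category via a fixed precedence order, so
category percentages over any probe set always sum to 100%:

    5utr > 3utr > exon > intron > upstream > intergenic

``upstream`` is measured strand-aware from the gene's outermost transcription
start site, 4 kb by default.  CpG-island context follows the island / shore
(<= 3 kb) / shelf (<= 4 kb) / open-sea convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Set

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .stats import TestResult, bonferroni, hypergeom_enrichment

CATEGORIES = ("5utr", "3utr", "exon", "intron", "upstream", "intergenic")
_PRECEDENCE = {c: i for i, c in enumerate(CATEGORIES)}

CPG_SHORE_BP = 3000
CPG_SHELF_BP = 4000
UPSTREAM_WINDOW_BP = 4000


@dataclass
class GeneModel:
    """A gene with exon structure, UTRs and one or more start sites.

    ``exons`` are half-open intervals in genomic order; ``tss_list`` holds
    the genomic boundary coordinate of each annotated start (for a minus
    strand gene the TSS is the interval's end coordinate).
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]]
    tss_list: list[int] = field(default_factory=list)
    gene_class: str = "coding"
    utr5: Optional[tuple[int, int]] = None
    utr3: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")
        if not self.tss_list:
            self.tss_list = [self.primary_tss]

    @property
    def primary_tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_id(self, index: int) -> str:
        return f"{self.gene_id}:{index}"

    def introns(self) -> list[tuple[int, int]]:
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
            if self.exons[i + 1][0] > self.exons[i][1]
        ]

    def upstream_window(self, window: int = UPSTREAM_WINDOW_BP) -> tuple[int, int]:
        tss = self.primary_tss
        if self.strand == "+":
            return (max(0, tss - window), tss)
        return (tss, tss + window)

    def flanking_introns(self, exon_index: int) -> list[tuple[int, int]]:
        """Introns genomically adjacent to the given exon (0, 1 or 2)."""
        out = []
        if exon_index > 0:
            out.append((self.exons[exon_index - 1][1], self.exons[exon_index][0]))
        if exon_index < self.n_exons - 1:
            out.append((self.exons[exon_index][1], self.exons[exon_index + 1][0]))
        return [iv for iv in out if iv[1] > iv[0]]


@dataclass
class RegionAssignment:
    target_id: str
    category: str
    gene_id: Optional[str] = None
    gene_class: Optional[str] = None


@dataclass
class CpGContext:
    target_id: str
    cls: str
    distance_to_nearest_island: float


class GenomeAnnotation:
    """Interval index over gene features for category assignment."""

    def __init__(
        self,
        genes: Sequence[GeneModel],
        upstream_window: int = UPSTREAM_WINDOW_BP,
        chroms: Optional[Iterable[str]] = None,
    ):
        self.genes = list(genes)
        self.upstream_window = upstream_window
        self.chroms = set(chroms) if chroms is not None else {g.chrom for g in self.genes}
        self.by_id: Dict[str, GeneModel] = {g.gene_id: g for g in self.genes}
        if len(self.by_id) != len(self.genes):
            raise ValueError("duplicate gene ids")
        self._trees: Dict[str, IntervalTree] = {}
        for g in self.genes:
            tree = self._trees.setdefault(g.chrom, IntervalTree())
            for cat, iv in self._gene_features(g):
                if iv[1] > iv[0]:
                    tree.addi(iv[0], iv[1], (cat, g.gene_id))

    def _gene_features(self, g: GeneModel):
        yield "upstream", g.upstream_window(self.upstream_window)
        utr_ivs = [iv for iv in (g.utr5, g.utr3) if iv is not None]
        if g.utr5 is not None:
            yield "5utr", g.utr5
        if g.utr3 is not None:
            yield "3utr", g.utr3
        for ex in g.exons:
            for part in _subtract(ex, utr_ivs):
                yield "exon", part
        for intron in g.introns():
            yield "intron", intron

    def assign(self, chrom: str, start: int, end: int, target_id: str = "") -> RegionAssignment:
        """Single category for an interval, by feature precedence.

        Ties between genes at equal precedence break on sorted gene id so the
        result is independent of annotation record order.
        """
        if chrom not in self.chroms:
            raise KeyError(f"unknown chromosome {chrom!r}")
        hits = sorted(
            ((_PRECEDENCE[cat], gid) for (_, _, (cat, gid)) in self._trees.get(chrom, IntervalTree()).overlap(start, end)),
        )
        if not hits:
            return RegionAssignment(target_id, "intergenic")
        prec, gid = hits[0]
        gene = self.by_id[gid]
        return RegionAssignment(target_id, CATEGORIES[prec], gid, gene.gene_class)

    def assign_many(self, intervals: pd.DataFrame) -> pd.Series:
        """Category per row of a frame with chrom/start/end columns."""
        cats = [
            self.assign(row.chrom, int(row.start), int(row.end)).category
            for row in intervals.itertuples()
        ]
        return pd.Series(cats, index=intervals.index, name="category")


def _subtract(iv: tuple[int, int], cuts: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = [iv]
    for c in cuts:
        nxt = []
        for s, e in pieces:
            if c[1] <= s or c[0] >= e:
                nxt.append((s, e))
                continue
            if c[0] > s:
                nxt.append((s, c[0]))
            if c[1] < e:
                nxt.append((c[1], e))
        pieces = nxt
    return pieces


def region_enrichment(
    tdmr_probe_ids: Set[str],
    probes: pd.DataFrame,
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """Per-category hypergeometric enrichment of T-DMR probes.

    The expected share of each category is the share of all (non-control)
    array probes assigned to it; significance is the upper hypergeometric
    tail of the observed T-DMR probe count.
    """
    genomic = probes.loc[~probes["is_control"]].copy()
    unknown = tdmr_probe_ids - set(genomic["probe_id"])
    if unknown:
        raise ValueError(f"T-DMR probes absent from the probe table: {sorted(unknown)[:3]}...")
    genomic["category"] = annotation.assign_many(genomic)
    in_tdmr = genomic["probe_id"].isin(tdmr_probe_ids)
    universe = len(genomic)
    draws = int(in_tdmr.sum())
    rows = []
    for cat in CATEGORIES:
        cat_mask = genomic["category"] == cat
        size = int(cat_mask.sum())
        if size == 0:
            continue
        obs = int((cat_mask & in_tdmr).sum())
        res = hypergeom_enrichment(obs, size, universe, draws)
        rows.append(
            {
                "category": cat,
                "observed_n": obs,
                "observed_pct": 100.0 * obs / draws if draws else math.nan,
                "expected_pct": 100.0 * size / universe,
                "p": res.p_value,
            }
        )
    return pd.DataFrame(rows)


def build_island_index(islands: Iterable[tuple[str, int, int]]) -> Dict[str, np.ndarray]:
    """Sorted per-chromosome (n, 2) arrays of island intervals."""
    by_chrom: Dict[str, list] = {}
    for chrom, s, e in islands:
        by_chrom.setdefault(chrom, []).append((s, e))
    return {c: np.array(sorted(v), dtype=np.int64).reshape(-1, 2) for c, v in by_chrom.items()}


def cpg_context(
    chrom: str,
    start: int,
    end: int,
    islands: Mapping[str, np.ndarray],
    target_id: str = "",
    shore_bp: int = CPG_SHORE_BP,
    shelf_bp: int = CPG_SHELF_BP,
) -> CpGContext:
    """Island / shore / shelf / open-sea class of an interval.

    Distance is the gap in bases to the closest island edge (0 on overlap).
    Chromosomes without any island give open_sea with an infinite distance.
    """
    arr = islands.get(chrom)
    if arr is None or arr.size == 0:
        return CpGContext(target_id, "open_sea", math.inf)
    gaps = np.maximum(arr[:, 0] - end, start - arr[:, 1])
    d = int(max(0, gaps.min()))
    overlap = bool((gaps < 0).any())
    if overlap:
        cls = "island"
    elif d <= shore_bp:
        cls = "shore"
    elif d <= shelf_bp:
        cls = "shelf"
    else:
        cls = "open_sea"
    return CpGContext(target_id, cls, 0 if overlap else d)


def geneset_enrichment(
    genes_of_interest: Set[str],
    gene_terms: Mapping[str, Set[str]],
    universe: Set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric term enrichment with Bonferroni correction.

    Terms are called significant at adjusted p < ``alpha``.  Genes outside
    the universe in ``gene_terms`` are ignored; terms with no universe gene
    are skipped.
    """
    if not genes_of_interest <= universe:
        raise ValueError("genes_of_interest must be a subset of the universe")
    term_genes: Dict[str, Set[str]] = {}
    for gene in universe:
        for term in gene_terms.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)
    rows = []
    for term in sorted(term_genes):
        members = term_genes[term]
        obs = len(members & genes_of_interest)
        res = hypergeom_enrichment(obs, len(members), len(universe), len(genes_of_interest))
        rows.append({"term": term, "observed": obs, "term_size": len(members), "p": res.p_value})
    df = pd.DataFrame(rows, columns=["term", "observed", "term_size", "p"])
    if len(df):
        df["q"] = bonferroni(df["p"].to_numpy())
        df["significant"] = df["q"] < alpha
    else:
        df["q"] = pd.Series(dtype=float)
        df["significant"] = pd.Series(dtype=bool)
    return df
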