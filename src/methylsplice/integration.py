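"""Joining T-DMRs with alternative-splicing calls.

Links a called T-DMR to an exon when the T-DMR intersects the exon's
window -- either the exon plus its two directly flanking introns, or the
exon plus fixed 1 kb flanks -- and labels the link's position in
gene-sense orientation (a T-DMR touching the exon itself is within_exon).
Regulation is classified per the sign convention: positive when the
hypermethylated tissue is also the tissue of greater exon inclusion,
negative when hypermethylation accompanies exclusion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import pandas as pd

from .annotation import GeneModel
from .stats import TestResult, hypergeom_enrichment, two_proportion_test
from .tdmr import TDMR

log = logging.getLogger(__name__)


@dataclass
class OverlapResult:
    test: TestResult
    n_overlap: int
    n_tdmr_genes: int
    n_as_genes: int
    n_universe: int
    pct_tdmr_genes_as: float
    pct_as_genes_with_tdmr: float


def gene_overlap_enrichment(tdmr_genes: set, as_genes: set, universe: set) -> OverlapResult:
    """Hypergeometric enrichment of the T-DMR x AS gene overlap.

    The universe is the set of genes represented on the expression
    platform; both input sets must be subsets of it.
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not (tdmr_genes <= universe and as_genes <= universe):
        raise ValueError("gene sets must be subsets of the universe")
    overlap = len(tdmr_genes & as_genes)
    res = hypergeom_enrichment(overlap, len(as_genes), len(universe), len(tdmr_genes))
    return OverlapResult(
        test=res,
        n_overlap=overlap,
        n_tdmr_genes=len(tdmr_genes),
        n_as_genes=len(as_genes),
        n_universe=len(universe),
        pct_tdmr_genes_as=100.0 * overlap / len(tdmr_genes) if tdmr_genes else float("nan"),
        pct_as_genes_with_tdmr=100.0 * overlap / len(as_genes) if as_genes else float("nan"),
    )


def exon_window(gene: GeneModel, exon_index: int, mode: str, flank: int = 1000) -> tuple[int, int]:
    """Genomic window around an exon: flanking introns or fixed flanks."""
    s, e = gene.exons[exon_index]
    if mode == "flanking_introns":
        lo = gene.exons[exon_index - 1][1] if exon_index > 0 else s
        hi = gene.exons[exon_index + 1][0] if exon_index < gene.n_exons - 1 else e
        return (min(lo, s), max(hi, e))
    if mode == "1kb":
        return (max(0, s - flank), e + flank)
    raise ValueError(f"unknown window mode {mode!r}")


def link_tdmrs_to_exons(
    exon_keys: Iterable[tuple[str, int]],
    tdmrs: Sequence[TDMR],
    genes_by_id: Mapping[str, GeneModel],
    mode: str = "1kb",
    flank: int = 1000,
) -> pd.DataFrame:
    """Per-exon T-DMR links with gene-sense position labels.

    One row per (tdmr, exon) pair whose window intersects; position is
    within_exon when the T-DMR touches the exon interval itself (exon
    contact dominates boundary-straddling T-DMRs), else upstream or
    downstream in gene-sense orientation.  Exons absent from the
    annotation are skipped with a log line.  Output is sorted, so link
    sets are invariant to T-DMR input order.
    """
    by_chrom: Dict[str, list[TDMR]] = {}
    for t in tdmrs:
        by_chrom.setdefault(t.chrom, []).append(t)
    rows = []
    for gene_id, exon_index in exon_keys:
        gene = genes_by_id.get(gene_id)
        if gene is None or not 0 <= exon_index < gene.n_exons:
            log.info("exon %s:%s absent from annotation; skipped", gene_id, exon_index)
            continue
        lo, hi = exon_window(gene, exon_index, mode, flank)
        es, ee = gene.exons[exon_index]
        for t in by_chrom.get(gene.chrom, ()):
            if t.start >= hi or t.end <= lo:
                continue
            if t.start < ee and t.end > es:
                position = "within_exon"
            else:
                genomically_before = t.end <= es
                position = (
                    "upstream"
                    if genomically_before == (gene.strand == "+")
                    else "downstream"
                )
            rows.append(
                {
                    "tdmr_id": t.tdmr_id,
                    "gene_id": gene_id,
                    "exon_index": exon_index,
                    "exon_id": gene.exon_id(exon_index),
                    "position": position,
                }
            )
    df = pd.DataFrame(rows, columns=["tdmr_id", "gene_id", "exon_index", "exon_id", "position"])
    return df.sort_values(["exon_id", "tdmr_id"], kind="mergesort").reset_index(drop=True)


def exon_level_association(
    as_calls: pd.DataFrame,
    tdmrs: Sequence[TDMR],
    genes_by_id: Mapping[str, GeneModel],
    mode: str = "1kb",
    flank: int = 1000,
    as_only: bool = True,
) -> pd.DataFrame:
    """T-DMR links for (by default) the AS exons of an AS-call table."""
    calls = as_calls.loc[as_calls["is_AS"]] if as_only else as_calls
    keys = [
        (row.gene_id, int(row.exon_id.rsplit(":", 1)[1]))
        for row in calls.itertuples()
    ]
    return link_tdmrs_to_exons(keys, tdmrs, genes_by_id, mode=mode, flank=flank)


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def coverage_fraction(
    exon_keys: Iterable[tuple[str, int]],
    tdmrs: Sequence[TDMR],
    genes_by_id: Mapping[str, GeneModel],
) -> tuple[float, int, int]:
    """Pooled fraction of exon + flanking-intron territory covered by
    T-DMRs (T-DMRs merged first, so duplicates never double count).

    Returns (fraction, covered bases, total bases).
    """
    tdmr_by_chrom: Dict[str, list[tuple[int, int]]] = {}
    for t in tdmrs:
        tdmr_by_chrom.setdefault(t.chrom, []).append((t.start, t.end))
    tdmr_by_chrom = {c: _merge(v) for c, v in tdmr_by_chrom.items()}
    total = covered = 0
    for gene_id, exon_index in exon_keys:
        gene = genes_by_id[gene_id]
        pieces = [gene.exons[exon_index]] + gene.flanking_introns(exon_index)
        for s, e in _merge(pieces):
            total += e - s
            for ts, te in tdmr_by_chrom.get(gene.chrom, ()):
                covered += max(0, min(e, te) - max(s, ts))
    return (covered / total if total else float("nan"), covered, total)


def coverage_comparison(
    as_exon_keys: Sequence[tuple[str, int]],
    non_as_exon_keys: Sequence[tuple[str, int]],
    tdmrs: Sequence[TDMR],
    genes_by_id: Mapping[str, GeneModel],
) -> dict:
    """T-DMR coverage of AS vs non-AS exon neighborhoods with a
    two-proportion comparison over pooled bases."""
    f_as, c_as, t_as = coverage_fraction(as_exon_keys, tdmrs, genes_by_id)
    f_non, c_non, t_non = coverage_fraction(non_as_exon_keys, tdmrs, genes_by_id)
    out = {
        "as_fraction": f_as,
        "non_as_fraction": f_non,
        "as_covered": c_as,
        "as_total": t_as,
        "non_as_covered": c_non,
        "non_as_total": t_non,
    }
    if t_as and t_non:
        out["test"] = two_proportion_test(c_as, t_as, c_non, t_non)
    return out


@dataclass
class RegulationAssignment:
    """Methylation-splicing regulation label for one T-DMR x exon link."""

    tdmr_id: str
    exon_id: str
    position: str
    regulation: str       # positive | negative
    delta_sign: str       # tissue of hypermethylation
    inclusion_tissue: str  # tissue of higher NI

    def __post_init__(self) -> None:
        expected = "positive" if self.delta_sign == self.inclusion_tissue else "negative"
        if self.regulation != expected:
            raise ValueError("regulation label inconsistent with tissue signs")


def classify_regulation(
    position: str,
    tdmr: TDMR,
    as_call: pd.Series,
) -> RegulationAssignment:
    """Positive when hypermethylation and greater inclusion share a tissue,
    negative otherwise; symmetric under relabeling of the two tissues."""
    if not bool(as_call["is_AS"]):
        raise ValueError(f"exon {as_call['exon_id']} is not AS; no regulation assignment")
    hyper = tdmr.direction
    included = str(as_call["included_in"])
    regulation = "positive" if hyper == included else "negative"
    return RegulationAssignment(
        tdmr_id=tdmr.tdmr_id,
        exon_id=str(as_call["exon_id"]),
        position=position,
        regulation=regulation,
        delta_sign=hyper,
        inclusion_tissue=included,
    )


def classify_links(
    links: pd.DataFrame,
    tdmrs: Sequence[TDMR],
    as_calls: pd.DataFrame,
) -> pd.DataFrame:
    """Regulation labels for every link to an AS exon (one assignment per
    (tdmr, exon) pair; a T-DMR linked to several AS exons contributes one
    row per exon)."""
    tdmr_by_id = {t.tdmr_id: t for t in tdmrs}
    calls = as_calls.set_index("exon_id")
    rows = []
    for row in links.itertuples():
        call = calls.loc[row.exon_id].copy()
        call["exon_id"] = row.exon_id
        if not bool(call["is_AS"]):
            continue
        a = classify_regulation(row.position, tdmr_by_id[row.tdmr_id], call)
        rows.append(
            {
                "tdmr_id": a.tdmr_id,
                "gene_id": row.gene_id,
                "exon_index": row.exon_index,
                "exon_id": a.exon_id,
                "position": a.position,
                "regulation": a.regulation,
                "delta_sign": a.delta_sign,
                "inclusion_tissue": a.inclusion_tissue,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "tdmr_id", "gene_id", "exon_index", "exon_id",
            "position", "regulation", "delta_sign", "inclusion_tissue",
        ],
    )
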