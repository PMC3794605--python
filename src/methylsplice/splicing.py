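"""Exon inclusion (NI), splicing index (SI) and alternative-splicing calls.

NI is the exon's log2 intensity relative to the overall expression of its
host gene (gene level = mean of the gene's exon log2 intensities, per
sample); SI is the difference of mean NIs between the two tissues, i.e.
the log2 fold change of inclusion.  An exon is called alternatively
spliced (AS) when the Welch t-test on NI across replicates gives
p < 0.01 and |SI| > log2(1.25).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import GeneModel
from .stats import welch_t_rows

log = logging.getLogger(__name__)

AS_P_CUTOFF = 0.01
AS_SI_CUTOFF = math.log2(1.25)


@dataclass
class ExonNI:
    """Per-exon normalized intensities with gene membership.

    ``values`` is indexed by exon_id with one column per sample;
    single-exon genes have NI identically zero by construction and are
    flagged for exclusion from AS calling.
    """

    values: pd.DataFrame
    gene_id: pd.Series
    single_exon_genes: set


def compute_ni(expression: pd.DataFrame) -> ExonNI:
    """NI = exon log2 intensity minus the gene-mean log2 intensity.

    ``expression`` needs gene_id and exon_id columns plus one column per
    sample.  Within each gene and sample the NIs sum to zero under the
    mean summarization.
    """
    samples = [c for c in expression.columns if c not in ("gene_id", "exon_id")]
    if expression["exon_id"].duplicated().any():
        raise ValueError("duplicate exon ids in expression matrix")
    vals = expression.set_index("exon_id")[samples]
    gene_id = expression.set_index("exon_id")["gene_id"]
    gene_mean = vals.groupby(gene_id).transform("mean")
    ni = vals - gene_mean
    counts = gene_id.value_counts()
    single = set(counts[counts == 1].index)
    if single:
        log.info("%d single-exon genes flagged (NI identically 0, excluded from AS calling)", len(single))
    return ExonNI(values=ni, gene_id=gene_id, single_exon_genes=single)


def call_as_exons(
    ni: ExonNI,
    sample_tissue: Mapping[str, str],
    tissues: Sequence[str],
    p_cutoff: float = AS_P_CUTOFF,
    si_cutoff: float = AS_SI_CUTOFF,
) -> pd.DataFrame:
    """Per-exon AS calls: SI, p, is_AS flag and the inclusion tissue.

    SI = mean NI(tissues[0]) - mean NI(tissues[1]); both the significance
    and the magnitude threshold must be met (strict inequalities).
    Exons of single-exon genes are excluded.
    """
    cols_a = [s for s in ni.values.columns if sample_tissue[s] == tissues[0]]
    cols_b = [s for s in ni.values.columns if sample_tissue[s] == tissues[1]]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per tissue")
    keep = ~ni.gene_id.isin(ni.single_exon_genes)
    vals = ni.values.loc[keep]
    a = vals[cols_a].to_numpy()
    b = vals[cols_b].to_numpy()
    t, p = welch_t_rows(a, b)
    si = a.mean(axis=1) - b.mean(axis=1)
    calls = pd.DataFrame(
        {
            "exon_id": vals.index,
            "gene_id": ni.gene_id.loc[keep].to_numpy(),
            "SI": si,
            "p": p,
            "is_AS": (p < p_cutoff) & (np.abs(si) > si_cutoff),
            "included_in": np.where(si > 0, tissues[0], tissues[1]),
        }
    ).reset_index(drop=True)
    log.info("AS calling: %d / %d exons pass p<%g and |SI|>%.4f", int(calls["is_AS"].sum()), len(calls), p_cutoff, si_cutoff)
    return calls


def as_robustness_sweep(
    ni: ExonNI,
    sample_tissue: Mapping[str, str],
    tissues: Sequence[str],
    grid: Sequence[tuple[float, float]],
    tdmr_genes: set | None = None,
    universe: set | None = None,
) -> pd.DataFrame:
    """AS exon/gene counts across a grid of (p_cutoff, si_cutoff) pairs.

    When a T-DMR gene set and expressed universe are supplied, each row
    also reports the hypergeometric enrichment p of the T-DMR/AS gene
    overlap at that cutoff pair.
    """
    if not len(grid):
        raise ValueError("empty cutoff grid")
    from .integration import gene_overlap_enrichment

    rows = []
    for p_cut, si_cut in grid:
        calls = call_as_exons(ni, sample_tissue, tissues, p_cutoff=p_cut, si_cutoff=si_cut)
        as_exons = int(calls["is_AS"].sum())
        as_genes = set(calls.loc[calls["is_AS"], "gene_id"])
        row = {
            "p_cutoff": p_cut,
            "si_cutoff": si_cut,
            "n_as_exons": as_exons,
            "n_as_genes": len(as_genes),
        }
        if tdmr_genes is not None and universe is not None:
            res = gene_overlap_enrichment(tdmr_genes & universe, as_genes, universe)
            row["overlap_p"] = res.test.p_value
        rows.append(row)
    return pd.DataFrame(rows)


def alternative_start_genes(
    genes: Sequence[GeneModel],
    as_calls: pd.DataFrame,
    genes_by_id: Dict[str, GeneModel] | None = None,
) -> list[str]:
    """Genes with >= 2 annotated start sites and an AS exon inside the
    alternative-start region [min TSS, max TSS)."""
    genes_by_id = genes_by_id or {g.gene_id: g for g in genes}
    as_only = as_calls.loc[as_calls["is_AS"]]
    flagged = []
    for g in genes:
        if len(set(g.tss_list)) < 2:
            continue
        lo, hi = min(g.tss_list), max(g.tss_list)
        for exon_id in as_only.loc[as_only["gene_id"] == g.gene_id, "exon_id"]:
            idx = int(exon_id.rsplit(":", 1)[1])
            s, e = g.exons[idx]
            if lo <= s and e <= hi:
                flagged.append(g.gene_id)
                break
    return flagged
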