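"""Parameter-recovery benchmarks on planted synthetic data.

Each benchmark builds a synthetic data set under the package's standard
study conditions, runs the relevant pipeline stage, and scores the result
against the planted truth.  They are used by the test suite and by
``scripts/acceptance.py``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict

import numpy as np
import pandas as pd

from . import motifs as mot
from . import tdmr as td
from .splicing import call_as_exons, compute_ni
from .integration import classify_links, exon_level_association
from .synthetic_data import (
    SimConfig,
    generate_genome,
    plant_motifs,
    plant_truth,
    simulate_dataset,
)


def _overlaps(chrom, start, end, t) -> bool:
    return chrom == t.chrom and start < t.end and end > t.start


def tdmr_recovery_benchmark(seed: int = 1, config: SimConfig | None = None) -> Dict[str, float]:
    """Call T-DMRs on the standard planted benchmark (~2 Mb, ~50k probes,
    100 planted regions, delta 0.3, M-noise sd 0.1, 3v3) and score
    interval-level sensitivity and empirical FDR (a called region is true
    when it overlaps a planted region by >= 1 bp)."""
    cfg = config or SimConfig(seed=seed)
    cfg = dataclasses.replace(cfg, seed=seed)
    ds = simulate_dataset(cfg)
    table = td.filter_background(td.normalize(ds.probe_table))
    m = td.relative_methylation(table)
    calls = td.call_tdmrs(m, table.probes, table.sample_tissue, table.tissues)
    true_calls = sum(
        any(_overlaps(c.chrom, c.start, c.end, t) for t in ds.truth.tdmrs) for c in calls
    )
    recovered = sum(
        any(_overlaps(c.chrom, c.start, c.end, t) for c in calls) for t in ds.truth.tdmrs
    )
    n_calls = len(calls)
    return {
        "n_planted": len(ds.truth.tdmrs),
        "n_called": n_calls,
        "sensitivity": recovered / len(ds.truth.tdmrs),
        "fdr": 1.0 - true_calls / n_calls if n_calls else float("nan"),
    }


def regulation_recovery_benchmark(seed: int = 13) -> Dict[str, float]:
    """Noise-free coupled data: fraction of planted positive/negative
    regulation labels reproduced by classify_regulation through the full
    NI -> AS -> link -> classify path, using the true T-DMR intervals."""
    cfg = SimConfig(
        seed=seed,
        n_chromosomes=1,
        chrom_length=450_000,
        n_genes=16,
        n_ncrna=2,
        planted_tdmr_count=12,
        n_control_probes=200,
        methyl_noise_sd=0.0,
        expr_noise_sd=0.0,
        dead_probe_fraction=0.0,
    )
    ds = simulate_dataset(cfg)
    genes = ds.bundle.genes_by_id()
    tdmrs = [
        td.TDMR(
            tdmr_id=t.tdmr_id, chrom=t.chrom, start=t.start, end=t.end,
            probe_ids=["x", "y", "z"], direction=t.direction,
            mean_delta=0.3 if t.direction == cfg.tissues[0] else -0.3,
            min_probe_p=1e-9,
        )
        for t in ds.truth.tdmrs
    ]
    calls = call_as_exons(
        compute_ni(ds.expression), ds.probe_table.sample_tissue, cfg.tissues
    )
    links = exon_level_association(calls, tdmrs, genes, mode="1kb")
    labelled = classify_links(links, tdmrs, calls).set_index(["tdmr_id", "exon_id"])
    n_ok = 0
    for c in ds.truth.couplings:
        key = (c.tdmr_id, f"{c.gene_id}:{c.exon_index}")
        if key in labelled.index and labelled.loc[key, "regulation"] == c.regulation:
            n_ok += 1
    return {
        "n_couplings": len(ds.truth.couplings),
        "n_recovered": n_ok,
        "accuracy": n_ok / len(ds.truth.couplings),
    }


def motif_benchmark_config(seed: int, planted: bool = True) -> SimConfig:
    """Design with >= 200 kb of downstream-negative group sequence."""
    return SimConfig(
        seed=seed,
        n_chromosomes=3,
        chrom_length=1_700_000,
        n_genes=260,
        n_ncrna=0,
        planted_tdmr_count=280,
        coupling_table={"negative": 1.0},
        coupling_positions={"downstream": 1.0},
        tdmr_length=(750, 980),
        planted_motifs=[("ACCGCT", "downstream_negative", 5.0)] if planted else [],
    )


def motif_recovery_benchmark(seed: int = 3, planted: bool = True) -> Dict[str, float]:
    """Plant one 6mer at 5x background in the downstream-negative group and
    test its recovery at BH FDR 1%; with ``planted=False`` the same design
    measures the null significant fraction."""
    cfg = motif_benchmark_config(seed, planted)
    bundle = generate_genome(cfg)
    truth = plant_truth(bundle, cfg)
    plant_motifs(bundle, truth, cfg)
    links = pd.DataFrame(
        [
            {
                "tdmr_id": c.tdmr_id, "gene_id": c.gene_id, "exon_index": c.exon_index,
                "position": c.position, "regulation": c.regulation,
            }
            for c in truth.couplings
        ]
    )
    tdmr_iv = {t.tdmr_id: (t.chrom, t.start, t.end) for t in truth.tdmrs}
    groups = mot.extract_group_sequences(links, tdmr_iv, bundle.genes_by_id(), bundle.sequences)
    seqs = [g.seq for g in groups[("downstream", "negative")]]
    background = mot.build_background(
        bundle.genes, bundle.sequences, n_exons=10000, side="downstream", seed=seed
    )
    stats = mot.count_and_test(seqs, background)
    out = {
        "group_bp": float(sum(len(s) for s in seqs)),
        "significant_fraction": float(stats["significant"].mean()),
        "n_significant": int(stats["significant"].sum()),
    }
    if planted:
        row = stats.set_index("kmer").loc["ACCGCT"]
        out["planted_q"] = float(row["q"])
        out["planted_recovered"] = float(bool(row["significant"]))
        out["planted_fold"] = float(row["M"] / (row["f"] * row["N"])) if row["f"] > 0 else float("inf")
    return out


def distance_calibration_benchmark(seed: int = 1, n_groups: int = 60, length: int = 1000) -> Dict[str, float]:
    """Shuffled motif-pair distances vs the analytic uniform-placement
    expectation for two points on a discrete interval."""
    rows = []
    for g in range(n_groups):
        rows.append({"group": f"g{g}", "kmer": "ACCGCT", "pos": 100, "lo": 0, "hi": length - mot.K})
        rows.append({"group": f"g{g}", "kmer": "ACCGCT", "pos": 130, "lo": 0, "hi": length - mot.K})
    res = mot.pair_distance_test(pd.DataFrame(rows), n_shuffles=100, seed=seed)
    m = length - mot.K
    expected = m * (m + 2) / (3 * (m + 1))
    return {
        "shuffled_mean": res.shuffled_mean,
        "expected_mean": expected,
        "relative_error": abs(res.shuffled_mean - expected) / expected,
    }
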