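"""Generator contracts: determinism, planted-effect exactness, truth
integrity and structural validity of the synthetic study design."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from methylsplice.splicing import compute_ni
from methylsplice.synthetic_data import (
    ConfigError,
    SimConfig,
    SizingError,
    generate_genome,
    plant_motifs,
    plant_truth,
    simulate_dataset,
    simulate_exon_expression,
    simulate_methylation,
    validate_truth,
)


class TestGenerateGenome:
    def test_empty_gene_case_still_emits_sequence(self):
        cfg = SimConfig(seed=0, n_chromosomes=1, chrom_length=100_000, n_genes=0, n_ncrna=0)
        bundle = generate_genome(cfg)
        assert bundle.genes == []
        assert len(bundle.sequences["chr1"]) == 100_000
        assert set(bytes(bundle.sequences["chr1"])) <= set(b"ACGT")

    def test_exon_structure_and_containment(self):
        cfg = SimConfig(
            seed=1, n_chromosomes=2, chrom_length=800_000,
            n_genes=20, n_ncrna=0, exons_per_gene=(5, 5),
        )
        bundle = generate_genome(cfg)
        assert len(bundle.genes) == 20
        for g in bundle.genes:
            assert g.n_exons == 5
            for s, e in g.exons:
                assert g.start <= s < e <= g.end
            # exons ordered and separated by introns
            for (s1, e1), (s2, e2) in zip(g.exons, g.exons[1:]):
                assert e1 < s2

    def test_genes_non_overlapping(self, small_dataset):
        by_chrom = {}
        for g in small_dataset.bundle.genes:
            by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_conservation_in_unit_interval(self, small_dataset):
        for arr in small_dataset.bundle.conservation.values():
            assert arr.min() >= 0.0 and arr.max() <= 1.0

    def test_cpg_island_classes_all_represented(self, small_dataset):
        from methylsplice.annotation import build_island_index, cpg_context

        islands = build_island_index(small_dataset.bundle.cpg_islands)
        chrom = "chr1"
        length = len(small_dataset.bundle.sequences[chrom])
        classes = {
            cpg_context(chrom, p, p + 50, islands).cls
            for p in range(0, length - 50, 500)
        }
        assert classes == {"island", "shore", "shelf", "open_sea"}

    def test_multi_tss_genes_exist(self, small_dataset):
        multi = [g for g in small_dataset.bundle.genes if len(g.tss_list) > 1]
        assert multi, "expected a subset of genes with two start sites"
        for g in multi:
            assert g.start <= min(g.tss_list) and max(g.tss_list) <= g.end

    def test_sizing_error(self):
        cfg = SimConfig(seed=0, n_chromosomes=1, chrom_length=60_000, n_genes=20)
        with pytest.raises(SizingError):
            generate_genome(cfg)

    def test_determinism_byte_identical(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        assert {c: bytes(s) for c, s in a.bundle.sequences.items()} == {
            c: bytes(s) for c, s in b.bundle.sequences.items()
        }
        for c in a.bundle.conservation:
            assert np.array_equal(a.bundle.conservation[c], b.bundle.conservation[c])
        pd.testing.assert_frame_equal(a.probe_table.input, b.probe_table.input)
        pd.testing.assert_frame_equal(a.probe_table.enriched, b.probe_table.enriched)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        assert a.truth == b.truth


class TestTruth:
    def test_referential_integrity(self, small_dataset):
        validate_truth(small_dataset.bundle, small_dataset.truth)
        exon_ids = {a.exon_id for a in small_dataset.truth.as_exons}
        for c in small_dataset.truth.couplings:
            assert f"{c.gene_id}:{c.exon_index}" in exon_ids

    def test_corrupted_truth_raises(self, small_dataset):
        truth = dataclasses.replace(small_dataset.truth)
        bad = dataclasses.replace(truth.couplings[0], tdmr_id="D9999")
        truth = dataclasses.replace(truth, couplings=[bad])
        with pytest.raises(ValueError):
            validate_truth(small_dataset.bundle, truth)

    def test_coupling_fractions_respected(self, small_dataset):
        counts = {"positive": 0, "negative": 0}
        for c in small_dataset.truth.couplings:
            counts[c.regulation] += 1
        cfg = small_dataset.config
        assert counts["positive"] == round(cfg.coupling_table["positive"] * cfg.planted_tdmr_count)
        assert counts["negative"] == round(cfg.coupling_table["negative"] * cfg.planted_tdmr_count)

    def test_coupled_tdmrs_inside_flank_windows(self, small_dataset):
        from methylsplice.motifs import flank_window

        genes = small_dataset.bundle.genes_by_id()
        tdmrs = {t.tdmr_id: t for t in small_dataset.truth.tdmrs}
        for c in small_dataset.truth.couplings:
            t = tdmrs[c.tdmr_id]
            gene = genes[c.gene_id]
            es, ee = gene.exons[c.exon_index]
            if c.position == "within_exon":
                assert t.start < ee and t.end > es
            else:
                chrom_len = len(small_dataset.bundle.sequences[t.chrom])
                lo, hi = flank_window(gene, c.exon_index, c.position, 1000, chrom_len)
                assert lo <= t.start and t.end <= hi


class TestSimulateMethylation:
    def test_noise_free_difference_is_exactly_delta(self, noise_free_dataset):
        ds = noise_free_dataset
        cfg = ds.config
        table = ds.probe_table
        genomic = ~table.probes["is_control"].to_numpy()
        m = table.enriched - table.input
        cols_a = table.samples_of(cfg.tissues[0])
        cols_b = table.samples_of(cfg.tissues[1])
        diff = (m[cols_a].mean(axis=1) - m[cols_b].mean(axis=1)).to_numpy()[genomic]
        probes = table.probes.loc[genomic].reset_index(drop=True)
        inside = np.zeros(len(probes), dtype=bool)
        direction_sign = np.zeros(len(probes))
        for t in ds.truth.tdmrs:
            hit = (
                (probes["chrom"] == t.chrom)
                & (probes["start"] < t.end)
                & (probes["end"] > t.start)
            ).to_numpy()
            inside |= hit
            direction_sign[hit] = 1.0 if t.direction == cfg.tissues[0] else -1.0
        assert diff[inside] == pytest.approx((direction_sign[inside] * cfg.planted_delta), abs=1e-12)
        assert diff[~inside] == pytest.approx(0.0, abs=1e-12)

    def test_control_probes_have_no_genomic_assignment(self, small_dataset):
        controls = small_dataset.probe_table.probes.query("is_control")
        assert (controls["chrom"] == "*").all()
        assert (controls["start"] == -1).all()

    def test_controls_sit_at_background_level(self, small_dataset):
        t = small_dataset.probe_table
        ctrl = t.probes["is_control"].to_numpy()
        assert t.input.to_numpy()[ctrl].mean() < t.input.to_numpy()[~ctrl].mean() - 3

    def test_invalid_delta_rejected(self, small_config):
        cfg = dataclasses.replace(small_config, planted_delta=-0.1)
        with pytest.raises(ConfigError):
            cfg.validate()


class TestSimulateExpression:
    def test_planted_si_signs_follow_regulation(self, noise_free_dataset):
        """Positive coupling: exon included in the hypermethylated tissue;
        negative coupling: included in the other tissue."""
        ds = noise_free_dataset
        cfg = ds.config
        ni = compute_ni(ds.expression)
        cols_a = [s for s in ni.values.columns if s.startswith(cfg.tissues[0])]
        cols_b = [s for s in ni.values.columns if s.startswith(cfg.tissues[1])]
        si = ni.values[cols_a].mean(axis=1) - ni.values[cols_b].mean(axis=1)
        tdmrs = {t.tdmr_id: t for t in ds.truth.tdmrs}
        assert ds.truth.couplings
        for c in ds.truth.couplings:
            hyper = tdmrs[c.tdmr_id].direction
            included = hyper if c.regulation == "positive" else (
                cfg.tissues[1] if hyper == cfg.tissues[0] else cfg.tissues[0]
            )
            expected = cfg.as_effect if included == cfg.tissues[0] else -cfg.as_effect
            assert si[f"{c.gene_id}:{c.exon_index}"] == pytest.approx(expected, abs=1e-9)

    def test_non_as_exons_have_zero_or_sibling_leakage_si(self, noise_free_dataset):
        """Exons in unplanted genes have SI exactly 0; siblings of a planted
        exon absorb the within-gene normalization shift, -SI/(n-1)."""
        ds = noise_free_dataset
        ni = compute_ni(ds.expression)
        planted = {a.exon_id for a in ds.truth.as_exons}
        planted_genes = {a.gene_id for a in ds.truth.as_exons}
        cols_a = [s for s in ni.values.columns if s.startswith(ds.config.tissues[0])]
        cols_b = [s for s in ni.values.columns if s.startswith(ds.config.tissues[1])]
        si = ni.values[cols_a].mean(axis=1) - ni.values[cols_b].mean(axis=1)
        untouched = si[~ni.gene_id.isin(planted_genes)]
        assert untouched.abs().max() == pytest.approx(0.0, abs=1e-9)
        siblings = si.drop(index=list(planted))
        siblings = siblings[ni.gene_id.loc[siblings.index].isin(planted_genes)]
        n_exons = ni.gene_id.value_counts()
        for exon_id, value in siblings.items():
            n = n_exons[ni.gene_id[exon_id]]
            assert abs(value) == pytest.approx(ds.config.as_effect / (n - 1), abs=1e-9)

    def test_zero_effect_plants_nothing(self, noise_free_config):
        cfg = dataclasses.replace(noise_free_config, as_effect=0.0)
        ds = simulate_dataset(cfg)
        ni = compute_ni(ds.expression)
        cols_a = [s for s in ni.values.columns if s.startswith(cfg.tissues[0])]
        cols_b = [s for s in ni.values.columns if s.startswith(cfg.tissues[1])]
        si = ni.values[cols_a].mean(axis=1) - ni.values[cols_b].mean(axis=1)
        assert si.abs().max() == pytest.approx(0.0, abs=1e-9)


class TestPlantMotifs:
    def test_fold_one_is_a_no_op(self, small_config):
        cfg = dataclasses.replace(
            small_config, planted_motifs=[("ACCGCT", "downstream_negative", 1.0)]
        )
        bundle = generate_genome(cfg)
        truth = plant_truth(bundle, cfg)
        before = {c: bytes(s) for c, s in bundle.sequences.items()}
        plant_motifs(bundle, truth, cfg)
        assert {c: bytes(s) for c, s in bundle.sequences.items()} == before
        assert truth.planted_motif_sites == []

    def test_validation_errors(self):
        for bad in [("ACGTN", "downstream_negative", 5.0),
                    ("ACGTA", "downstream_negative", 5.0),
                    ("ACCGCT", "sideways_negative", 5.0),
                    ("ACCGCT", "downstream_negative", 0.5)]:
            cfg = SimConfig(planted_motifs=[bad])
            with pytest.raises(ConfigError):
                cfg.validate()

    def test_planted_sites_carry_the_motif_in_gene_sense(self, small_config):
        from methylsplice.motifs import revcomp

        cfg = dataclasses.replace(
            small_config,
            planted_motifs=[("ACCGCT", "downstream_negative", 30.0)],
        )
        bundle = generate_genome(cfg)
        truth = plant_truth(bundle, cfg)
        plant_motifs(bundle, truth, cfg)
        assert truth.planted_motif_sites
        strands = {g.gene_id: g.strand for g in bundle.genes}
        coup = {c.tdmr_id: c for c in truth.couplings}
        tdmr_gene = {t.tdmr_id: coup[t.tdmr_id].gene_id for t in truth.tdmrs if t.tdmr_id in coup}
        for kmer, chrom, pos in truth.planted_motif_sites:
            written = bytes(bundle.sequences[chrom][pos : pos + 6])
            assert written in (kmer.encode(), revcomp(kmer.encode()))
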