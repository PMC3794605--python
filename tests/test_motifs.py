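"""6mer counting, enrichment, positional roles, CpG content, clustering,
PWM similarity and pair-distance statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from methylsplice.motifs import (
    ALL_KMERS,
    BackgroundModel,
    N_KMERS,
    class_counts_from_sizes,
    cluster_consensus,
    count_and_test,
    count_kmers,
    cpg_content,
    index_to_kmer,
    kmer_to_index,
    motif_instances,
    pair_distance_test,
    position_roles,
    positional_comparison,
    pwm_from_consensus,
    pwm_similarity,
    revcomp,
    window_codes,
    GroupSequence,
)


class TestCounting:
    def test_kmer_index_roundtrip(self):
        for idx in (0, 1, 4095, 2048):
            assert kmer_to_index(index_to_kmer(idx)) == idx
        assert index_to_kmer(0) == "AAAAAA"
        assert index_to_kmer(4095) == "TTTTTT"

    def test_sequence_of_length_l_contributes_l_minus_5_windows(self):
        for L in (6, 10, 57):
            seq = b"ACGT" * (L // 4 + 2)
            assert window_codes(seq[:L]).size == L - 5

    def test_homopolymer_background(self):
        counts, total = count_kmers([b"A" * 100])
        assert total == 95
        assert counts[kmer_to_index("AAAAAA")] == 95
        assert counts.sum() == 95

    def test_windows_with_non_acgt_dropped(self):
        counts, total = count_kmers([b"ACGTACNGTACGTA"])
        assert total == 14 - 5 - 6  # six windows touch the N

    def test_uniform_genome_frequencies_near_uniform(self):
        rng = np.random.default_rng(0)
        seq = bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 4_000_000))
        counts, total = count_kmers([seq])
        f = counts / total
        # each kmer ~976 +/- 31 occurrences: 6 sigma bound on the frequency
        assert np.abs(f - 1 / N_KMERS).max() < 6 * math.sqrt((1 / N_KMERS) / total)

    def test_revcomp(self):
        assert revcomp(b"ACCGCT") == b"AGCGGT"
        assert revcomp(revcomp(b"GATTAC")) == b"GATTAC"


def uniform_background(total=10**6):
    return BackgroundModel(f=np.full(N_KMERS, 1 / N_KMERS), total_windows=total, n_sequences=100)


class TestCountAndTest:
    def test_m_sums_to_n(self):
        rng = np.random.default_rng(1)
        seqs = [bytes(rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), 500)) for _ in range(5)]
        stats = count_and_test(seqs, uniform_background())
        assert stats["M"].sum() == stats["N"].iloc[0]

    def test_absent_kmer_never_significant(self):
        stats = count_and_test([b"A" * 100], uniform_background())
        absent = stats[stats["M"] == 0]
        assert (absent["p"] == 1.0).all()
        assert not absent["significant"].any()

    def test_zero_background_with_hits_flagged(self):
        f = np.full(N_KMERS, 1 / (N_KMERS - 1))
        f[kmer_to_index("AAAAAA")] = 0.0
        bg = BackgroundModel(f=f / f.sum(), total_windows=10**5, n_sequences=10)
        stats = count_and_test([b"A" * 50], bg).set_index("kmer")
        row = stats.loc["AAAAAA"]
        assert row["p"] == 0.0
        assert row["zero_background"]

    def test_pseudocount_avoids_zero_p(self):
        f = np.zeros(N_KMERS)
        f[kmer_to_index("CCCCCC")] = 1.0
        bg = BackgroundModel(f=f, total_windows=10**4, n_sequences=10)
        stats = count_and_test([b"A" * 50], bg, pseudocount=True).set_index("kmer")
        assert 0.0 < stats.loc["AAAAAA", "p"] < 1e-10
        assert not stats["zero_background"].any()

    def test_planted_motif_recovered_at_fdr(self):
        rng = np.random.default_rng(2)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = []
        motif = b"ACCGCT"
        for _ in range(100):
            s = bytearray(rng.choice(base, 2000))
            for _ in range(3):  # ~5x the uniform expectation
                pos = int(rng.integers(0, 1994))
                s[pos : pos + 6] = motif
            seqs.append(bytes(s))
        stats = count_and_test(seqs, uniform_background()).set_index("kmer")
        assert stats.loc["ACCGCT", "significant"]

    def test_null_group_calibrated(self):
        rng = np.random.default_rng(3)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = [bytes(rng.choice(base, 2000)) for _ in range(100)]
        stats = count_and_test(seqs, uniform_background(10**7))
        assert stats["significant"].mean() <= 0.05

    def test_lowering_fdr_never_adds_motifs(self):
        rng = np.random.default_rng(4)
        base = np.frombuffer(b"ACGT", dtype=np.uint8)
        seqs = [bytes(rng.choice(base, 3000)) for _ in range(30)]
        loose = count_and_test(seqs, uniform_background(), fdr=0.05)
        strict = count_and_test(seqs, uniform_background(), fdr=0.01)
        assert set(strict.loc[strict["significant"], "kmer"]) <= set(
            loose.loc[loose["significant"], "kmer"]
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            count_and_test([b"ACG"], uniform_background())


def roles_from(sig_map):
    """Build a role Series over the kmer space from {kmer: role}."""
    s = pd.Series("none", index=ALL_KMERS, name="role")
    for k, v in sig_map.items():
        s[k] = v
    return s


class TestPositionalComparison:
    def test_same_role_single_kmer(self):
        df, counts = positional_comparison(
            roles_from({"AAAAAA": "negative"}), roles_from({"AAAAAA": "negative"})
        )
        assert counts["n_union"] == 1
        assert counts["same_role"] == 1
        assert counts["same_role_pct"] == pytest.approx(100.0)

    def test_set_algebra_example(self):
        up = roles_from({"CCCCCC": "negative", "GGGGGG": "positive"})
        down = roles_from({"AAAAAA": "negative", "CCCCCC": "positive"})
        df, counts = positional_comparison(up, down)
        assert counts["n_union"] == 3
        assert counts["one_position_only"] == 2  # AAAAAA, GGGGGG
        assert counts["opposing"] == 1  # CCCCCC flips sign
        assert counts["one_position_only_pct"] == pytest.approx(200 / 3)

    def test_dual_vs_single_counts_as_opposing(self):
        df, counts = positional_comparison(
            roles_from({"AAAAAA": "dual"}), roles_from({"AAAAAA": "negative"})
        )
        assert counts["opposing"] == 1

    def test_counts_partition_the_union(self):
        rng = np.random.default_rng(5)
        kmers = rng.choice(ALL_KMERS, 300, replace=False)
        role_values = ["positive", "negative", "dual"]
        up = roles_from({k: role_values[i % 3] for i, k in enumerate(kmers[:200])})
        down = roles_from({k: role_values[i % 2] for i, k in enumerate(kmers[100:])})
        _, c = positional_comparison(up, down)
        assert c["same_role"] + c["one_position_only"] + c["opposing"] == c["n_union"]
        assert c["same_role"] + c["opposing"] == c["n_up"] + c["n_down"] - c["n_union"]

    def test_published_count_arithmetic(self):
        out = class_counts_from_sizes(n_down=280, n_up=224, n_union=381)
        assert out["one_position_only"] == 258
        assert out["one_position_only_pct"] == pytest.approx(67.7, abs=0.05)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(ValueError):
            class_counts_from_sizes(10, 10, 25)


class TestCpGContent:
    def test_all_kmer_fraction_matches_enumeration(self):
        enumerated = sum(
            1 for k in itertools.product("ACGT", repeat=6) if "CG" in "".join(k)
        )
        assert enumerated == 1185
        out = cpg_content(["ACCGCT"], [b"ACGTACGTACGT" * 10])
        assert out["all_kmer_cpg_fraction"] == pytest.approx(1185 / 4096)

    def test_all_cg_motifs_give_unit_fraction(self):
        out = cpg_content(["CGAAAA", "CGTTTT"], [b"CGAAAACGTTTTCGAAAA" * 5])
        assert out["unique_motif_cpg_fraction"] == 1.0

    def test_instance_fractions_hand_case(self):
        # T-DMR sequence with known window composition
        seq = b"AAAAAAAACGAAAAAAA"  # 12 windows, those containing the CG: positions 3..9
        out = cpg_content(["AAAACG"], [seq])
        counts, total = count_kmers([seq])
        cg_windows = sum(
            counts[i] for i in range(N_KMERS) if "CG" in index_to_kmer(i)
        )
        assert out["tdmr_window_cpg_fraction"] == pytest.approx(cg_windows / total)
        assert out["motif_instance_cpg_fraction"] == 1.0

    def test_empty_motif_set_rejected(self):
        with pytest.raises(ValueError):
            cpg_content([], [b"ACGTACGT"])


class TestClusterConsensus:
    def test_single_kmer_is_its_own_consensus(self):
        clusters = cluster_consensus(["ACCGCT"])
        assert len(clusters) == 1
        assert clusters[0].consensus == "ACCGCT"

    def test_degenerate_column_uses_iupac(self):
        clusters = cluster_consensus(["CCGGAA", "CCGGCA"])
        assert len(clusters) == 1
        assert clusters[0].consensus == "CCGGMA"  # M = A/C

    def test_duplicates_collapse(self):
        clusters = cluster_consensus(["ACCGCT", "ACCGCT", "ACCGCT"])
        assert len(clusters) == 1
        assert clusters[0].kmers == ["ACCGCT"]

    def test_dissimilar_kmers_split(self):
        clusters = cluster_consensus(["AAAAAA", "CCCCCC", "GGGGGG"])
        assert len(clusters) == 3

    def test_shifted_kmers_cluster(self):
        # CCGGAA shifted by one vs CGGAAT: 5 matching positions at shift 1
        clusters = cluster_consensus(["CCGGAA", "CGGAAT"])
        assert len(clusters) == 1

    def test_pfm_columns_are_distributions(self):
        for cl in cluster_consensus(["CCGGAA", "CCGGCA", "CCTGCA"]):
            assert cl.pfm.sum(axis=1) == pytest.approx(1.0)

    def test_deterministic(self):
        kmers = ["CCGGAA", "CCGGCA", "ACCGCT", "TTTTTT"]
        a = cluster_consensus(kmers)
        b = cluster_consensus(list(reversed(kmers)))
        assert [c.consensus for c in a] == [c.consensus for c in b]


class TestPwmSimilarity:
    def test_consensus_kmer_scores_maximal(self):
        pwm = pwm_from_consensus("ACCGCT")
        scores, all_scores, _ = pwm_similarity(["ACCGCT"], pwm)
        assert scores.iloc[0] == pytest.approx(all_scores.max())

    def test_uniform_pwm_scores_equal(self):
        pwm = np.full((8, 4), 0.25)
        _, all_scores, _ = pwm_similarity(["ACCGCT"], pwm)
        assert np.ptp(all_scores) == pytest.approx(0.0)

    def test_offset_maximisation_matches_brute_force(self):
        rng = np.random.default_rng(6)
        pwm = rng.dirichlet(np.ones(4), size=9)
        kmer = "ACGTAC"
        scores, _, _ = pwm_similarity([kmer], pwm)
        logodds = np.log2(np.maximum(pwm, 1e-6) / 0.25)
        idx = [("ACGT").index(c) for c in kmer]
        brute = max(
            np.mean([logodds[o + i, idx[i]] for i in range(6)]) for o in range(4)
        )
        assert scores.iloc[0] == pytest.approx(brute)

    def test_enriched_set_shifts_distribution(self):
        pwm = pwm_from_consensus("CCGGAA")
        near = ["CCGGAA", "CCGGCA", "CCGGAT", "ACGGAA"]
        _, _, test = pwm_similarity(near, pwm)
        assert test.p_value < 0.01

    def test_short_pwm_rejected(self):
        with pytest.raises(ValueError):
            pwm_similarity(["ACCGCT"], np.full((4, 4), 0.25))


class TestPairDistance:
    def test_two_instances_single_distance(self):
        inst = pd.DataFrame(
            {"group": ["x", "x"], "kmer": ["ACCGCT"] * 2,
             "pos": [10, 16], "lo": [0, 0], "hi": [94, 94]}
        )
        res = pair_distance_test(inst, n_shuffles=10, seed=0)
        assert res.observed.tolist() == [6]
        assert res.n_pairs == 1

    def test_empty_when_no_cooccurrence(self):
        inst = pd.DataFrame(
            {"group": ["x", "y"], "kmer": ["ACCGCT"] * 2,
             "pos": [10, 16], "lo": [0, 0], "hi": [94, 94]}
        )
        assert pair_distance_test(inst, n_shuffles=10, seed=0).empty

    def test_shuffled_mean_matches_uniform_expectation(self):
        # 60 groups x 2 instances on [0, 994]: E|X-Y| = m(m+2)/(3(m+1))
        rows = []
        for g in range(60):
            rows += [
                {"group": f"g{g}", "kmer": "ACCGCT", "pos": 100, "lo": 0, "hi": 994},
                {"group": f"g{g}", "kmer": "ACCGCT", "pos": 120, "lo": 0, "hi": 994},
            ]
        res = pair_distance_test(pd.DataFrame(rows), n_shuffles=100, seed=1)
        m = 994
        expected = m * (m + 2) / (3 * (m + 1))
        assert res.shuffled_mean == pytest.approx(expected, rel=0.05)

    def test_clustered_instances_detected(self):
        rows = []
        for g in range(40):
            rows += [
                {"group": f"g{g}", "kmer": "ACCGCT", "pos": 500, "lo": 0, "hi": 994},
                {"group": f"g{g}", "kmer": "ACCGCT", "pos": 510, "lo": 0, "hi": 994},
            ]
        res = pair_distance_test(pd.DataFrame(rows), n_shuffles=100, seed=2)
        assert res.observed_mean == pytest.approx(10.0)
        assert res.p_smaller <= 1 / 101 + 1e-9

    def test_uniformly_planted_instances_are_null(self):
        rng = np.random.default_rng(7)
        rows = []
        for g in range(80):
            for pos in rng.integers(0, 995, size=2):
                rows.append({"group": f"g{g}", "kmer": "ACCGCT", "pos": int(pos), "lo": 0, "hi": 994})
        res = pair_distance_test(pd.DataFrame(rows), n_shuffles=100, seed=3)
        assert res.observed_mean == pytest.approx(res.shuffled_mean, rel=0.15)
        assert res.p_smaller > 0.05

    def test_instance_extraction_strand_aware(self):
        gs_plus = GroupSequence(
            seq=b"AAACCGCTAA", chrom="chr1", start=100, end=110, strand="+",
            exon_id="g:1", position="downstream", tdmr_id="T1",
        )
        # minus strand: genomic sequence is the revcomp of the gene-sense seq
        gs_minus = GroupSequence(
            seq=b"AAACCGCTAA", chrom="chr1", start=200, end=210, strand="-",
            exon_id="g:2", position="downstream", tdmr_id="T2",
        )
        inst = motif_instances([gs_plus, gs_minus], ["ACCGCT"])
        by_exon = inst.set_index("group")
        assert by_exon.loc[[("g:1", "downstream")], "pos"].iloc[0] == 102
        # offset 2 from the gene-sense 5' end = genomic end - offset - k
        assert by_exon.loc[[("g:2", "downstream")], "pos"].iloc[0] == 210 - 2 - 6
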