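"""Position- and regulation-stratified 6mer motif analysis.

T-DMR subsequences falling in the 1 kb flank upstream or downstream of an
alternatively spliced exon (gene-sense strand, no reverse-complement
pooling) form four foreground groups: {upstream, downstream} x {positive,
negative} regulation.  Every 6mer's occurrence count over overlapping
windows is compared with its frequency in a background built from the
flanks of randomly drawn exons, via a binomial upper tail; Benjamini-
Hochberg correction is applied per group over the 4096 k-mers and motifs
are called at FDR 1%.

Also here: the positional role logic (same role / one position only /
opposing), CpG-content fractions, hierarchical consensus clustering,
PWM similarity scoring and the motif-pair distance shuffle test.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu

from .stats import TestResult, bh_fdr, binomial_uppertail_many, two_proportion_test

K = 6
N_KMERS = 4 ** K
BASES = b"ACGT"
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE[_b] = _i
    _CODE[ord(chr(_b).lower())] = _i

_COMPLEMENT = bytes.maketrans(b"ACGTacgt", b"TGCAtgca")


def revcomp(seq: bytes) -> bytes:
    return seq.translate(_COMPLEMENT)[::-1]


def kmer_to_index(kmer: str | bytes) -> int:
    if isinstance(kmer, str):
        kmer = kmer.encode()
    if len(kmer) != K:
        raise ValueError(f"k-mer must have length {K}: {kmer!r}")
    codes = _CODE[np.frombuffer(kmer, dtype=np.uint8)]
    if (codes == 255).any():
        raise ValueError(f"k-mer contains non-ACGT characters: {kmer!r}")
    return int(codes @ (4 ** np.arange(K - 1, -1, -1)))


def index_to_kmer(idx: int) -> str:
    out = []
    for _ in range(K):
        out.append("ACGT"[idx % 4])
        idx //= 4
    return "".join(reversed(out))


ALL_KMERS = [index_to_kmer(i) for i in range(N_KMERS)]


def window_codes(seq: bytes) -> np.ndarray:
    """4096-space code of every overlapping 6-mer window; windows touching
    a non-ACGT base are dropped.  A sequence of length L yields L-5 windows."""
    arr = _CODE[np.frombuffer(bytes(seq), dtype=np.uint8)]
    if arr.size < K:
        return np.empty(0, dtype=np.int64)
    valid = arr != 255
    codes = np.zeros(arr.size - K + 1, dtype=np.int64)
    ok = np.ones(arr.size - K + 1, dtype=bool)
    for i in range(K):
        codes = codes * 4 + arr[i : arr.size - K + 1 + i]
        ok &= valid[i : arr.size - K + 1 + i]
    return codes[ok]


def count_kmers(seqs: Iterable[bytes]) -> tuple[np.ndarray, int]:
    """Occurrence count per 6mer (overlapping windows) and the total window
    count across all sequences."""
    counts = np.zeros(N_KMERS, dtype=np.int64)
    total = 0
    for seq in seqs:
        codes = window_codes(seq)
        total += codes.size
        if codes.size:
            counts += np.bincount(codes, minlength=N_KMERS)
    return counts, total


@dataclass
class BackgroundModel:
    """Background 6mer frequencies from random exon flanks."""

    f: np.ndarray
    total_windows: int
    n_sequences: int

    def __post_init__(self) -> None:
        if self.total_windows > 0 and not np.isclose(self.f.sum(), 1.0):
            raise ValueError("background frequencies must sum to 1")


def build_background(
    genes,
    sequences: Mapping[str, bytes | bytearray],
    n_exons: int = 10000,
    side: str = "downstream",
    flank: int = 1000,
    seed: int = 0,
) -> BackgroundModel:
    """6mer background from the 1 kb flank of randomly selected exons.

    Exons are drawn uniformly (with replacement when the annotation holds
    fewer than ``n_exons``); each contributes its gene-sense ``side`` flank,
    truncated at chromosome bounds.
    """
    if side not in ("upstream", "downstream"):
        raise ValueError(f"side must be upstream/downstream, got {side!r}")
    pool = [(g, i) for g in genes for i in range(g.n_exons)]
    if not pool:
        raise ValueError("annotation contains no exons")
    rng = np.random.default_rng(seed)
    replace = len(pool) < n_exons
    idx = rng.choice(len(pool), size=n_exons, replace=replace)
    seqs = []
    for j in idx:
        g, i = pool[j]
        iv = flank_window(g, i, side, flank, len(sequences[g.chrom]))
        if iv[1] > iv[0]:
            seqs.append(fetch(sequences, g.chrom, iv[0], iv[1], g.strand))
    counts, total = count_kmers(seqs)
    f = counts / total if total else np.zeros(N_KMERS)
    return BackgroundModel(f=f, total_windows=total, n_sequences=len(seqs))


def flank_window(gene, exon_index: int, side: str, flank: int, chrom_len: int) -> tuple[int, int]:
    """Genomic interval of the gene-sense upstream/downstream flank of an exon."""
    s, e = gene.exons[exon_index]
    before = (max(0, s - flank), s)
    after = (e, min(chrom_len, e + flank))
    if (side == "upstream") == (gene.strand == "+"):
        return before
    return after


def fetch(sequences: Mapping[str, bytes | bytearray], chrom: str, start: int, end: int, strand: str) -> bytes:
    seq = bytes(sequences[chrom][start:end])
    return revcomp(seq) if strand == "-" else seq


@dataclass
class GroupSequence:
    """One T-DMR subsequence assigned to a motif group."""

    seq: bytes
    chrom: str
    start: int
    end: int
    strand: str
    exon_id: str
    position: str
    tdmr_id: str


def extract_group_sequences(
    links: pd.DataFrame,
    tdmrs: Mapping[str, tuple[str, int, int]],
    genes_by_id: Mapping[str, "object"],
    sequences: Mapping[str, bytes | bytearray],
    flank: int = 1000,
) -> Dict[tuple[str, str], list[GroupSequence]]:
    """Foreground sequences per (position, regulation) group.

    ``links`` must carry tdmr_id, gene_id, exon_index, position and
    regulation columns (1 kb-mode links classified by regulation); each
    upstream/downstream link contributes the T-DMR clipped to the flank
    window, read on the gene-sense strand.
    """
    groups: Dict[tuple[str, str], list[GroupSequence]] = {}
    for row in links.itertuples():
        if row.position not in ("upstream", "downstream"):
            continue
        gene = genes_by_id[row.gene_id]
        chrom, ts, te = tdmrs[row.tdmr_id]
        win = flank_window(gene, int(row.exon_index), row.position, flank, len(sequences[chrom]))
        s, e = max(ts, win[0]), min(te, win[1])
        if e - s < K:
            continue
        gs = GroupSequence(
            seq=fetch(sequences, chrom, s, e, gene.strand),
            chrom=chrom,
            start=s,
            end=e,
            strand=gene.strand,
            exon_id=f"{row.gene_id}:{int(row.exon_index)}",
            position=row.position,
            tdmr_id=row.tdmr_id,
        )
        groups.setdefault((row.position, row.regulation), []).append(gs)
    return groups


def count_and_test(
    seqs: Sequence[bytes],
    background: BackgroundModel,
    fdr: float = 0.01,
    pseudocount: bool = False,
) -> pd.DataFrame:
    """Binomial enrichment of every 6mer in a foreground group.

    Returns one row per k-mer with M (foreground count), N (total windows),
    f (background frequency), the binomial upper-tail p, the BH q over all
    4096 k-mers and the significance flag at q < ``fdr``.  A k-mer absent
    from the background but present in the foreground gets p = 0 and is
    flagged, unless ``pseudocount`` substitutes 0.5/total background
    windows for the zero frequency.
    """
    counts, total = count_kmers(seqs)
    if total == 0:
        raise ValueError("foreground group has no 6mer windows")
    f = background.f.copy()
    flagged = (f == 0) & (counts > 0)
    if pseudocount and background.total_windows > 0:
        f = np.where(f == 0, 0.5 / background.total_windows, f)
        flagged = np.zeros_like(flagged)
    p = np.where((f == 0) & (counts > 0), 0.0, binomial_uppertail_many(counts, total, np.minimum(f, 1.0)))
    q = bh_fdr(p)
    return pd.DataFrame(
        {
            "kmer": ALL_KMERS,
            "M": counts,
            "N": total,
            "f": f,
            "p": p,
            "q": q,
            "significant": q < fdr,
            "zero_background": flagged,
        }
    )


def position_roles(pos_stats: Optional[pd.DataFrame], neg_stats: Optional[pd.DataFrame]) -> pd.Series:
    """Role of every k-mer at one position: positive, negative, dual or none.

    Dual means significant in both the positive- and negative-regulation
    group tests at that position.
    """
    sig_pos = pos_stats["significant"].to_numpy() if pos_stats is not None else np.zeros(N_KMERS, bool)
    sig_neg = neg_stats["significant"].to_numpy() if neg_stats is not None else np.zeros(N_KMERS, bool)
    roles = np.where(
        sig_pos & sig_neg, "dual", np.where(sig_pos, "positive", np.where(sig_neg, "negative", "none"))
    )
    return pd.Series(roles, index=ALL_KMERS, name="role")


def positional_comparison(up_roles: pd.Series, down_roles: pd.Series) -> tuple[pd.DataFrame, dict]:
    """Compare k-mer regulatory roles between upstream and downstream flanks.

    K-mers significant at either position partition into: same_role
    (identical non-none roles at both), one_position_only, and opposing
    (differing non-none roles, including dual-vs-single mismatches).
    """
    if not up_roles.index.equals(down_roles.index):
        raise ValueError("role tables must cover the same k-mer space")
    df = pd.DataFrame({"up": up_roles, "down": down_roles})
    df = df[(df["up"] != "none") | (df["down"] != "none")].copy()
    both = (df["up"] != "none") & (df["down"] != "none")
    df["cls"] = np.where(
        both & (df["up"] == df["down"]),
        "same_role",
        np.where(both, "opposing", "one_position_only"),
    )
    union = len(df)
    counts = {
        "n_up": int((df["up"] != "none").sum()),
        "n_down": int((df["down"] != "none").sum()),
        "n_union": union,
        "same_role": int((df["cls"] == "same_role").sum()),
        "one_position_only": int((df["cls"] == "one_position_only").sum()),
        "opposing": int((df["cls"] == "opposing").sum()),
    }
    for key in ("same_role", "one_position_only", "opposing"):
        counts[f"{key}_pct"] = 100.0 * counts[key] / union if union else float("nan")
    return df, counts


def class_counts_from_sizes(n_down: int, n_up: int, n_union: int) -> dict:
    """Positional class arithmetic from set sizes alone.

    With D k-mers significant downstream, U upstream and |D u U| = n_union,
    the number significant at exactly one position is 2|D u U| - D - U and
    the number at both is D + U - |D u U|.
    """
    if n_union > n_down + n_up or n_union < max(n_down, n_up):
        raise ValueError("inconsistent set sizes")
    one = 2 * n_union - n_down - n_up
    both = n_down + n_up - n_union
    return {
        "one_position_only": one,
        "both_positions": both,
        "one_position_only_pct": 100.0 * one / n_union if n_union else float("nan"),
    }


_CG_MASK = np.array([b"CG" in k.encode() for k in ALL_KMERS])


def cpg_content(significant_kmers: Sequence[str], tdmr_seqs: Sequence[bytes]) -> dict:
    """CpG-dinucleotide content of motifs vs the k-mer space and of motif
    instances vs all T-DMR windows.

    Returns the four fractions (unique significant k-mers containing CG;
    all 4096 k-mers containing CG; significant-motif instances in the
    T-DMR sequence containing CG; all T-DMR 6mer windows containing CG)
    plus two-proportion comparisons.
    """
    sig = sorted(set(significant_kmers))
    if not sig:
        raise ValueError("no significant motifs supplied")
    sig_idx = np.array([kmer_to_index(k) for k in sig])
    counts, total = count_kmers(tdmr_seqs)
    sig_cg = int(_CG_MASK[sig_idx].sum())
    all_cg = int(_CG_MASK.sum())
    inst_total = int(counts[sig_idx].sum())
    inst_cg = int(counts[sig_idx[_CG_MASK[sig_idx]]].sum())
    win_cg = int(counts[_CG_MASK].sum())
    out = {
        "unique_motif_cpg_fraction": sig_cg / len(sig),
        "all_kmer_cpg_fraction": all_cg / N_KMERS,
        "motif_instance_cpg_fraction": inst_cg / inst_total if inst_total else float("nan"),
        "tdmr_window_cpg_fraction": win_cg / total if total else float("nan"),
        "n_unique_motifs": len(sig),
        "n_motif_instances": inst_total,
        "n_tdmr_windows": total,
    }
    out["unique_vs_all_test"] = two_proportion_test(sig_cg, len(sig), all_cg, N_KMERS)
    if inst_total and total:
        out["instance_vs_window_test"] = two_proportion_test(inst_cg, inst_total, win_cg, total)
    return out


# --- consensus clustering ---------------------------------------------------

_IUPAC = {
    frozenset("A"): "A", frozenset("C"): "C", frozenset("G"): "G", frozenset("T"): "T",
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("GT"): "K", frozenset("AC"): "M", frozenset("CGT"): "B", frozenset("AGT"): "D",
    frozenset("ACT"): "H", frozenset("ACG"): "V", frozenset("ACGT"): "N",
}


def _best_alignment(a: str, b: str, max_shift: int = 2) -> tuple[int, int]:
    """(matches, shift) of the best ungapped alignment of b against a;
    ties prefer the smaller |shift|, then the smaller shift."""
    best = (-1, 0)
    for shift in sorted(range(-max_shift, max_shift + 1), key=lambda s: (abs(s), s)):
        m = sum(1 for i in range(max(0, shift), min(K, K + shift)) if a[i] == b[i - shift])
        if m > best[0]:
            best = (m, shift)
    return best


@dataclass
class MotifCluster:
    kmers: list[str]
    offsets: list[int]
    consensus: str
    pfm: np.ndarray = field(repr=False)


def cluster_consensus(
    kmers: Sequence[str],
    max_shift: int = 2,
    distance_threshold: float = 2.0,
) -> list[MotifCluster]:
    """Cluster similar 6mers and derive an IUPAC consensus per cluster.

    Pairwise distance is 6 minus the best ungapped match count over shifts
    in [-max_shift, max_shift]; average-linkage clustering is cut at
    ``distance_threshold``.  Each cluster's members are aligned to its
    lexicographically smallest k-mer and the consensus takes, per column
    covered by at least half the members, the IUPAC code of the most
    frequent base(s).
    """
    uniq = sorted(set(kmers))
    if not uniq:
        raise ValueError("no k-mers to cluster")
    if len(uniq) == 1:
        labels = np.array([1])
    else:
        n = len(uniq)
        dist = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            m, _ = _best_alignment(uniq[i], uniq[j], max_shift)
            dist[i, j] = dist[j, i] = K - m
        labels = fcluster(linkage(squareform(dist), method="average"), t=distance_threshold, criterion="distance")
    clusters = []
    for lab in sorted(set(labels)):
        members = [uniq[i] for i in range(len(uniq)) if labels[i] == lab]
        ref = members[0]
        offsets = [_best_alignment(ref, m, max_shift)[1] for m in members]
        lo, hi = min(offsets), max(offsets)
        width = K + hi - lo
        pfm = np.zeros((width, 4))
        for kmer, off in zip(members, offsets):
            for i, base in enumerate(kmer):
                pfm[i + off - lo, "ACGT".index(base)] += 1
        coverage = pfm.sum(axis=1)
        keep = coverage >= max(1, len(members) / 2)
        cons = []
        for row in pfm[keep]:
            top = row.max()
            bases = frozenset("ACGT"[i] for i in range(4) if row[i] == top)
            cons.append(_IUPAC[bases])
        total = pfm[keep].sum(axis=1, keepdims=True)
        clusters.append(
            MotifCluster(
                kmers=members,
                offsets=[o - lo for o in offsets],
                consensus="".join(cons),
                pfm=pfm[keep] / np.where(total == 0, 1, total),
            )
        )
    return clusters


# --- PWM similarity ---------------------------------------------------------

def pwm_similarity(
    kmers: Sequence[str],
    pwm: np.ndarray,
    floor: float = 1e-6,
) -> tuple[pd.Series, np.ndarray, TestResult]:
    """Log-odds similarity of k-mers against a PWM (rows = positions,
    columns = A,C,G,T probabilities).

    The score of a k-mer is the maximum over placements of the mean
    per-position log2 odds against a uniform background.  Returns the
    scores for ``kmers``, the score distribution over all 4096 k-mers, and
    a one-sided Mann-Whitney shift test that the supplied set scores
    higher than the full k-mer space.
    """
    pwm = np.asarray(pwm, dtype=float)
    if pwm.ndim != 2 or pwm.shape[1] != 4:
        raise ValueError("pwm must be (length, 4)")
    if pwm.shape[0] < K:
        raise ValueError(f"pwm shorter than {K}")
    logodds = np.log2(np.maximum(pwm, floor) / 0.25)
    all_codes = np.array([[_CODE[c] for c in k.encode()] for k in ALL_KMERS])
    n_off = pwm.shape[0] - K + 1
    per_offset = np.stack(
        [logodds[o : o + K, :][np.arange(K), all_codes].mean(axis=1) for o in range(n_off)]
    )
    all_scores = per_offset.max(axis=0)
    idx = [kmer_to_index(k) for k in kmers]
    scores = pd.Series(all_scores[idx], index=list(kmers), name="similarity")
    if len(set(kmers)) < N_KMERS and len(kmers) > 0:
        u, p = mannwhitneyu(scores.to_numpy(), all_scores, alternative="greater")
        test = TestResult(statistic=float(u), p_value=float(p), n=len(kmers) + N_KMERS)
    else:
        test = TestResult(statistic=0.0, p_value=1.0, n=N_KMERS)
    return scores, all_scores, test


def pwm_from_consensus(consensus: str, weight: float = 0.97) -> np.ndarray:
    """Near-deterministic PWM for a plain ACGT consensus string."""
    pwm = np.full((len(consensus), 4), (1 - weight) / 3)
    for i, base in enumerate(consensus):
        pwm[i, "ACGT".index(base)] = weight
    return pwm


# --- motif pair distances ---------------------------------------------------

@dataclass
class DistanceTest:
    """Observed vs shuffled pairwise motif-instance distances."""

    observed: np.ndarray
    observed_mean: float
    shuffled_means: np.ndarray
    shuffled_mean: float
    p_smaller: float
    n_pairs: int
    empty: bool = False


def motif_instances(
    group_seqs: Sequence[GroupSequence],
    significant_kmers: Sequence[str],
) -> pd.DataFrame:
    """Genomic start positions of significant-motif occurrences in group
    sequences, keyed by (exon_id, position) so pair distances are taken
    among the T-DMR(s) flanking the same AS exon side."""
    kset = [k.encode() for k in sorted(set(significant_kmers))]
    rows = []
    for gs in group_seqs:
        for kb in kset:
            off = gs.seq.find(kb)
            while off != -1:
                gpos = gs.start + off if gs.strand == "+" else gs.end - off - K
                rows.append(
                    {
                        "group": (gs.exon_id, gs.position),
                        "kmer": kb.decode(),
                        "pos": gpos,
                        "lo": gs.start,
                        "hi": gs.end - K,
                    }
                )
                off = gs.seq.find(kb, off + 1)
    return pd.DataFrame(rows, columns=["group", "kmer", "pos", "lo", "hi"])


def pair_distance_test(
    instances: pd.DataFrame,
    n_shuffles: int = 100,
    seed: int = 0,
) -> DistanceTest:
    """Shuffle test for clustering of motif instances.

    ``instances`` needs columns group, pos, lo, hi: observed pairwise
    |pos_i - pos_j| are pooled within each group; the null repositions each
    instance uniformly on [lo, hi] within its own sequence, ``n_shuffles``
    times.  ``p_smaller`` is the one-sided permutation p that the observed
    mean distance is smaller than expected.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    groups = [g for _, g in instances.groupby("group", sort=True) if len(g) >= 2]
    if not groups:
        return DistanceTest(np.empty(0), float("nan"), np.empty(0), float("nan"), float("nan"), 0, empty=True)
    rng = np.random.default_rng(seed)

    def pooled(posmap: list[np.ndarray]) -> np.ndarray:
        out = []
        for pos in posmap:
            d = np.abs(pos[:, None] - pos[None, :])
            out.append(d[np.triu_indices(len(pos), k=1)])
        return np.concatenate(out)

    obs = pooled([g["pos"].to_numpy() for g in groups])
    shuffled_means = np.empty(n_shuffles)
    for s in range(n_shuffles):
        sim = [
            rng.integers(g["lo"].to_numpy(), g["hi"].to_numpy() + 1)
            for g in groups
        ]
        shuffled_means[s] = pooled(sim).mean()
    observed_mean = float(obs.mean())
    p = (1 + int(np.sum(shuffled_means <= observed_mean))) / (n_shuffles + 1)
    return DistanceTest(
        observed=obs,
        observed_mean=observed_mean,
        shuffled_means=shuffled_means,
        shuffled_mean=float(shuffled_means.mean()),
        p_smaller=float(p),
        n_pairs=int(obs.size),
    )
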