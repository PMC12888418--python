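import itertools
import math

import numpy as np
import pytest

from asbkit._seq import BASES, de_bruijn_sequence, encode, revcomp, revcomp_matrix
from asbkit.errors import ConfigError, ValidationError
from asbkit.io import HetSNP, Motif, PeakSet
from asbkit.motifs import (
    classify_nopeak_motif,
    cluster_motifs,
    debruijn_similarity,
    fpr_threshold,
    logodds_scan,
    score_het_snp,
    trim_motif_edges,
)

from .conftest import one_hot_motif, random_motif


def brute_best_overlapping(motif, window, center):
    """Independent oracle: best score over strands and placements covering
    ``center``, computed with a plain double loop."""
    L = len(motif)
    best = -math.inf
    for strand_matrix in (motif.matrix, revcomp_matrix(motif.matrix)):
        for i in range(len(window) - L + 1):
            if not (i <= center <= i + L - 1):
                continue
            s = 0.0
            for j, base in enumerate(window[i : i + L]):
                if base not in BASES:
                    s = -math.inf
                    break
                s += math.log2(strand_matrix[j, BASES.index(base)] / 0.25)
            best = max(best, s)
    return best


class TestLogoddsScan:
    def test_uniform_motif_scores_zero(self):
        m = Motif(name="u", matrix=np.full((5, 4), 0.25))
        scores = logodds_scan(m, "ACGTACGTAC")
        np.testing.assert_allclose(scores, 0.0, atol=1e-12)

    def test_one_hot_hand_computed(self):
        m = one_hot_motif("AACG")  # non-palindromic
        scores = logodds_scan(m, "AACG")
        # perfect match: 4 * log2(1 / 0.25) = 8; mismatches hit log2(0) = -inf
        assert scores[0, 0] == pytest.approx(8.0)
        assert scores[0, 1] == -math.inf  # reverse strand mismatch

    def test_strand_symmetry(self, rng):
        m = random_motif(rng, 6)
        seq = "".join(rng.choice(list(BASES), 30))
        rc_m = Motif(name="rc", matrix=revcomp_matrix(m.matrix))
        fwd = logodds_scan(m, seq)
        rc_on_rc = logodds_scan(rc_m, revcomp(seq))
        np.testing.assert_allclose(np.max(fwd), np.max(rc_on_rc), atol=1e-9)

    def test_n_scores_minus_inf(self):
        m = one_hot_motif("ACGT", p_major=0.97)
        scores = logodds_scan(m, "ACNTACGT")
        assert scores[0, 0] == -math.inf

    def test_zero_background_rejected(self):
        m = one_hot_motif("ACGT", p_major=0.97)
        with pytest.raises(ValidationError):
            logodds_scan(m, "ACGTAC", background=np.array([0.5, 0.5, 0.0, 0.0]))


def enumerate_best_scores(motif, window_len):
    """All-window best scan scores, written independently of the scanner:
    base-4 digit enumeration plus an explicit placement/strand loop."""
    n = 4**window_len
    powers = 4 ** np.arange(window_len - 1, -1, -1, dtype=np.int64)
    digits = (np.arange(n, dtype=np.int64)[:, None] // powers[None, :]) % 4
    with np.errstate(divide="ignore"):
        log_fwd = np.log2(motif.matrix) - np.log2(0.25)
        log_rev = np.log2(motif.matrix[::-1, ::-1]) - np.log2(0.25)
    L = len(motif)
    best = np.full(n, -np.inf)
    for i in range(window_len - L + 1):
        for table in (log_fwd, log_rev):
            s = np.zeros(n)
            for j in range(L):
                s += table[j, digits[:, i + j]]
            best = np.maximum(best, s)
    return best


def brute_fpr_threshold(motif, window_len, fpr):
    """Independent oracle: exhaustive enumeration of every window."""
    best = enumerate_best_scores(motif, window_len)
    n = len(best)
    candidates = [u for u in np.unique(best) if (best >= u).sum() / n < fpr]
    if not candidates:
        return float(np.nextafter(best.max(), np.inf))
    return float(min(candidates))


class TestFprThreshold:
    @pytest.mark.parametrize("motif_len,window_len", [(4, 6), (5, 7), (6, 8)])
    def test_exact_equals_enumeration(self, rng, motif_len, window_len):
        m = random_motif(rng, motif_len)
        got = fpr_threshold(m, fpr=0.05, window_len=window_len, method="exact")
        expected = brute_fpr_threshold(m, window_len, 0.05)
        assert got == pytest.approx(expected, abs=1e-9)

    def test_property_exact_vs_enumeration_small(self, rng):
        for motif_len, window_len in [(4, 5), (5, 6), (6, 10)]:
            m = random_motif(rng, motif_len, name=f"p{motif_len}")
            got = fpr_threshold(m, fpr=0.1, window_len=window_len, method="exact")
            assert got == pytest.approx(brute_fpr_threshold(m, window_len, 0.1), abs=1e-9)

    def test_fpr_near_one_gives_smallest_achievable(self, rng):
        # the strict-inequality quantile cannot return the minimum itself
        # (its tail probability is exactly 1); the threshold must be the
        # smallest value whose exceedance probability drops below fpr
        m = random_motif(rng, 4)
        fpr = 0.999
        thr = fpr_threshold(m, fpr=fpr, window_len=6, method="exact")
        best = enumerate_best_scores(m, 6)
        n = len(best)
        assert (best >= thr).sum() / n < fpr
        lower = np.unique(best)
        lower = lower[lower < thr]
        if len(lower):
            assert (best >= lower[-1]).sum() / n >= fpr  # minimality

    def test_mc_deterministic(self, rng):
        m = random_motif(rng, 6)
        t1 = fpr_threshold(m, method="mc", seed=3, n_samples=5000, window_len=20)
        t2 = fpr_threshold(m, method="mc", seed=3, n_samples=5000, window_len=20)
        assert t1 == t2

    def test_invalid_fpr(self, rng):
        with pytest.raises(ConfigError):
            fpr_threshold(random_motif(rng, 4), fpr=0.0, window_len=6)

    def test_window_shorter_than_motif(self, rng):
        with pytest.raises(ConfigError):
            fpr_threshold(random_motif(rng, 8), window_len=6)


class TestScoreHetSnp:
    @pytest.fixture
    def setting(self, rng):
        motif = one_hot_motif("TGACTCAG", p_major=0.94)
        seq = "".join(rng.choice(list(BASES), 200))
        pos = 100  # 1-based; plant the motif so the SNP hits column 2 (0-based)
        seq = seq[: pos - 3] + "TGACTCAG" + seq[pos + 5 :]
        genome = {"chr1": seq}
        snp = HetSNP("rs1", "chr1", pos, "A", "C", 0.5, 0.99)
        peaks = PeakSet([("chr1", 50, 150)])
        return motif, genome, snp, peaks

    def test_matches_brute_force_oracle(self, setting):
        motif, genome, snp, peaks = setting
        sc = score_het_snp(motif, genome, snp, peaks, threshold=0.0)
        window = genome["chr1"][snp.pos - 26 : snp.pos + 25]
        center = 25
        ref_window = window[:center] + "A" + window[center + 1 :]
        alt_window = window[:center] + "C" + window[center + 1 :]
        assert sc.ref_score == pytest.approx(brute_best_overlapping(motif, ref_window, center))
        assert sc.alt_score == pytest.approx(brute_best_overlapping(motif, alt_window, center))
        assert sc.msd == sc.ref_score - sc.alt_score
        assert sc.msd > 0  # ALT destroys a high-information column
        assert sc.in_peak and sc.matches

    def test_allele_swap_flips_msd_exactly(self, setting):
        motif, genome, snp, peaks = setting
        swapped = HetSNP("rs1", "chr1", snp.pos, "C", "A", 0.5, 0.99)
        a = score_het_snp(motif, genome, snp, peaks, threshold=0.0)
        b = score_het_snp(motif, genome, swapped, peaks, threshold=0.0)
        assert a.msd == -b.msd

    def test_no_match_below_threshold(self, rng):
        motif = one_hot_motif("TGACTCAG", p_major=0.94)
        seq = "".join(rng.choice(list(BASES), 200))
        snp = HetSNP("rs1", "chr1", 100, seq[99] if seq[99] != "T" else "A",
                     "G" if seq[99] != "G" else "C", 0.5, 0.99)
        sc = score_het_snp(motif, {"chr1": seq}, snp, None, threshold=1e9)
        assert not sc.matches and not sc.in_peak

    def test_window_truncated_at_edge(self):
        motif = one_hot_motif("ACGT", p_major=0.94)
        snp = HetSNP("rs1", "chr1", 3, "A", "C", 0.5, 0.99)
        sc = score_het_snp(motif, {"chr1": "AAAAAAAAAACGTAAAAAA"}, snp, None, threshold=0.0)
        assert np.isfinite(sc.msd)


def profile_oracle(motif, k=7):
    """Independent per-position profile on the same substrate, plain loops."""
    from asbkit.motifs import _similarity_substrate

    codes = _similarity_substrate(k)
    mat = np.clip(motif.matrix, 1e-4, None)
    table = np.log2(mat) - np.log2(0.25)
    L = len(motif)
    out = np.empty(len(codes) - L + 1)
    for i in range(len(out)):
        s = 0.0
        for j in range(L):
            c = codes[i + j]
            s += table[j, c] if c < 4 else -math.inf
        out[i] = s
    return out


class TestDebruijnSimilarity:
    def test_self_similarity(self, rng):
        m = random_motif(rng, 8)
        res = debruijn_similarity(m, m)
        assert res.similarity == pytest.approx(1.0, abs=1e-9)
        assert res.best_offset == 0 and res.best_orientation == "forward"

    def test_reverse_complement_similarity(self, rng):
        m = random_motif(rng, 9)
        rc = Motif(name="rc", matrix=revcomp_matrix(m.matrix))
        res = debruijn_similarity(m, rc)
        assert res.similarity == pytest.approx(1.0, abs=1e-9)
        assert res.best_orientation == "reverse_complement"

    def test_dissimilar_one_hots(self):
        a = one_hot_motif("AAAAAA", p_major=0.97, name="A6")
        c = one_hot_motif("CCCCCC", p_major=0.97, name="C6")
        res = debruijn_similarity(a, c)
        assert res.similarity < 0.3
        # independent recomputation of the offset-0 correlation
        pa, pc = profile_oracle(a), profile_oracle(c)
        r0 = np.corrcoef(pa, pc)[0, 1]
        assert res.similarity >= r0 - 1e-9

    def test_symmetry_and_bounds(self, rng):
        a, b = random_motif(rng, 7, name="a"), random_motif(rng, 10, name="b")
        r_ab = debruijn_similarity(a, b)
        r_ba = debruijn_similarity(b, a)
        assert r_ab.similarity == pytest.approx(r_ba.similarity, abs=1e-9)
        assert -1.0 <= r_ab.similarity <= 1.0

    def test_invariant_to_rc_both(self, rng):
        a, b = random_motif(rng, 8, name="a"), random_motif(rng, 8, name="b")
        arc = Motif(name="arc", matrix=revcomp_matrix(a.matrix))
        brc = Motif(name="brc", matrix=revcomp_matrix(b.matrix))
        assert debruijn_similarity(arc, brc).similarity == pytest.approx(
            debruijn_similarity(a, b).similarity, abs=1e-9
        )

    def test_profile_matches_loop_oracle(self, rng):
        from asbkit.motifs import _similarity_profile

        m = random_motif(rng, 5)
        fast = _similarity_profile(m, 7, np.full(4, 0.25))
        slow = profile_oracle(m)
        np.testing.assert_allclose(fast, slow, atol=1e-9)


class TestTrimMotifEdges:
    def test_uniform_edges_removed(self):
        core = one_hot_motif("ACGT", p_major=0.97).matrix
        mat = np.vstack([np.full((1, 4), 0.25), core, np.full((1, 4), 0.25)])
        m = Motif(name="m", matrix=mat)
        trimmed = trim_motif_edges(m)
        assert len(trimmed) == 4
        np.testing.assert_allclose(trimmed.matrix, core)

    def test_one_hot_unchanged(self):
        m = one_hot_motif("ACGTAC")
        assert len(trim_motif_edges(m)) == 6

    def test_ic_pattern_trimmed_to_core(self):
        low = np.array([0.30, 0.25, 0.23, 0.22])  # IC ~ 0.01 bits
        high = np.array([0.94, 0.02, 0.02, 0.02])  # IC ~ 1.7 bits
        mat = np.vstack([low, low, *[high] * 4, low, low])
        m = Motif(name="m", matrix=mat / mat.sum(axis=1, keepdims=True))
        trimmed = trim_motif_edges(m, min_ic=0.25)
        assert len(trimmed) == 4
        ic = trimmed.information_content()
        assert np.all(ic > 1.0)

    def test_never_below_length_four(self):
        m = Motif(name="m", matrix=np.full((5, 4), 0.25))
        assert len(trim_motif_edges(m)) == 4


class TestClusterMotifs:
    def test_two_identical_merge(self, rng):
        m = random_motif(rng, 8, name="x1")
        m2 = Motif(name="x2", matrix=m.matrix.copy())
        reps = cluster_motifs([m, m2])
        assert len(reps) == 1
        np.testing.assert_allclose(reps[0].matrix, m.matrix, atol=1e-9)
        assert reps[0].name == "Average_1"

    def test_dissimilar_pass_through(self):
        a = one_hot_motif("AAAAAA", p_major=0.97, name="A6")
        c = one_hot_motif("CCCCCC", p_major=0.97, name="C6")
        reps = cluster_motifs([a, c])
        assert {r.name for r in reps} == {"A6", "C6"}

    def test_noisy_copies_recover_planted(self):
        rng = np.random.default_rng(3)
        truth = one_hot_motif("TGACTCAG", p_major=0.94, name="truth")
        noisy = []
        for i in range(3):
            jitter = np.vstack(
                [rng.dirichlet(truth.matrix[j] * 60) for j in range(len(truth))]
            )
            noisy.append(Motif(name=f"n{i}", matrix=jitter))
        reps = cluster_motifs(noisy)
        assert len(reps) == 1
        assert debruijn_similarity(reps[0], truth).similarity > 0.9

    def test_permutation_stable(self, rng):
        motifs = [random_motif(rng, 8, name=f"m{i}") for i in range(5)]
        truth = one_hot_motif("TGACTCAG", p_major=0.94, name="t0")
        near = Motif(name="t1", matrix=truth.matrix.copy())
        motifs += [truth, near]
        reps_a = cluster_motifs(motifs)
        reps_b = cluster_motifs(list(reversed(motifs)))
        names_a = sorted(r.name for r in reps_a)
        names_b = sorted(r.name for r in reps_b)
        assert names_a == names_b
        for ra, rb in zip(sorted(reps_a, key=lambda r: r.name),
                          sorted(reps_b, key=lambda r: r.name)):
            np.testing.assert_allclose(ra.matrix, rb.matrix, atol=1e-12)


class TestClassifyNopeak:
    @pytest.fixture
    def db(self):
        return [
            one_hot_motif("TGACTCAG", p_major=0.94, name="J1", tf="TF1"),
            one_hot_motif("CCCGGGCC", p_major=0.94, name="J2", tf="TF2"),
        ]

    def test_redundant(self, db):
        nopeak = Motif(name="n", matrix=db[0].matrix.copy(), source="NoPeak")
        assert classify_nopeak_motif(nopeak, db, "TF1") == "redundant"

    def test_accessory(self, db):
        nopeak = Motif(name="n", matrix=db[1].matrix.copy(), source="NoPeak")
        assert classify_nopeak_motif(nopeak, db, "TF1") == "accessory"

    def test_de_novo(self, db, rng):
        nopeak = one_hot_motif("ATATATAT", p_major=0.8, name="n", source="NoPeak")
        for jm in db:
            assert debruijn_similarity(nopeak, jm).similarity < 0.7
        assert classify_nopeak_motif(nopeak, db, "TF1") == "de_novo"

    def test_empty_db_rejected(self, rng):
        with pytest.raises(ValidationError):
            classify_nopeak_motif(random_motif(rng, 8), [], "TF1")
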