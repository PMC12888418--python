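"""PWM log-odds scanning, FPR thresholds, SNP-window scoring, motif similarity.

Scores are log2 odds of a window belonging to the motif versus a background
base distribution (uniform by default). Motif similarity follows the
de Bruijn-substrate approach: both motifs are scored along a fixed order-k
de Bruijn sequence concatenated with its own reverse complement (the combined
substrate is reverse-complement symmetric, which makes the similarity score
invariant to reverse-complementing both motifs), and the maximum Pearson
correlation over offsets and orientations is taken.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from ._seq import de_bruijn_cycle, encode, revcomp_matrix
from .errors import ConfigError, ValidationError
from .io import GenomeSource, HetSNP, Motif, PeakSet, load_genome

logger = logging.getLogger(__name__)

__all__ = [
    "SnpMotifScore",
    "SimilarityResult",
    "logodds_scan",
    "fpr_threshold",
    "score_het_snp",
    "debruijn_similarity",
    "trim_motif_edges",
    "cluster_motifs",
    "classify_nopeak_motif",
]

UNIFORM_BG = np.full(4, 0.25)

#: probability floor applied to motif matrices before log-odds scoring in the
#: similarity substrate, so one-hot (zero-probability) columns cannot generate
#: -inf profile entries that would break Pearson correlations.
SIMILARITY_PROB_FLOOR = 1e-4


@dataclass
class SnpMotifScore:
    """REF/ALT log-odds scores for one SNP against one motif."""

    snp_id: str
    motif_name: str
    ref_score: float
    alt_score: float
    msd: float  # ref_score - alt_score
    matches: bool
    in_peak: bool
    motif_class: str = "unclassified"
    motif_source: str = ""


@dataclass
class SimilarityResult:
    motif_a: str
    motif_b: str
    similarity: float
    best_offset: int
    best_orientation: str  # forward | reverse_complement


def _check_background(background: Optional[np.ndarray]) -> np.ndarray:
    if background is None:
        return UNIFORM_BG
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or np.any(bg < 0):
        raise ValidationError("background must be 4 nonnegative probabilities summing to 1")
    if np.any(bg == 0):
        raise ValidationError("background has a zero probability for some base")
    return bg


def _logodds_tables(matrix: np.ndarray, bg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward and reverse-complement log2-odds lookup tables, with a fifth
    column of -inf for unscorable (N) positions."""
    with np.errstate(divide="ignore"):
        lo = np.log2(matrix) - np.log2(bg)[None, :]
    lo_rc = revcomp_matrix(matrix)
    with np.errstate(divide="ignore"):
        lo_rc = np.log2(lo_rc) - np.log2(bg)[None, :]
    pad = np.full((len(lo), 1), -np.inf)
    return np.hstack([lo, pad]), np.hstack([lo_rc, pad])


def _scan_codes(codes: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Score all placements of a lookup table along an encoded sequence."""
    L = len(table)
    if len(codes) < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(codes, L)
    with np.errstate(invalid="ignore"):
        return table[np.arange(L)[None, :], windows].sum(axis=1)


def logodds_scan(
    motif: Motif, sequence: str, background: Optional[np.ndarray] = None
) -> np.ndarray:
    """Per-placement log2-odds scores on both strands.

    Returns an array of shape (n_placements, 2) whose columns are the forward
    and reverse-strand scores; placements containing an N score -inf.
    """
    bg = _check_background(background)
    if len(sequence) < len(motif):
        raise ValidationError("sequence shorter than motif")
    codes = encode(sequence)
    fwd_t, rc_t = _logodds_tables(motif.matrix, bg)
    return np.column_stack([_scan_codes(codes, fwd_t), _scan_codes(codes, rc_t)])


# ---------------------------------------------------------------------------
# FPR-calibrated match thresholds
# ---------------------------------------------------------------------------


def _best_scores_for_windows(windows: np.ndarray, fwd_t: np.ndarray, rc_t: np.ndarray):
    """Best (over placements and strands) score for each window row."""
    L = len(fwd_t)
    W = windows.shape[1]
    n_place = W - L + 1
    idx = np.arange(L)
    best = np.full(len(windows), -np.inf)
    for i in range(n_place):
        chunk = windows[:, i : i + L]
        s_f = fwd_t[idx[None, :], chunk].sum(axis=1)
        s_r = rc_t[idx[None, :], chunk].sum(axis=1)
        np.maximum(best, s_f, out=best)
        np.maximum(best, s_r, out=best)
    return best


def _threshold_from_distribution(scores: np.ndarray, weights: np.ndarray, fpr: float) -> float:
    """Smallest value t with P(best >= t) < fpr under the given distribution."""
    order = np.argsort(scores)
    s, w = scores[order], weights[order]
    uniq, first = np.unique(s, return_index=True)
    cum = np.concatenate([[0.0], np.cumsum(w)])
    total = cum[-1]
    tails = (total - cum[first]) / total  # P(best >= uniq[i])
    ok = np.nonzero(tails < fpr)[0]
    if len(ok) == 0:
        # even the maximum is reached too often; no finite score qualifies
        return float(np.nextafter(uniq[-1], np.inf))
    return float(uniq[ok[0]])


def fpr_threshold(
    motif: Motif,
    background: Optional[np.ndarray] = None,
    fpr: float = 0.05,
    window_len: int = 51,
    method: str = "auto",
    seed: int = 0,
    n_samples: int = 100_000,
) -> float:
    """Match threshold such that a random background window's best scan score
    reaches it with probability < ``fpr``.

    ``method='exact'`` enumerates all ``4**window_len`` windows (only permitted
    for motif length <= 8 and window length <= 12); otherwise a seeded
    Monte-Carlo estimate over ``n_samples`` windows is used. The returned value
    is the smallest achievable empirical quantile.
    """
    if not 0.0 < fpr < 1.0:
        raise ConfigError(f"fpr {fpr} outside (0, 1)")
    if window_len < len(motif):
        raise ConfigError(f"window_len {window_len} shorter than motif length {len(motif)}")
    bg = _check_background(background)
    if method == "auto":
        method = "exact" if (len(motif) <= 8 and window_len <= 12) else "mc"
    fwd_t, rc_t = _logodds_tables(motif.matrix, bg)

    if method == "exact":
        if len(motif) > 8 or window_len > 12:
            raise ConfigError("exact enumeration limited to motif length <= 8, window <= 12")
        n_windows = 4**window_len
        logbg = np.log(bg)
        chunk_size = 1 << 18
        all_scores, all_weights = [], []
        powers = 4 ** np.arange(window_len - 1, -1, -1, dtype=np.int64)
        for lo in range(0, n_windows, chunk_size):
            hi = min(lo + chunk_size, n_windows)
            ids = np.arange(lo, hi, dtype=np.int64)
            digits = ((ids[:, None] // powers[None, :]) % 4).astype(np.uint8)
            all_scores.append(_best_scores_for_windows(digits, fwd_t, rc_t))
            all_weights.append(np.exp(logbg[digits].sum(axis=1)))
        return _threshold_from_distribution(
            np.concatenate(all_scores), np.concatenate(all_weights), fpr
        )

    rng = np.random.default_rng(seed)
    scores = []
    remaining = n_samples
    while remaining > 0:
        m = min(remaining, 20_000)
        windows = rng.choice(4, size=(m, window_len), p=bg).astype(np.uint8)
        scores.append(_best_scores_for_windows(windows, fwd_t, rc_t))
        remaining -= m
    scores = np.concatenate(scores)
    return _threshold_from_distribution(scores, np.ones(len(scores)), fpr)


# ---------------------------------------------------------------------------
# SNP-window scoring and MSD
# ---------------------------------------------------------------------------


def score_het_snp(
    motif: Motif,
    genome,
    snp: HetSNP,
    peaks: Optional[PeakSet] = None,
    flank: int = 25,
    threshold: Optional[float] = None,
    background: Optional[np.ndarray] = None,
) -> SnpMotifScore:
    """Score the REF and ALT allele windows of a SNP against a motif.

    The window is the reference sequence +/- ``flank`` around the SNP with the
    central base forced to each allele in turn. Scores are maxima over both
    strands and all placements that overlap the central position; the MSD is
    ref_score - alt_score. ``matches`` is true when either allele's best score
    reaches ``threshold``.
    """
    bg = _check_background(background)
    gs = load_genome(genome)
    chrom_len = gs.length(snp.chrom)
    start0 = snp.pos - 1 - flank
    end0 = snp.pos + flank
    if start0 < 0 or end0 > chrom_len:
        logger.info("%s: +/-%d window truncated at chromosome edge", snp.snp_id, flank)
        start0 = max(0, start0)
        end0 = min(chrom_len, end0)
    window = gs.fetch(snp.chrom, start0, end0).upper()
    center = snp.pos - 1 - start0
    ref_base = window[center]
    if ref_base not in (snp.ref_allele, snp.alt_allele):
        logger.warning(
            "%s: reference base %s matches neither REF %s nor ALT %s; forcing alleles",
            snp.snp_id,
            ref_base,
            snp.ref_allele,
            snp.alt_allele,
        )

    L = len(motif)

    def best(allele: str) -> float:
        seq = window[:center] + allele + window[center + 1 :]
        scores = logodds_scan(motif, seq, bg)
        lo = max(0, center - L + 1)
        hi = min(len(scores) - 1, center)
        if hi < lo:
            return -math.inf
        sub = scores[lo : hi + 1]
        return float(np.max(sub)) if sub.size else -math.inf

    ref_score = best(snp.ref_allele)
    alt_score = best(snp.alt_allele)
    matches = False
    if threshold is not None:
        matches = max(ref_score, alt_score) >= threshold
    in_peak = peaks.contains(snp.chrom, snp.pos) if peaks is not None else False
    return SnpMotifScore(
        snp_id=snp.snp_id,
        motif_name=motif.name,
        ref_score=ref_score,
        alt_score=alt_score,
        msd=ref_score - alt_score,
        matches=matches,
        in_peak=in_peak,
        motif_class=motif.motif_class,
        motif_source=motif.source,
    )


# ---------------------------------------------------------------------------
# De Bruijn similarity, trimming, clustering, classification
# ---------------------------------------------------------------------------

_MAX_MOTIF_FOR_SUBSTRATE = 32


@lru_cache(maxsize=2)
def _similarity_substrate(k: int) -> np.ndarray:
    """Encoded rc-symmetric substrate: de Bruijn cycle (+ wrap) followed by its
    reverse complement."""
    from ._seq import revcomp

    lin = de_bruijn_cycle(k)
    lin = lin + lin[: k - 1 + _MAX_MOTIF_FOR_SUBSTRATE]
    t = lin + revcomp(lin)
    return encode(t)


def _similarity_profile(motif: Motif, k: int, background: np.ndarray) -> np.ndarray:
    matrix = np.clip(motif.matrix, SIMILARITY_PROB_FLOOR, None)
    with np.errstate(divide="ignore"):
        table = np.log2(matrix) - np.log2(background)[None, :]
    table = np.hstack([table, np.full((len(table), 1), -np.inf)])
    return _scan_codes(_similarity_substrate(k), table)


def _offset_correlations(pa: np.ndarray, pb: np.ndarray, max_abs_offset: int, min_overlap: int):
    """Yield (offset, pearson_r) for profile_a[i] vs profile_b[i+d] over the
    maximal index overlap (symmetric in the two profiles by construction)."""
    na, nb = len(pa), len(pb)
    for d in range(-max_abs_offset, max_abs_offset + 1):
        i_lo = max(0, -d)
        i_hi = min(na, nb - d)
        if i_hi - i_lo < min_overlap:
            continue
        a = pa[i_lo:i_hi]
        b = pb[i_lo + d : i_hi + d]
        if a.std() == 0 or b.std() == 0:
            yield d, 0.0
            continue
        yield d, float(np.corrcoef(a, b)[0, 1])


def debruijn_similarity(
    motif_a: Motif,
    motif_b: Motif,
    k: int = 7,
    background: Optional[np.ndarray] = None,
) -> SimilarityResult:
    """Maximum Pearson correlation between the motifs' de Bruijn score profiles
    over all offsets (|d| < max motif length) and both orientations of b.

    A zero-variance profile yields similarity 0 (logged).
    """
    bg = _check_background(background)
    if len(motif_a) > _MAX_MOTIF_FOR_SUBSTRATE or len(motif_b) > _MAX_MOTIF_FOR_SUBSTRATE:
        raise ValidationError(f"motif longer than {_MAX_MOTIF_FOR_SUBSTRATE} not supported")
    pa = _similarity_profile(motif_a, k, bg)
    pb = _similarity_profile(motif_b, k, bg)
    rc_b = Motif(
        name=motif_b.name,
        matrix=revcomp_matrix(motif_b.matrix),
        source=motif_b.source,
        tf=motif_b.tf,
    )
    pb_rc = _similarity_profile(rc_b, k, bg)

    if pa.std() == 0 or (pb.std() == 0 and pb_rc.std() == 0):
        logger.info(
            "similarity(%s, %s): zero-variance profile, defining similarity 0",
            motif_a.name,
            motif_b.name,
        )
        return SimilarityResult(motif_a.name, motif_b.name, 0.0, 0, "forward")

    # the extra |len_a - len_b| keeps the offset set closed under the index
    # mirror induced by reverse-complementing both motifs
    max_off = max(len(motif_a), len(motif_b)) - 1 + abs(len(motif_a) - len(motif_b))
    min_overlap = (4**k) // 2
    best = (-np.inf, 0, "forward")
    for orientation, profile in (("forward", pb), ("reverse_complement", pb_rc)):
        for d, r in _offset_correlations(pa, profile, max_off, min_overlap):
            # deterministic tie-breaks: higher r, then forward, then smaller |d|
            key = (r, orientation == "forward", -abs(d))
            cur = (best[0], best[2] == "forward", -abs(best[1]))
            if key > cur:
                best = (r, d, orientation)
    return SimilarityResult(motif_a.name, motif_b.name, float(best[0]), best[1], best[2])


def trim_motif_edges(motif: Motif, min_ic: float = 0.25) -> Motif:
    """Strip low-information columns (< ``min_ic`` bits) from both motif edges,
    never trimming below length 4."""
    ic = motif.information_content()
    lo, hi = 0, len(motif)
    while hi - lo > 4 and ic[lo] < min_ic:
        lo += 1
    while hi - lo > 4 and ic[hi - 1] < min_ic:
        hi -= 1
    if lo == 0 and hi == len(motif):
        return motif
    return Motif(
        name=motif.name,
        matrix=motif.matrix[lo:hi],
        source=motif.source,
        tf=motif.tf,
        kmer_support=motif.kmer_support,
        motif_class=motif.motif_class,
    )


def cluster_motifs(
    motifs: Sequence[Motif],
    threshold: float = 0.7,
    k: int = 7,
    background: Optional[np.ndarray] = None,
) -> list[Motif]:
    """Single-linkage clustering of motifs by de Bruijn similarity > threshold.

    Each multi-member cluster is replaced by the position-wise mean of its
    member matrices after aligning members to the cluster seed (the member with
    the lexicographically smallest name) at their best offset/orientation;
    positions not covered by a member are padded with the background before
    averaging. Singletons pass through unchanged. Representatives are named
    ``Average_<n>`` with a deterministic counter.
    """
    bg = _check_background(background)
    n = len(motifs)
    if n == 0:
        return []
    order = sorted(range(n), key=lambda i: motifs[i].name)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    sims: dict[tuple[int, int], SimilarityResult] = {}
    for ii, i in enumerate(order):
        for j in order[ii + 1 :]:
            res = debruijn_similarity(motifs[i], motifs[j], k=k, background=bg)
            sims[(i, j)] = sims[(j, i)] = res
            if res.similarity > threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)

    # deterministic cluster order: by smallest member name
    ordered = sorted(clusters.values(), key=lambda ms: min(motifs[m].name for m in ms))
    out: list[Motif] = []
    counter = 1
    for members in ordered:
        if len(members) == 1:
            out.append(motifs[members[0]])
            continue
        members = sorted(members, key=lambda m: motifs[m].name)
        seed = members[0]
        seed_m = motifs[seed]
        placements: list[tuple[np.ndarray, int]] = [(seed_m.matrix, 0)]
        for m in members[1:]:
            res = debruijn_similarity(seed_m, motifs[m], k=k, background=bg)
            mat = motifs[m].matrix
            if res.best_orientation == "reverse_complement":
                mat = revcomp_matrix(mat)
            # profile_b shifted by +d aligns with profile_a: member sits at -d
            placements.append((mat, -res.best_offset))
        starts = [off for _, off in placements]
        ends = [off + len(mat) for mat, off in placements]
        lo, hi = min(starts), max(ends)
        width = hi - lo
        stack = np.empty((len(placements), width, 4))
        for idx, (mat, off) in enumerate(placements):
            padded = np.tile(bg, (width, 1))
            padded[off - lo : off - lo + len(mat)] = mat
            stack[idx] = padded
        mean = stack.mean(axis=0)
        mean = mean / mean.sum(axis=1, keepdims=True)
        support = sum(motifs[m].kmer_support or 0 for m in members) or None
        out.append(
            Motif(
                name=f"Average_{counter}",
                matrix=mean,
                source="NoPeak",
                tf=seed_m.tf,
                kmer_support=support,
                motif_class="unclassified",
            )
        )
        counter += 1
    return out


def classify_nopeak_motif(
    nopeak_motif: Motif,
    jaspar_db: Sequence[Motif],
    target_tf: str,
    threshold: float = 0.7,
    k: int = 7,
    background: Optional[np.ndarray] = None,
) -> str:
    """Classify a discovered motif against a known-motif database.

    ``redundant`` when its best similarity > threshold is to a motif of the
    target TF (such motifs are excluded downstream); ``accessory`` when
    similarity > threshold only to motifs of other TFs; ``de_novo`` otherwise.
    """
    if not jaspar_db:
        raise ValidationError("jaspar_db is empty")
    best_sim, best_tf = -np.inf, None
    any_hit = False
    for jm in jaspar_db:
        res = debruijn_similarity(nopeak_motif, jm, k=k, background=background)
        if res.similarity > best_sim:
            best_sim, best_tf = res.similarity, jm.tf
        if res.similarity > threshold:
            any_hit = True
    if best_sim > threshold and best_tf == target_tf:
        return "redundant"
    if any_hit:
        return "accessory"
    return "de_novo"
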