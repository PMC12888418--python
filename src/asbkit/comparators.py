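"""MAF-matched empirical-null comparator sets and associated statistics.

The focal (e.g. high-quality ASB) SNP set is compared against resampled sets
of never-ASB, high-coverage SNPs matched on minor allele frequency within a
relative tolerance; observed statistics are referred to the resampled null
distribution with the positively-biased (r+1)/(n+1) empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError
from .inference import ASBCall
from .io import HetSNP

__all__ = [
    "ComparatorSets",
    "build_nonasb_pool",
    "sample_maf_matched",
    "empirical_pvalue",
    "conservation_counts",
    "rank_sum_test",
]


@dataclass
class ComparatorSets:
    target_ids: list[str]
    sampled_sets: list[list[str]]  # n_sets lists, each |targets| long
    median_set: list[str]
    seed: int


def build_nonasb_pool(
    all_tested_snps: Sequence[HetSNP],
    asb_calls: Sequence[ASBCall],
    min_reads: int = 100,
) -> list[HetSNP]:
    """Never-ASB SNPs with pooled read coverage >= ``min_reads``.

    A SNP id called ASB in ANY cell line or TF is excluded. Read coverage is
    the sum of ``total_counts`` over every call for that SNP id.
    """
    asb_ids = {c.snp_id for c in asb_calls if c.is_asb}
    totals: dict[str, int] = {}
    for c in asb_calls:
        totals[c.snp_id] = totals.get(c.snp_id, 0) + c.total_counts
    pool = [
        s
        for s in all_tested_snps
        if s.snp_id not in asb_ids and totals.get(s.snp_id, 0) >= min_reads
    ]
    if not pool:
        raise ValidationError(
            f"empty non-ASB pool at min_reads={min_reads}; relax the coverage threshold"
        )
    return pool


def sample_maf_matched(
    pool: Sequence[HetSNP],
    targets: Sequence[HetSNP],
    rel_tol: float = 0.05,
    n_sets: int = 1000,
    seed: int = 0,
) -> ComparatorSets:
    """Sample ``n_sets`` MAF-matched comparator sets with replacement.

    A pool SNP is a candidate for a target when |maf_c - maf_t| <=
    ``rel_tol * maf_t`` (a relative tolerance). The median set picks, per
    target, the drawn candidate with the (lower) median MAF across the
    ``n_sets`` draws. Fully deterministic given ``seed``.
    """
    pool_mafs = []
    for s in pool:
        if s.maf is None:
            raise ValidationError(f"pool SNP {s.snp_id} lacks a MAF annotation")
        pool_mafs.append(s.maf)
    pool_mafs = np.array(pool_mafs)
    pool_ids = [s.snp_id for s in pool]

    candidates: list[np.ndarray] = []
    unmatched = []
    for t in targets:
        if t.maf is None:
            raise ValidationError(f"target SNP {t.snp_id} lacks a MAF annotation")
        mask = np.abs(pool_mafs - t.maf) <= rel_tol * t.maf
        idx = np.nonzero(mask)[0]
        if len(idx) == 0:
            unmatched.append(t.snp_id)
        candidates.append(idx)
    if unmatched:
        raise ValidationError(f"targets with no MAF-matched pool candidate: {unmatched}")

    rng = np.random.default_rng(seed)
    n_t = len(targets)
    draws = np.empty((n_sets, n_t), dtype=np.int64)  # indices into pool
    for j, idx in enumerate(candidates):
        draws[:, j] = idx[rng.integers(0, len(idx), size=n_sets)]

    sampled_sets = [[pool_ids[i] for i in draws[s]] for s in range(n_sets)]

    median_set = []
    for j in range(n_t):
        chosen = draws[:, j]
        # lower median on even counts; deterministic tie-break by (maf, snp_id)
        order = sorted(chosen, key=lambda i: (pool_mafs[i], pool_ids[i]))
        median_set.append(pool_ids[order[(n_sets - 1) // 2]])

    return ComparatorSets(
        target_ids=[t.snp_id for t in targets],
        sampled_sets=sampled_sets,
        median_set=median_set,
        seed=seed,
    )


def empirical_pvalue(observed_stat: float, null_stats: Sequence[float], tail: str) -> float:
    """Empirical p-value (r+1)/(n+1) against a resampled null distribution."""
    null = np.asarray(null_stats, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    if tail == "greater":
        r = int(np.sum(null >= observed_stat))
    elif tail == "less":
        r = int(np.sum(null <= observed_stat))
    else:
        raise ValidationError(f"tail must be 'greater' or 'less', got {tail!r}")
    return (1 + r) / (1 + null.size)


class ConservationCounts(NamedTuple):
    n_conserved: int
    n_nonconserved: int
    n_missing: int


def conservation_counts(
    snps: Sequence[HetSNP], hi: float = 0.95, lo: float = 0.05
) -> ConservationCounts:
    """Counts of strictly conserved (score > hi) and non-conserved (score < lo)
    SNPs; missing scores are excluded and counted separately."""
    n_cons = n_non = n_missing = 0
    for s in snps:
        score = s.conservation_score
        if score is None:
            n_missing += 1
            continue
        if not 0.0 <= score <= 1.0:
            raise ValidationError(f"{s.snp_id}: conservation score {score} outside [0, 1]")
        if score > hi:
            n_cons += 1
        elif score < lo:
            n_non += 1
    return ConservationCounts(n_cons, n_non, n_missing)


def rank_sum_test(
    values_a: Sequence[float], values_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test with mid-ranks.

    Exact enumeration for small samples (both n <= 20; via permutation
    enumeration when ties are present), normal approximation with tie
    correction otherwise. Identical values across both groups give p = 1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be nonempty")
    if np.all(a == a[0]) and np.all(b == a[0]):
        u = a.size * b.size / 2.0
        return u, 1.0
    small = a.size <= 20 and b.size <= 20
    has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    if small and not has_ties:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    elif small and a.size <= 12 and b.size <= 12:
        # exact under ties: enumerate all group assignments
        method = stats.PermutationMethod(n_resamples=3_000_000, rng=0)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    else:
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)
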