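"""Bayesian beta-binomial inference of allele-specific binding.

The latent allelic balance ``beta`` (the corrected allelic ratio, CAR, after
copy-number and mapping-bias correction) has a flat Beta(1,1) prior. Each
replicate's REF-read probability is the odds composition

    theta = beta*raf*b / (beta*raf*b + (1-beta)*(1-raf)*(1-b))

with ``raf`` the reference allele frequency (copy-number proxy) and ``b`` the
reference-mapping bias, so that raf and b act as pure nuisance multipliers on
the odds scale and theta == beta when raf == b == 0.5. Replicate likelihoods
are beta-binomial with overdispersion ``phi`` (binomial when phi == 0).
Posterior sampling uses a Gaussian random walk Metropolis-Hastings on
logit(beta) with step-size adaptation restricted to burn-in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import betaln, expit

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "AllelicCount",
    "ModelConfig",
    "ASBCall",
    "compose_theta",
    "simulate_from_model",
    "infer_asb",
    "hpd_interval",
    "estimate_rm_bias",
    "estimate_overdispersion",
    "raf_from_bad",
    "extract_allelic_counts",
]


@dataclass(frozen=True)
class AllelicCount:
    """Per-replicate REF/ALT read counts at one heterozygous SNP."""

    snp_id: str
    replicate_id: str
    ref_count: int
    alt_count: int

    def __post_init__(self) -> None:
        if self.ref_count < 0 or self.alt_count < 0:
            raise ValidationError(f"{self.snp_id}: negative read counts")

    @property
    def total(self) -> int:
        return self.ref_count + self.alt_count


@dataclass
class ModelConfig:
    """Sampler and model settings for ASB inference."""

    rm_bias_b: float = 0.5
    dispersion_phi: float = 0.0
    n_iter: int = 5000
    n_burnin: int = 1000
    hpd_level: float = 0.95
    step: float = 0.3
    seed: int = 1234

    def __post_init__(self) -> None:
        if not 0.0 < self.rm_bias_b < 1.0:
            raise ValidationError(f"rm_bias_b {self.rm_bias_b} outside (0, 1)")
        if self.dispersion_phi < 0 or self.dispersion_phi >= 1:
            raise ValidationError(f"dispersion_phi {self.dispersion_phi} outside [0, 1)")
        if self.n_burnin >= self.n_iter:
            raise ValidationError("n_burnin must be < n_iter")
        if not 0.0 < self.hpd_level < 1.0:
            raise ValidationError(f"hpd_level {self.hpd_level} outside (0, 1)")


@dataclass
class ASBCall:
    """Posterior summary for one SNP: CAR, HPD interval and the ASB flag."""

    snp_id: str
    car: float
    hpd_lo: float
    hpd_hi: float
    is_asb: bool
    total_counts: int
    tf: str = ""
    cell_line: str = ""
    acceptance_rate: float = float("nan")
    warning: Optional[str] = None


def compose_theta(beta, raf, b):
    """Observed REF-read probability from balance beta, RAF and RM bias b."""
    num = beta * raf * b
    den = num + (1.0 - beta) * (1.0 - raf) * (1.0 - b)
    return num / den


def simulate_from_model(beta, raf, b, phi, n_reads, rng):
    """Draw (ref_count, alt_count) from the generative model used by infer_asb."""
    if n_reads <= 0:
        raise ValidationError("n_reads must be >= 1")
    theta = compose_theta(beta, raf, b)
    if phi > 0:
        a = theta * (1.0 / phi - 1.0)
        bb = (1.0 - theta) * (1.0 / phi - 1.0)
        p = rng.beta(a, bb)
    else:
        p = theta
    ref = int(rng.binomial(n_reads, p))
    return ref, n_reads - ref


def hpd_interval(samples: Sequence[float], level: float) -> tuple[float, float]:
    """Shortest contiguous window of ceil(level*n) sorted samples.

    Ties are broken by the earliest (leftmost) window. Requires >= 100 samples
    for a stable interval.
    """
    s = np.sort(np.asarray(samples, dtype=float))
    n = len(s)
    if n < 100:
        raise ValidationError(f"need >= 100 samples for a stable HPD, got {n}")
    if not 0.0 < level < 1.0:
        raise ValidationError(f"level {level} outside (0, 1)")
    m = int(math.ceil(level * n))
    if m >= n:
        return float(s[0]), float(s[-1])
    widths = s[m - 1 :] - s[: n - m + 1]
    i = int(np.argmin(widths))  # argmin returns the first minimum: earliest window
    return float(s[i]), float(s[i + m - 1])


def estimate_rm_bias(
    counts: Sequence[AllelicCount],
    trim_fraction: float = 0.1,
    min_total: int = 10,
    min_snps: int = 20,
) -> float:
    """Reference-mapping bias as a trimmed mean of per-SNP REF fractions.

    Counts are pooled per SNP across replicates; SNPs with fewer than
    ``min_total`` pooled reads are ignored. Falls back to 0.5 (logged) when
    fewer than ``min_snps`` SNPs are eligible.
    """
    from scipy.stats import trim_mean

    pooled: dict[str, list[int]] = {}
    for c in counts:
        acc = pooled.setdefault(c.snp_id, [0, 0])
        acc[0] += c.ref_count
        acc[1] += c.alt_count
    fractions = [
        r / (r + a) for r, a in pooled.values() if (r + a) >= min_total
    ]
    if len(fractions) < min_snps:
        logger.warning(
            "RM-bias estimation: only %d eligible SNPs (< %d); falling back to 0.5",
            len(fractions),
            min_snps,
        )
        return 0.5
    return float(trim_mean(fractions, trim_fraction))


def estimate_overdispersion(counts: Sequence[AllelicCount]) -> float:
    """Method-of-moments beta-binomial overdispersion across replicates.

    Returns 0 when fewer than 3 replicates carry reads (no between-replicate
    information) or when the between-replicate variance does not exceed the
    binomial expectation.
    """
    reps = [(c.ref_count, c.total) for c in counts if c.total > 0]
    if len(reps) < 3:
        return 0.0
    refs = np.array([r for r, _ in reps], dtype=float)
    ns = np.array([n for _, n in reps], dtype=float)
    p_hat = refs.sum() / ns.sum()
    if p_hat <= 0 or p_hat >= 1:
        return 0.0
    ps = refs / ns
    s2 = float(np.var(ps, ddof=1))
    mean_inv_n = float(np.mean(1.0 / ns))
    denom = p_hat * (1 - p_hat) * (1 - mean_inv_n)
    if denom <= 0:
        return 0.0
    phi = (s2 - p_hat * (1 - p_hat) * mean_inv_n) / denom
    return float(min(max(phi, 0.0), 0.9))


def raf_from_bad(mean_bad: float) -> float:
    """Convert a mean background allelic dosage to a reference allele frequency."""
    if mean_bad < 0:
        raise ValidationError(f"mean_bad {mean_bad} must be >= 0")
    return 1.0 / (mean_bad + 1.0)


def _make_loglik(refs: np.ndarray, alts: np.ndarray, raf: float, b: float, phi: float):
    """Log-likelihood of beta given per-replicate counts (constants dropped)."""
    if phi == 0.0:

        def loglik(beta: float) -> float:
            theta = compose_theta(beta, raf, b)
            return float(refs.sum() * math.log(theta) + alts.sum() * math.log1p(-theta))

    else:
        c = 1.0 / phi - 1.0

        def loglik(beta: float) -> float:
            theta = compose_theta(beta, raf, b)
            a0 = theta * c
            b0 = (1.0 - theta) * c
            return float(np.sum(betaln(refs + a0, alts + b0)) - len(refs) * betaln(a0, b0))

    return loglik


def infer_asb(
    counts: Sequence[AllelicCount],
    raf: float,
    config: ModelConfig,
    tf: str = "",
    cell_line: str = "",
    return_samples: bool = False,
):
    """Infer the corrected allelic ratio and ASB status for one SNP.

    CAR is the posterior median of beta; the HPD interval is the shortest
    window holding ``config.hpd_level`` of the post-burn-in samples; the SNP is
    an ASB when that interval excludes 0.5. Deterministic given
    ``config.seed``.
    """
    if not counts:
        raise ValidationError("no allelic counts supplied")
    if not 0.0 < raf < 1.0:
        raise ValidationError(f"raf {raf} is not heterozygous-compatible (must be in (0,1))")
    refs = np.array([c.ref_count for c in counts], dtype=float)
    alts = np.array([c.alt_count for c in counts], dtype=float)
    if np.all(refs + alts < 1):
        raise ValidationError("every replicate has zero reads")
    snp_id = counts[0].snp_id

    loglik = _make_loglik(refs, alts, raf, config.rm_bias_b, config.dispersion_phi)

    def logpost(x: float) -> float:
        beta = expit(x)
        if beta <= 0.0 or beta >= 1.0:
            return -math.inf
        # flat Beta(1,1) prior on beta + Jacobian of the logit transform
        return loglik(beta) + math.log(beta) + math.log1p(-beta)

    rng = np.random.default_rng(config.seed)
    n_iter, n_burnin = config.n_iter, config.n_burnin
    normals = rng.standard_normal(n_iter)
    log_unifs = np.log(rng.random(n_iter))

    x = 0.0  # beta = 0.5
    lp = logpost(x)
    step = config.step
    samples = np.empty(n_iter - n_burnin)
    accepted_post = 0
    accepted_window = 0
    for i in range(n_iter):
        prop = x + step * normals[i]
        lp_prop = logpost(prop)
        if lp_prop - lp >= log_unifs[i]:
            x, lp = prop, lp_prop
            if i >= n_burnin:
                accepted_post += 1
            else:
                accepted_window += 1
        if i < n_burnin and (i + 1) % 100 == 0:
            # adapt only during burn-in so post-burn-in kernel is fixed
            rate = accepted_window / 100.0
            if rate < 0.2:
                step *= 0.7
            elif rate > 0.5:
                step *= 1.4
            accepted_window = 0
        if i >= n_burnin:
            samples[i - n_burnin] = expit(x)

    acc_rate = accepted_post / (n_iter - n_burnin)
    warning = None
    if not 0.05 <= acc_rate <= 0.8:
        warning = f"acceptance rate {acc_rate:.3f} outside [0.05, 0.8] after adaptation"
        logger.warning("%s: %s", snp_id, warning)

    car = float(np.median(samples))
    lo, hi = hpd_interval(samples, config.hpd_level)
    call = ASBCall(
        snp_id=snp_id,
        car=car,
        hpd_lo=lo,
        hpd_hi=hi,
        is_asb=bool(hi < 0.5 or lo > 0.5),
        total_counts=int(refs.sum() + alts.sum()),
        tf=tf,
        cell_line=cell_line,
        acceptance_rate=acc_rate,
        warning=warning,
    )
    if return_samples:
        return call, samples
    return call


def _count_one_alignment(af, het_snps, min_base_quality, exclude_duplicates):
    refs = set(af.references)
    missing = sorted({s.chrom for s in het_snps} - refs)
    if missing:
        raise ValidationError(f"chromosomes in SNP table absent from alignments: {missing}")
    # unmapped/secondary/qcfail always excluded; duplicates only on request
    flag_filter = 0x4 | 0x100 | 0x200
    if exclude_duplicates:
        flag_filter |= 0x400
    counts: dict[str, tuple[int, int]] = {}
    for snp in het_snps:
        ref_n = alt_n = 0
        for col in af.pileup(
            snp.chrom,
            snp.pos - 1,
            snp.pos,
            truncate=True,
            min_base_quality=min_base_quality,
            ignore_overlaps=False,
            flag_filter=flag_filter,
        ):
            for pr in col.pileups:
                if pr.is_del or pr.is_refskip or pr.query_position is None:
                    continue
                aln = pr.alignment
                if exclude_duplicates and aln.is_duplicate:
                    continue
                base = aln.query_sequence[pr.query_position].upper()
                if base == snp.ref_allele:
                    ref_n += 1
                elif base == snp.alt_allele:
                    alt_n += 1
        counts[snp.snp_id] = (ref_n, alt_n)
    return counts


def extract_allelic_counts(
    alignments,
    het_snps,
    min_base_quality: int = 20,
    exclude_duplicates: bool = True,
) -> list[AllelicCount]:
    """Count REF/ALT reads per SNP per replicate from indexed alignments.

    ``alignments`` is a single BAM/CRAM path (one replicate) or a mapping
    ``{replicate_id: path}``. Files must be coordinate-sorted and indexed.
    Bases other than REF/ALT are ignored; duplicate-flagged reads are skipped
    when ``exclude_duplicates``. SNPs lacking at least one read on EACH allele
    in the counts pooled across replicates are dropped entirely. A chromosome
    present in the SNP table but absent from an alignment header is an error
    listing the offenders.
    """
    import pysam

    if not isinstance(alignments, dict):
        alignments = {"rep1": alignments}

    per_rep: dict[str, dict[str, tuple[int, int]]] = {}
    for rep_id, source in alignments.items():
        if isinstance(source, pysam.AlignmentFile):
            af, own = source, False
        else:
            af, own = pysam.AlignmentFile(str(source)), True
        try:
            if not af.has_index():
                raise ValidationError(f"alignment file for {rep_id!r} has no index")
            per_rep[rep_id] = _count_one_alignment(
                af, het_snps, min_base_quality, exclude_duplicates
            )
        finally:
            if own:
                af.close()

    out: list[AllelicCount] = []
    for snp in het_snps:
        pooled_ref = sum(per_rep[r][snp.snp_id][0] for r in per_rep)
        pooled_alt = sum(per_rep[r][snp.snp_id][1] for r in per_rep)
        if pooled_ref < 1 or pooled_alt < 1:
            continue  # coverage required on both alleles
        for rep_id in per_rep:
            ref_n, alt_n = per_rep[rep_id][snp.snp_id]
            if ref_n + alt_n >= 1:
                out.append(
                    AllelicCount(
                        snp_id=snp.snp_id,
                        replicate_id=rep_id,
                        ref_count=ref_n,
                        alt_count=alt_n,
                    )
                )
    return out
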