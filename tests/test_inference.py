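import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

from asbkit.errors import ValidationError
from asbkit.inference import (
    AllelicCount,
    ASBCall,
    ModelConfig,
    compose_theta,
    estimate_rm_bias,
    extract_allelic_counts,
    hpd_interval,
    infer_asb,
    raf_from_bad,
    simulate_from_model,
)


def fast_config(**kwargs):
    return ModelConfig(n_iter=4000, n_burnin=800, **kwargs)


def grid_posterior_median(ref, alt, raf, b, n_grid=10_001):
    """Independent oracle: posterior median of beta by grid integration with
    the exact binomial likelihood."""
    grid = np.linspace(0, 1, n_grid)[1:-1]
    theta = (grid * raf * b) / (grid * raf * b + (1 - grid) * (1 - raf) * (1 - b))
    loglik = ref * np.log(theta) + alt * np.log1p(-theta)
    w = np.exp(loglik - loglik.max())
    cdf = np.cumsum(w) / w.sum()
    return float(np.interp(0.5, cdf, grid))


def analytic_beta_hpd(a, b, level):
    """Independent oracle: HPD of a Beta(a, b) by density-level root finding."""
    mode = (a - 1) / (a + b - 2)

    def mass_above(h):
        lo = brentq(lambda x: beta_dist.pdf(x, a, b) - h, 1e-12, mode)
        hi = brentq(lambda x: beta_dist.pdf(x, a, b) - h, mode, 1 - 1e-12)
        return beta_dist.cdf(hi, a, b) - beta_dist.cdf(lo, a, b), lo, hi

    peak = beta_dist.pdf(mode, a, b)
    h = brentq(lambda x: mass_above(x)[0] - level, 1e-9, peak * (1 - 1e-9))
    _, lo, hi = mass_above(h)
    return lo, hi


class TestComposeTheta:
    def test_neutral_when_raf_and_bias_half(self):
        for beta in (0.1, 0.5, 0.9):
            assert compose_theta(beta, 0.5, 0.5) == pytest.approx(beta)

    def test_raf_shifts_theta(self):
        assert compose_theta(0.5, 0.75, 0.5) == pytest.approx(0.75)


class TestInferAsb:
    def test_symmetric_null(self):
        call = infer_asb([AllelicCount("s", "r", 500, 500)], 0.5, fast_config())
        assert abs(call.car - 0.5) < 0.02
        assert not call.is_asb

    def test_strong_imbalance_matches_grid_oracle(self):
        call = infer_asb([AllelicCount("s", "r", 90, 10)], 0.5, fast_config())
        assert call.is_asb
        assert call.car == pytest.approx(0.9, abs=0.03)
        oracle = grid_posterior_median(90, 10, 0.5, 0.5)
        assert call.car == pytest.approx(oracle, abs=0.01)

    def test_cnv_correction_prevents_false_call(self):
        # counts generated from beta = 0.5 with raf = 0.75 (theta = 0.75)
        rng = np.random.default_rng(7)
        ref, alt = simulate_from_model(0.5, 0.75, 0.5, 0.0, 100, rng)
        corrected = infer_asb([AllelicCount("s", "r", ref, alt)], 0.75, fast_config())
        uncorrected = infer_asb([AllelicCount("s", "r", ref, alt)], 0.5, fast_config())
        assert abs(corrected.car - 0.5) < 0.1
        assert not corrected.is_asb
        assert uncorrected.is_asb  # naive analysis mistakes CNV for ASB

    def test_raf_zero_or_one_rejected(self):
        for raf in (0.0, 1.0):
            with pytest.raises(ValidationError):
                infer_asb([AllelicCount("s", "r", 5, 5)], raf, fast_config())

    def test_deterministic_given_seed(self):
        counts = [AllelicCount("s", "r1", 30, 20), AllelicCount("s", "r2", 25, 25)]
        a = infer_asb(counts, 0.5, fast_config(seed=5))
        b = infer_asb(counts, 0.5, fast_config(seed=5))
        assert a == b

    def test_monotone_in_ref_count(self):
        cars = [
            infer_asb([AllelicCount("s", "r", ref, 30)], 0.5, fast_config()).car
            for ref in (10, 30, 60, 120)
        ]
        assert cars == sorted(cars)

    def test_label_swap_symmetry(self):
        cfg = fast_config(rm_bias_b=0.6)
        cfg_sw = fast_config(rm_bias_b=0.4)
        a = infer_asb([AllelicCount("s", "r", 70, 30)], 0.65, cfg)
        b = infer_asb([AllelicCount("s", "r", 30, 70)], 0.35, cfg_sw)
        assert a.car == pytest.approx(1 - b.car, abs=0.02)

    def test_overdispersed_likelihood_widens_interval(self):
        counts = [AllelicCount("s", "r", 70, 30)]
        tight = infer_asb(counts, 0.5, fast_config(dispersion_phi=0.0))
        wide = infer_asb(counts, 0.5, fast_config(dispersion_phi=0.1))
        assert (wide.hpd_hi - wide.hpd_lo) > (tight.hpd_hi - tight.hpd_lo)


class TestHpdInterval:
    def test_uniform_grid(self):
        samples = np.linspace(0.001, 0.999, 999)
        lo, hi = hpd_interval(samples, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.01)
        assert lo < 0.5 < hi

    def test_matches_analytic_beta_hpd(self, rng):
        samples = rng.beta(20, 2, size=40_000)
        lo, hi = hpd_interval(samples, 0.95)
        exp_lo, exp_hi = analytic_beta_hpd(20, 2, 0.95)
        assert lo == pytest.approx(exp_lo, abs=0.01)
        assert hi == pytest.approx(exp_hi, abs=0.01)

    def test_degenerate_samples(self):
        lo, hi = hpd_interval(np.full(200, 0.3), 0.95)
        assert (lo, hi) == (0.3, 0.3)

    def test_too_few_samples(self):
        with pytest.raises(ValidationError):
            hpd_interval(np.linspace(0, 1, 99), 0.95)


class TestRmBias:
    def test_all_half(self):
        counts = [AllelicCount(f"s{i}", "r", 25, 25) for i in range(30)]
        assert estimate_rm_bias(counts) == pytest.approx(0.5)

    def test_outliers_trimmed(self):
        counts = [AllelicCount(f"s{i}", "r", 52, 48) for i in range(98)]
        counts.append(AllelicCount("hi", "r", 99, 1))
        counts.append(AllelicCount("lo", "r", 1, 99))
        assert estimate_rm_bias(counts, trim_fraction=0.1) == pytest.approx(0.52)

    def test_fallback_with_few_snps(self):
        counts = [AllelicCount(f"s{i}", "r", 30, 20) for i in range(5)]
        assert estimate_rm_bias(counts) == 0.5

    def test_empty_input(self):
        assert estimate_rm_bias([]) == 0.5

    def test_low_coverage_snps_ignored(self):
        eligible = [AllelicCount(f"s{i}", "r", 6, 4) for i in range(25)]
        noise = [AllelicCount(f"n{i}", "r", 3, 0) for i in range(50)]  # total < 10
        assert estimate_rm_bias(eligible + noise) == pytest.approx(0.6)


class TestRafFromBad:
    @pytest.mark.parametrize("bad,expected", [(1, 0.5), (0, 1.0), (3, 0.25)])
    def test_formula(self, bad, expected):
        assert raf_from_bad(bad) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            raf_from_bad(-0.1)


def make_bam(path, reads, chrom="chr1", chrom_len=1000):
    """Write a sorted, indexed BAM from (name, pos0, seq, is_dup) tuples."""
    import pysam

    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": chrom_len}]}
    reads = sorted(reads, key=lambda r: r[1])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for name, pos0, seq, is_dup in reads:
            a = pysam.AlignedSegment()
            a.query_name = name
            a.query_sequence = seq
            a.reference_id = 0
            a.reference_start = pos0
            a.mapping_quality = 60
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            a.flag = 1024 if is_dup else 0
            bam.write(a)
    pysam.index(str(path))


class TestExtractAllelicCounts:
    snp = None

    @pytest.fixture
    def het_snp(self):
        from asbkit.io import HetSNP

        return HetSNP("rs1", "chr1", 101, "A", "G", 0.5, 0.99)  # 0-based 100

    def test_counts_match_brute_force(self, tmp_path, het_snp):
        reads = []
        for i in range(7):
            reads.append((f"ref{i}", 95, "CCCCC" + "A" + "CCCCC", False))
        for i in range(3):
            reads.append((f"alt{i}", 98, "CC" + "G" + "CCCCC", False))
        reads.append(("dup", 95, "CCCCC" + "A" + "CCCCC", True))  # duplicate skipped
        reads.append(("third", 95, "CCCCC" + "T" + "CCCCC", False))  # neither allele
        bam = tmp_path / "a.bam"
        make_bam(bam, reads)
        counts = extract_allelic_counts(bam, [het_snp])
        assert len(counts) == 1
        assert (counts[0].ref_count, counts[0].alt_count) == (7, 3)

    def test_duplicates_kept_when_requested(self, tmp_path, het_snp):
        reads = [
            ("r1", 95, "CCCCCACCCCC", False),
            ("r2", 95, "CCCCCGCCCCC", False),
            ("dup", 95, "CCCCCACCCCC", True),
        ]
        bam = tmp_path / "a.bam"
        make_bam(bam, reads)
        counts = extract_allelic_counts(bam, [het_snp], exclude_duplicates=False)
        assert (counts[0].ref_count, counts[0].alt_count) == (2, 1)

    def test_single_allele_coverage_dropped(self, tmp_path, het_snp):
        reads = [(f"r{i}", 95, "CCCCCACCCCC", False) for i in range(10)]
        bam = tmp_path / "a.bam"
        make_bam(bam, reads)
        assert extract_allelic_counts(bam, [het_snp]) == []

    def test_third_allele_only_dropped(self, tmp_path, het_snp):
        reads = [(f"r{i}", 95, "CCCCCTCCCCC", False) for i in range(5)]
        bam = tmp_path / "a.bam"
        make_bam(bam, reads)
        assert extract_allelic_counts(bam, [het_snp]) == []

    def test_missing_index_errors(self, tmp_path, het_snp):
        bam = tmp_path / "a.bam"
        make_bam(bam, [("r", 95, "CCCCCACCCCC", False)])
        (tmp_path / "a.bam.bai").unlink()
        with pytest.raises(ValidationError, match="index"):
            extract_allelic_counts(bam, [het_snp])

    def test_chromosome_mismatch_lists_offenders(self, tmp_path):
        from asbkit.io import HetSNP

        bam = tmp_path / "a.bam"
        make_bam(bam, [("r", 95, "CCCCCACCCCC", False)])
        snp = HetSNP("rs9", "chr9", 101, "A", "G", 0.5, 0.99)
        with pytest.raises(ValidationError, match="chr9"):
            extract_allelic_counts(bam, [snp])

    def test_pooled_both_allele_rule_across_replicates(self, tmp_path, het_snp):
        bam1 = tmp_path / "r1.bam"
        bam2 = tmp_path / "r2.bam"
        make_bam(bam1, [(f"r{i}", 95, "CCCCCACCCCC", False) for i in range(4)])
        make_bam(bam2, [("x", 95, "CCCCCGCCCCC", False)])
        counts = extract_allelic_counts({"r1": bam1, "r2": bam2}, [het_snp])
        assert {(c.replicate_id, c.ref_count, c.alt_count) for c in counts} == {
            ("r1", 4, 0),
            ("r2", 0, 1),
        }
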