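"""Deterministic synthetic fixture generation for end-to-end testing.

Generates a miniature dataset — genome, motif database, heterozygous SNPs,
peaks, allelic counts, annotations and (optionally) read 5'-end intervals —
with planted motif-disrupting allele-specific binding sites whose ground-truth
latent quantities are recorded in a truth table. The planted effect encodes
the concordance premise: the true allelic balance is a logistic function of
the motif score difference, so CAR~MSD concordance holds by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._seq import BASES
from .errors import ValidationError
from .inference import compose_theta, simulate_from_model
from .io import (
    GenomeSource,
    HetSNP,
    Motif,
    PeakSet,
    write_counts_tsv,
    write_het_snps,
    write_jaspar_pfm,
)

__all__ = ["FixtureSpec", "FixtureBundle", "default_planted_motif", "generate_fixture", "simulate_counts"]


def default_planted_motif(name: str = "MA9001.1", tf: str = "TF1") -> Motif:
    """A strong 8-column planted motif (consensus TGACTCAG, p=0.94 per column)."""
    consensus = "TGACTCAG"
    p_major, p_minor = 0.94, 0.02
    matrix = np.full((len(consensus), 4), p_minor)
    for i, b in enumerate(consensus):
        matrix[i, BASES.index(b)] = p_major
    return Motif(name=name, matrix=matrix, source="JASPAR", tf=tf, motif_class="canonical")


@dataclass
class FixtureSpec:
    """Knobs for the synthetic dataset generator."""

    genome_len: int = 30_000
    n_snps: int = 200
    n_planted_asb: int = 30
    planted_motif: Motif = field(default_factory=default_planted_motif)
    effect_slope: float = 0.15  # true beta = logistic(slope * MSD)
    coverage_mean: float = 100.0  # mean reads per replicate
    raf_distortion: float = 0.2  # fraction of SNPs with raf != 0.5 (CNV mimic)
    rm_bias_true: float = 0.5
    dispersion_phi: float = 0.0
    n_replicates: int = 3
    peak_halfwidth: int = 50
    n_extra_motif_sites: int = 60  # motif instances without SNPs (for discovery)
    tf: str = "TF1"
    cell_line: str = "CL1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted_asb > self.n_snps:
            raise ValidationError("n_planted_asb > n_snps")
        if self.coverage_mean < 20:
            raise ValidationError("coverage_mean must be >= 20")
        if len(self.planted_motif) > 2 * self.peak_halfwidth:
            raise ValidationError("planted motif longer than peak width")


@dataclass
class FixtureBundle:
    """In-memory fixture; ``write`` serializes every piece as plain text."""

    genome: dict  # chrom -> sequence
    snps: list  # list[HetSNP] (all rows, pre genotype-quality filtering)
    peaks: PeakSet
    counts: pd.DataFrame  # snp_id, replicate_id, ref_count, alt_count
    truth: pd.DataFrame
    motif_db: list  # planted + decoy JASPAR motifs
    reads: Optional[list] = None  # (chrom, five_prime_pos, strand)
    tf: str = "TF1"
    cell_line: str = "CL1"

    def genome_source(self) -> GenomeSource:
        return GenomeSource(self.genome)

    def write(self, out_dir) -> dict:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "genome": out / "genome.fa",
            "snps": out / "snps.tsv",
            "peaks": out / "peaks.bed",
            "counts": out / "counts.tsv",
            "truth": out / "truth_table.tsv",
            "motifs": out / "motifs.jaspar",
        }
        with open(paths["genome"], "w") as fh:
            for chrom, seq in self.genome.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        write_het_snps(self.snps, paths["snps"])
        with open(paths["peaks"], "w") as fh:
            for chrom, start, end in self.peaks.intervals:
                fh.write(f"{chrom}\t{start}\t{end}\n")
        write_counts_tsv(self.counts, paths["counts"])
        self.truth.to_csv(paths["truth"], sep="\t", index=False)
        write_jaspar_pfm(self.motif_db, paths["motifs"])
        if self.reads is not None:
            paths["reads"] = out / "reads.bed"
            read_len = 36
            with open(paths["reads"], "w") as fh:
                for i, (chrom, pos, strand) in enumerate(self.reads):
                    # BED6; the 5' end is `start` for + reads and `end - 1` for -
                    if strand == "+":
                        s, e = pos, pos + read_len
                    else:
                        s, e = max(0, pos - read_len + 1), pos + 1
                    fh.write(f"{chrom}\t{s}\t{e}\tread{i}\t0\t{strand}\n")
        return {k: str(v) for k, v in paths.items()}


def simulate_counts(
    beta: float, raf: float, b: float, phi: float, n_reads: int, seed=None, rng=None
) -> tuple[int, int]:
    """Draw (ref_count, alt_count) from the odds-composition generative model."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return simulate_from_model(beta, raf, b, phi, n_reads, rng)


def _decoy_motifs() -> list[Motif]:
    """Two fixed decoy database motifs for other TFs, dissimilar to the
    planted consensus."""
    def one_hot(consensus: str, name: str, tf: str) -> Motif:
        m = np.full((len(consensus), 4), 0.02)
        for i, b in enumerate(consensus):
            m[i, BASES.index(b)] = 0.94
        return Motif(name=name, matrix=m, source="JASPAR", tf=tf, motif_class="canonical")

    return [
        one_hot("CCCGGGCC", "MA9002.1", "TF2"),
        one_hot("AATTATAA", "MA9003.1", "TF3"),
    ]


def generate_fixture(spec: FixtureSpec, make_reads: bool = False) -> FixtureBundle:
    """Generate the full fixture bundle; byte-identical for identical seeds."""
    rng = np.random.default_rng(spec.seed)
    motif = spec.planted_motif
    L = len(motif)
    chrom = "chr1"

    genome = rng.choice(list(BASES), size=spec.genome_len)

    # lay out non-overlapping slots for planted SNPs, extra motif sites and
    # null SNPs
    margin = 2 * spec.peak_halfwidth + 60
    n_slots = spec.n_snps + spec.n_extra_motif_sites
    slot_span = (spec.genome_len - 2 * margin) // max(n_slots, 1)
    if slot_span < 55:
        raise ValidationError("genome_len too small for the requested site count")
    slot_starts = margin + slot_span * np.arange(n_slots)
    rng.shuffle(slot_starts)

    ic = motif.information_content()
    snp_col = int(np.argmax(ic))
    consensus = motif.consensus

    snp_rows = []
    truth_rows = []
    count_rows = []
    peak_intervals = []
    motif_sites = []  # (start0, planted bool) for read generation

    # helper: sample an instance sequence from the motif
    def sample_instance() -> list[str]:
        return [BASES[rng.choice(4, p=motif.matrix[j])] for j in range(L)]

    planted_flags = np.array(
        [True] * spec.n_planted_asb + [False] * (spec.n_snps - spec.n_planted_asb)
    )
    raf_flags = rng.random(spec.n_snps) < spec.raf_distortion
    raf_values = np.where(raf_flags, rng.choice([0.25, 0.75], size=spec.n_snps), 0.5)

    # log-odds tables for computing the true MSD analytically (best placement
    # is the planted one for these high-information motifs)
    logodds = np.log2(np.clip(motif.matrix, 1e-9, None)) - np.log2(0.25)

    for i in range(spec.n_snps):
        slot = int(slot_starts[i])
        snp_id = f"snp{i:04d}"
        if planted_flags[i]:
            inst = sample_instance()
            # force the SNP column to consensus so the REF window is a strong
            # instance; ALT is the least-preferred base at that column
            strong = consensus[snp_col]
            weak = BASES[int(np.argmin(motif.matrix[snp_col]))]
            inst[snp_col] = strong
            m_start = slot
            genome[m_start : m_start + L] = inst
            pos = m_start + snp_col + 1  # 1-based
            flip = bool(rng.random() < 0.5)
            ref_allele, alt_allele = (strong, weak) if not flip else (weak, strong)
            genome[pos - 1] = ref_allele
            msd_true = float(logodds[snp_col, BASES.index(ref_allele)] -
                             logodds[snp_col, BASES.index(alt_allele)])
            beta_true = float(1.0 / (1.0 + np.exp(-spec.effect_slope * msd_true)))
            peak_intervals.append(
                (chrom, max(0, pos - 1 - spec.peak_halfwidth),
                 min(spec.genome_len, pos - 1 + spec.peak_halfwidth))
            )
            motif_sites.append((m_start, True))
            in_peak = True
        else:
            pos = slot + rng.integers(5, 50)
            pos = int(pos)
            ref_allele = genome[pos - 1]
            alt_allele = BASES[int((BASES.index(ref_allele) + 1 + rng.integers(0, 3)) % 4)]
            msd_true = 0.0
            beta_true = 0.5
            in_peak = False

        raf = float(raf_values[i])
        for r in range(spec.n_replicates):
            n = int(rng.poisson(spec.coverage_mean)) or 1
            ref_c, alt_c = simulate_from_model(
                beta_true, raf, spec.rm_bias_true, spec.dispersion_phi, n, rng
            )
            count_rows.append(
                {
                    "snp_id": snp_id,
                    "replicate_id": f"rep{r + 1}",
                    "ref_count": ref_c,
                    "alt_count": alt_c,
                }
            )

        maf = float(np.round(rng.uniform(0.01, 0.5), 4))
        conservation = float(np.round(rng.uniform(0.0, 1.0), 4))
        binding = ref_allele if beta_true > 0.5 else alt_allele
        ancestral = binding if rng.random() < 0.8 else (
            alt_allele if binding == ref_allele else ref_allele
        )
        snp_rows.append(
            HetSNP(
                snp_id=snp_id,
                chrom=chrom,
                pos=int(pos),
                ref_allele=str(ref_allele),
                alt_allele=str(alt_allele),
                raf=raf,
                genotype_quality=float(np.round(rng.uniform(0.96, 1.0), 4)),
                maf=maf,
                ancestral_allele=str(ancestral),
                conservation_score=conservation,
            )
        )
        truth_rows.append(
            {
                "snp_id": snp_id,
                "pos": int(pos),
                "is_planted": bool(planted_flags[i]),
                "beta_true": beta_true,
                "msd_true": msd_true,
                "raf": raf,
                "theta_true": compose_theta(beta_true, raf, spec.rm_bias_true),
                "in_peak": in_peak,
            }
        )

    # extra motif instances (no SNP) so k-mer discovery has many occurrences
    for j in range(spec.n_extra_motif_sites):
        start = int(slot_starts[spec.n_snps + j])
        genome[start : start + L] = sample_instance()
        motif_sites.append((start, False))

    reads = None
    if make_reads:
        reads = []
        read_len = 36
        for start, _ in motif_sites:
            center = start + L // 2
            n_site_reads = int(rng.poisson(30))
            for _ in range(n_site_reads):
                if rng.random() < 0.5:
                    # forward read: 5' end upstream of the site
                    p5 = center - int(rng.integers(5, 80)) - read_len // 2
                    reads.append((chrom, max(0, p5), "+"))
                else:
                    p5 = center + int(rng.integers(5, 80)) + read_len // 2
                    reads.append((chrom, min(spec.genome_len - 1, p5), "-"))
        n_bg = len(motif_sites) * 6
        for p5 in rng.integers(0, spec.genome_len - read_len, size=n_bg):
            reads.append((chrom, int(p5), "+" if rng.random() < 0.5 else "-"))

    genome_str = "".join(genome)
    peaks = PeakSet(peak_intervals, tf=spec.tf, cell_line=spec.cell_line)
    truth = pd.DataFrame.from_records(truth_rows)
    truth["in_peak"] = [peaks.contains(chrom, int(p)) for p in truth["pos"]]
    return FixtureBundle(
        genome={chrom: genome_str},
        snps=snp_rows,
        peaks=peaks,
        counts=pd.DataFrame.from_records(count_rows),
        truth=truth,
        motif_db=[motif] + _decoy_motifs(),
        reads=reads,
        tf=spec.tf,
        cell_line=spec.cell_line,
    )
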