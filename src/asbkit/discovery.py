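"""De novo k-mer motif discovery from aligned-read 5' positions.

No peak calls are needed: for every canonical k-mer occurring in the genome a
read-start offset histogram ("score profile") is built; k-mers whose profiles
show read enrichment over the k-mer are selected and greedily assembled into
probability-matrix motifs by ungapped sequence similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from ._seq import canonical_kmer, revcomp
from .errors import ConfigError
from .io import Motif, load_genome

logger = logging.getLogger(__name__)

__all__ = [
    "KmerProfile",
    "read_reads_bed",
    "build_kmer_profiles",
    "select_binding_kmers",
    "assemble_motifs",
]


def read_reads_bed(path) -> list[tuple[str, int, str]]:
    """Read 5'-end read positions from a BED6 file.

    Returns ``(chrom, five_prime_pos, strand)`` tuples: the 5' end is ``start``
    for + reads and ``end - 1`` for - reads. A missing strand column defaults
    to '+'.
    """
    reads = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) > 5 else "+"
            reads.append((chrom, start if strand == "+" else end - 1, strand))
    return reads


@dataclass
class KmerProfile:
    """Offset histogram between read 5' starts and genomic k-mer occurrences."""

    kmer: str  # canonical (strand-collapsed) form
    profile: np.ndarray  # length 2W+1, offsets -W..+W
    n_occurrences: int
    window_w: int
    enrichment: float = field(default=float("nan"))

    @property
    def n_reads(self) -> int:
        return int(self.profile.sum())


def build_kmer_profiles(
    read_intervals: Iterable[tuple[str, int, str]],
    genome,
    k: int = 8,
    window_w: int = 200,
) -> list[KmerProfile]:
    """Build read-start offset profiles for every canonical k-mer in the genome.

    ``read_intervals`` are ``(chrom, five_prime_pos, strand)`` with the 0-based
    genomic coordinate of each read's 5' end. For every genomic occurrence of a
    canonical k-mer, every read 5' start within +/- ``window_w`` increments the
    offset bin ``start - occurrence`` (forward reads) or ``occurrence - start``
    (reverse reads; the sign flip makes profiles strand-symmetric).
    """
    if not 4 <= k <= 12:
        raise ConfigError(f"k={k} outside [4, 12]")
    gs = load_genome(genome)

    reads_by_chrom: dict[str, dict[str, list[int]]] = {}
    n_reads = 0
    for chrom, pos, strand in read_intervals:
        reads_by_chrom.setdefault(chrom, {"+": [], "-": []})[strand].append(int(pos))
        n_reads += 1
    if n_reads == 0:
        return []
    sorted_reads = {
        chrom: {s: np.array(sorted(v), dtype=np.int64) for s, v in d.items()}
        for chrom, d in reads_by_chrom.items()
    }

    profiles: dict[str, np.ndarray] = {}
    occurrences: dict[str, int] = {}
    width = 2 * window_w + 1
    for chrom in gs.chroms():
        seq = gs.fetch(chrom, 0, gs.length(chrom)).upper()
        chrom_reads = sorted_reads.get(chrom)
        if chrom_reads is None:
            continue
        plus, minus = chrom_reads["+"], chrom_reads["-"]
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(c not in "ACGT" for c in kmer):
                continue
            canon = canonical_kmer(kmer)
            prof = profiles.get(canon)
            if prof is None:
                prof = profiles[canon] = np.zeros(width, dtype=np.int64)
                occurrences[canon] = 0
            occurrences[canon] += 1
            if len(plus):
                lo = np.searchsorted(plus, i - window_w, side="left")
                hi = np.searchsorted(plus, i + window_w, side="right")
                if hi > lo:
                    np.add.at(prof, plus[lo:hi] - i + window_w, 1)
            if len(minus):
                lo = np.searchsorted(minus, i - window_w, side="left")
                hi = np.searchsorted(minus, i + window_w, side="right")
                if hi > lo:
                    np.add.at(prof, i - minus[lo:hi] + window_w, 1)
    return [
        KmerProfile(kmer=km, profile=profiles[km], n_occurrences=occurrences[km], window_w=window_w)
        for km in sorted(profiles)
    ]


def select_binding_kmers(
    profiles: Sequence[KmerProfile],
    enrichment_min: float = 2.0,
    min_occurrences: int = 50,
    central_half: int = 100,
    min_reads: int = 0,
) -> list[KmerProfile]:
    """Keep k-mers whose central read density exceeds the flank density.

    Density ratio = ((central+1)/n_central_bins) / ((flank+1)/n_flank_bins),
    comparing |offset| <= ``central_half`` against the remaining flanks; k-mers
    are retained when ratio > ``enrichment_min``, with at least
    ``min_occurrences`` genomic occurrences and ``min_reads`` supporting read
    incidences, sorted by descending enrichment.
    """
    out: list[KmerProfile] = []
    for p in profiles:
        w = p.window_w
        if central_half >= w:
            raise ConfigError("central_half must be < window_w")
        offsets = np.arange(-w, w + 1)
        central_mask = np.abs(offsets) <= central_half
        c = int(p.profile[central_mask].sum())
        f = int(p.profile[~central_mask].sum())
        n_c = int(central_mask.sum())
        n_f = int((~central_mask).sum())
        ratio = ((c + 1) / n_c) / ((f + 1) / n_f)
        p.enrichment = float(ratio)
        if ratio > enrichment_min and p.n_occurrences >= min_occurrences and p.n_reads >= min_reads:
            out.append(p)
    out.sort(key=lambda p: (-p.enrichment, p.kmer))
    return out


def _best_ungapped_alignment(a: str, b: str) -> Optional[tuple[int, str, int]]:
    """Best (offset, orientation, n_matches) aligning b onto a, requiring
    >= len-2 matching positions in some ungapped overlap; None when no
    alignment qualifies."""
    k = len(a)
    need = k - 2
    best: Optional[tuple[int, str, int]] = None
    for orientation, bb in (("forward", b), ("reverse_complement", revcomp(b))):
        for d in range(-(len(bb) - need), k - need + 1):
            lo = max(0, d)
            hi = min(k, d + len(bb))
            if hi - lo < need:
                continue
            matches = sum(1 for i in range(lo, hi) if a[i] == bb[i - d])
            if matches >= need:
                cand = (d, orientation, matches)
                if (
                    best is None
                    or matches > best[2]
                    or (matches == best[2] and (abs(d), orientation != "forward") < (abs(best[0]), best[1] != "forward"))
                ):
                    best = cand
    return best


def assemble_motifs(
    selected_kmers: Sequence[KmerProfile],
    min_kmer_support: int = 10,
    sample_id: str = "sample",
) -> list[Motif]:
    """Greedily group similar selected k-mers and emit probability motifs.

    K-mers are seeded in descending enrichment order; a k-mer joins a group if
    some ungapped offset alignment to the group seed (either orientation) has
    at least k-2 matching positions. Group members are stacked at their
    alignment offsets; per-column base frequencies over covering members form
    the motif matrix. Groups with fewer than ``min_kmer_support`` member k-mers
    are discarded.
    """
    ordered = sorted(
        selected_kmers,
        key=lambda p: (-(p.enrichment if np.isfinite(p.enrichment) else 0.0), p.kmer),
    )
    groups: list[dict] = []
    for prof in ordered:
        placed = False
        for g in groups:
            aln = _best_ungapped_alignment(g["seed"], prof.kmer)
            if aln is not None:
                d, orientation, _ = aln
                km = prof.kmer if orientation == "forward" else revcomp(prof.kmer)
                g["members"].append((km, d))
                placed = True
                break
        if not placed:
            groups.append({"seed": prof.kmer, "members": [(prof.kmer, 0)]})

    motifs: list[Motif] = []
    n = 0
    for g in groups:
        members = g["members"]
        if len(members) < min_kmer_support:
            continue
        starts = [d for _, d in members]
        ends = [d + len(km) for km, d in members]
        lo, hi = min(starts), max(ends)
        width = hi - lo
        counts = np.zeros((width, 4))
        for km, d in members:
            for j, base in enumerate(km):
                counts[d - lo + j, "ACGT".index(base)] += 1
        cov = counts.sum(axis=1, keepdims=True)
        cov[cov == 0] = 1.0
        matrix = counts / cov
        # columns covered by no member (cannot happen with ungapped overlaps,
        # but guard anyway) become uniform
        empty = counts.sum(axis=1) == 0
        matrix[empty] = 0.25
        if width < 4:
            continue
        motifs.append(
            Motif(
                name=f"{sample_id}_motif_{n}",
                matrix=matrix,
                source="NoPeak",
                kmer_support=len(members),
                motif_class="unclassified",
            )
        )
        n += 1
    return motifs
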