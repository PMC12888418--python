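"""Readers/writers for the standard formats the pipeline touches.

Coordinate conventions: SNP positions are 1-based throughout the package; BED
intervals are 0-based half-open, converted at the containment query (a 1-based
position ``p`` falls in ``(start, end)`` iff ``start <= p - 1 < end``).
"""

from __future__ import annotations

import io as _io
import re
from bisect import bisect_right
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

__all__ = [
    "HetSNP",
    "PeakSet",
    "Motif",
    "read_jaspar_pfm",
    "write_jaspar_pfm",
    "read_bed_peaks",
    "read_het_snps",
    "write_het_snps",
    "read_counts_tsv",
    "write_counts_tsv",
    "GenomeSource",
    "load_genome",
]

#: pseudocount added to every PFM count cell before column normalization;
#: avoids -inf log-odds for zero counts.
PFM_PSEUDOCOUNT = 0.01

SNP_TSV_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "raf", "genotype_quality"]
SNP_TSV_OPTIONAL = ["maf", "ancestral_allele", "conservation"]

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class HetSNP:
    """A genotyped heterozygous site with copy-number (RAF) and annotations."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    raf: float
    genotype_quality: float = 1.0
    maf: Optional[float] = None
    ancestral_allele: Optional[str] = None
    conservation_score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ref_allele not in _VALID_BASES or self.alt_allele not in _VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases A/C/G/T, got "
                f"{self.ref_allele!r}/{self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValidationError(f"{self.snp_id}: ref and alt alleles are identical")
        if not 0.0 <= self.raf <= 1.0:
            raise ValidationError(f"{self.snp_id}: raf {self.raf} outside [0, 1]")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1 (1-based)")
        if self.maf is not None and not 0.0 <= self.maf <= 0.5:
            raise ValidationError(f"{self.snp_id}: maf {self.maf} outside [0, 0.5]")
        if self.conservation_score is not None and not 0.0 <= self.conservation_score <= 1.0:
            raise ValidationError(
                f"{self.snp_id}: conservation score {self.conservation_score} outside [0, 1]"
            )


class PeakSet:
    """ChIP-seq peak intervals supporting point-containment queries.

    Intervals are stored 0-based half-open per chromosome; queries take 1-based
    SNP positions. Unknown chromosomes are simply "not in peak".
    """

    def __init__(
        self,
        intervals: Iterable[tuple[str, int, int]],
        tf: str = "",
        cell_line: str = "",
    ):
        self.tf = tf
        self.cell_line = cell_line
        self.intervals: list[tuple[str, int, int]] = []
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise FormatError(f"interval ({chrom},{start},{end}): start >= end")
            self.intervals.append((chrom, start, end))
            per_chrom.setdefault(chrom, []).append((start, end))
        self._index: dict[str, tuple[list[int], np.ndarray]] = {}
        for chrom, ivals in per_chrom.items():
            ivals.sort()
            starts = [s for s, _ in ivals]
            ends = np.maximum.accumulate(np.array([e for _, e in ivals]))
            self._index[chrom] = (starts, ends)

    def __len__(self) -> int:
        return len(self.intervals)

    def contains(self, chrom: str, pos: int) -> bool:
        """True iff the 1-based position ``pos`` lies inside any interval."""
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, cummax_ends = entry
        p0 = pos - 1
        i = bisect_right(starts, p0)
        return i > 0 and cummax_ends[i - 1] > p0


@dataclass
class Motif:
    """A TF binding motif as per-position base probabilities over A,C,G,T."""

    name: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    source: str = "JASPAR"  # JASPAR | NoPeak
    tf: Optional[str] = None
    kmer_support: Optional[int] = None
    motif_class: str = "unclassified"  # canonical|redundant|accessory|de_novo|unclassified

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError(f"motif {self.name}: matrix must be (L, 4)")
        if len(self.matrix) < 4:
            raise ValidationError(f"motif {self.name}: length {len(self.matrix)} < 4")
        if np.any(self.matrix < 0):
            raise ValidationError(f"motif {self.name}: negative probabilities")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(f"motif {self.name}: rows do not sum to 1")

    def __len__(self) -> int:
        return len(self.matrix)

    @property
    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.matrix.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits: 2 + sum p*log2(p)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(self.matrix > 0, self.matrix * np.log2(self.matrix), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def with_class(self, motif_class: str) -> "Motif":
        return replace(self, motif_class=motif_class)


# ---------------------------------------------------------------------------
# JASPAR PFM text format
# ---------------------------------------------------------------------------

_ROW_RE = re.compile(r"^([ACGT])?\s*\[?\s*(.*?)\s*\]?\s*$")


def read_jaspar_pfm(
    source: Union[str, Path, _io.TextIOBase],
    source_label: str = "JASPAR",
    pseudocount: float = PFM_PSEUDOCOUNT,
) -> list[Motif]:
    """Parse motifs from JASPAR PFM text format.

    Each record is a ``>name [tf]`` header followed by four count rows (A, C,
    G, T), optionally bracketed. Counts are converted to probabilities
    column-wise after adding ``pseudocount`` to every cell. Record order is
    preserved.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            text = fh.read()
    else:
        text = source.read()

    motifs: list[Motif] = []
    name: Optional[str] = None
    tf: Optional[str] = None
    rows: list[list[float]] = []

    def flush() -> None:
        nonlocal name, tf, rows
        if name is None:
            return
        if len(rows) != 4:
            raise FormatError(f"record {name!r}: expected 4 base rows, found {len(rows)}")
        lengths = {len(r) for r in rows}
        if lengths != {len(rows[0])} or len(rows[0]) == 0:
            raise FormatError(f"record {name!r}: ragged or zero-length count matrix")
        counts = np.array(rows, dtype=float).T  # (L, 4) in A,C,G,T order
        if np.any(counts < 0):
            raise FormatError(f"record {name!r}: negative counts")
        counts = counts + pseudocount
        matrix = counts / counts.sum(axis=1, keepdims=True)
        motifs.append(Motif(name=name, matrix=matrix, source=source_label, tf=tf))
        name, tf, rows = None, None, []

    for raw in text.splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            parts = line[1:].split(None, 1)
            if not parts:
                raise FormatError("record with empty header line")
            name = parts[0]
            tf = parts[1].strip() or None if len(parts) > 1 else None
            continue
        if name is None:
            raise FormatError(f"count row before any '>' header: {line!r}")
        m = _ROW_RE.match(line)
        if m is None:
            raise FormatError(f"record {name!r}: unparseable row {line!r}")
        base, numbers = m.group(1), m.group(2)
        if base is not None and len(rows) != "ACGT".index(base):
            raise FormatError(f"record {name!r}: base rows out of A,C,G,T order")
        try:
            values = [float(x) for x in numbers.split()]
        except ValueError as exc:
            raise FormatError(f"record {name!r}: non-numeric entry in row {line!r}") from exc
        if not values:
            raise FormatError(f"record {name!r}: empty count row")
        rows.append(values)
        if len(rows) > 4:
            raise FormatError(f"record {name!r}: more than 4 base rows")
    flush()
    return motifs


def write_jaspar_pfm(motifs: Sequence[Motif], path: Union[str, Path], scale: int = 100) -> None:
    """Write motifs in JASPAR PFM text format (probabilities x support as counts)."""
    with open(path, "w") as fh:
        for m in motifs:
            total = m.kmer_support if m.kmer_support else scale
            counts = m.matrix * total
            header = f">{m.name}"
            if m.tf:
                header += f" {m.tf}"
            fh.write(header + "\n")
            for bi, base in enumerate("ACGT"):
                row = " ".join(f"{c:.3f}" for c in counts[:, bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# BED peaks
# ---------------------------------------------------------------------------


def read_bed_peaks(path: Union[str, Path], tf: str = "", cell_line: str = "") -> PeakSet:
    """Read a 3+ column BED file (0-based half-open) into a PeakSet."""
    intervals: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            intervals.append((fields[0], start, end))
    return PeakSet(intervals, tf=tf, cell_line=cell_line)


# ---------------------------------------------------------------------------
# Heterozygous SNP tables
# ---------------------------------------------------------------------------


def read_het_snps(
    source: Union[str, Path, pd.DataFrame],
    min_quality: float = 0.95,
) -> list[HetSNP]:
    """Read the canonical tab-separated heterozygous SNP table.

    Rows with ``genotype_quality <= min_quality`` are removed (the filter is a
    strict greater-than). Duplicated ``snp_id`` values within one table (one
    cell line) are an error.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source, sep="\t", dtype={"chrom": str})
    missing = [c for c in SNP_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"SNP table missing required columns: {missing}")
    dup = df["snp_id"][df["snp_id"].duplicated()]
    if len(dup):
        raise ValidationError(f"duplicated snp_id within one cell line: {sorted(set(dup))}")
    kept = df[df["genotype_quality"] > min_quality]
    snps: list[HetSNP] = []
    for row in kept.itertuples(index=False):
        def _opt(attr: str, cast=float):
            v = getattr(row, attr, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        snps.append(
            HetSNP(
                snp_id=str(row.snp_id),
                chrom=str(row.chrom),
                pos=int(row.pos),
                ref_allele=str(row.ref),
                alt_allele=str(row.alt),
                raf=float(row.raf),
                genotype_quality=float(row.genotype_quality),
                maf=_opt("maf"),
                ancestral_allele=_opt("ancestral_allele", str),
                conservation_score=_opt("conservation"),
            )
        )
    return snps


def write_het_snps(snps: Sequence[HetSNP], path: Union[str, Path]) -> None:
    """Write HetSNPs to the canonical TSV (round-trips through read_het_snps)."""
    records = []
    for s in snps:
        records.append(
            {
                "snp_id": s.snp_id,
                "chrom": s.chrom,
                "pos": s.pos,
                "ref": s.ref_allele,
                "alt": s.alt_allele,
                "raf": s.raf,
                "genotype_quality": s.genotype_quality,
                "maf": s.maf,
                "ancestral_allele": s.ancestral_allele,
                "conservation": s.conservation_score,
            }
        )
    pd.DataFrame.from_records(records, columns=SNP_TSV_COLUMNS + SNP_TSV_OPTIONAL).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Allelic count tables
# ---------------------------------------------------------------------------

COUNTS_TSV_COLUMNS = ["snp_id", "replicate_id", "ref_count", "alt_count"]


def read_counts_tsv(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNTS_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"counts table missing required columns: {missing}")
    if (df["ref_count"] < 0).any() or (df["alt_count"] < 0).any():
        raise ValidationError("negative read counts")
    return df


def write_counts_tsv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    df.to_csv(path, sep="\t", index=False, columns=COUNTS_TSV_COLUMNS)


# ---------------------------------------------------------------------------
# Genome access
# ---------------------------------------------------------------------------


class GenomeSource:
    """Uniform coordinate access over a FASTA file or an in-memory dict."""

    def __init__(self, data: Union[str, Path, Mapping[str, str]]):
        if isinstance(data, (str, Path)):
            from pyfaidx import Fasta

            self._fasta = Fasta(str(data), as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: v.upper() for k, v in data.items()}

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start0: int, end0: int) -> str:
        """Sequence for the 0-based half-open interval [start0, end0)."""
        start0 = max(0, start0)
        if self._dict is not None:
            return self._dict[chrom][start0:end0]
        return str(self._fasta[chrom][start0:end0])

    def chroms(self) -> list[str]:
        if self._dict is not None:
            return list(self._dict)
        return list(self._fasta.keys())


def load_genome(data: Union[str, Path, Mapping[str, str], GenomeSource]) -> GenomeSource:
    if isinstance(data, GenomeSource):
        return data
    return GenomeSource(data)
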