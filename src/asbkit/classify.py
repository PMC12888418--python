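"""High-quality motif screening and High/Low/Unclassified ASB labelling.

A motif is "high-quality" when the corrected allelic ratio (CAR) and the motif
score difference (MSD) are significantly, positively rank-correlated across
in-peak SNPs matching the motif. An ASB is High when it has a concordant match
(CAR and MSD on the same side of their nulls) to a high-quality motif inside a
peak, Low when the concordant match lies outside every peak, and Unclassified
otherwise. Attribution prioritizes known (JASPAR) motifs, then accessory, then
de novo discovered motifs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import ValidationError
from .inference import ASBCall
from .motifs import SnpMotifScore

__all__ = [
    "MotifQuality",
    "ASBClassification",
    "spearman_car_msd",
    "classify_asb",
    "summarize_distinct",
]

#: attribution priority of motif classes (lower = attributed first)
_CLASS_PRIORITY = {"canonical": 0, "accessory": 1, "de_novo": 2}


@dataclass
class MotifQuality:
    motif_name: str
    n_snps: int
    rho: float  # nan when undefined
    pvalue: float  # nan when undefined
    high_quality: bool
    reason: Optional[str] = None


@dataclass
class ASBClassification:
    snp_id: str
    tf: str
    cell_line: str
    quality: str  # High | Low | Unclassified
    attributed_motif: Optional[str] = None
    attributed_class: Optional[str] = None


def _exact_spearman_pvalue(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p-value of the rank correlation, by full
    enumeration of all n! orderings of one rank vector (n <= 9)."""
    n = len(rx)
    perms = np.array(list(itertools.permutations(ry)))
    rxc = rx - rx.mean()
    pc = perms - ry.mean()
    denom = np.linalg.norm(rxc) * np.linalg.norm(pc[0])
    if denom == 0:
        return 1.0
    rhos = pc @ rxc / denom
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def spearman_car_msd(
    pairs: Sequence[tuple[float, float]],
    min_snps: int = 5,
    motif_name: str = "",
    alpha: float = 0.05,
) -> MotifQuality:
    """Spearman correlation between CAR and MSD with a high-quality verdict.

    rho is the Pearson correlation of mid-ranks (average ranks on ties); the
    p-value is exact (full permutation) for n <= 9 and uses the t
    approximation otherwise. The motif is high-quality when rho > 0 and
    p < ``alpha`` and n >= ``min_snps``.
    """
    n = len(pairs)
    if n < min_snps:
        return MotifQuality(
            motif_name=motif_name,
            n_snps=n,
            rho=float("nan"),
            pvalue=float("nan"),
            high_quality=False,
            reason=f"only {n} SNPs (< {min_snps})",
        )
    cars = np.array([c for c, _ in pairs], dtype=float)
    msds = np.array([m for _, m in pairs], dtype=float)
    rx, ry = rankdata(cars), rankdata(msds)
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return MotifQuality(
            motif_name=motif_name,
            n_snps=n,
            rho=float("nan"),
            pvalue=float("nan"),
            high_quality=False,
            reason="constant ranks",
        )
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 9:
        p = _exact_spearman_pvalue(rx, ry, rho)
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1 - rho * rho))
            from scipy.stats import t as t_dist

            p = float(2 * t_dist.sf(abs(t), df=n - 2))
    return MotifQuality(
        motif_name=motif_name,
        n_snps=n,
        rho=rho,
        pvalue=p,
        high_quality=bool(rho > 0 and p < alpha),
    )


def classify_asb(
    asb: ASBCall,
    scores: Sequence[SnpMotifScore],
    qualities: Mapping[str, MotifQuality],
) -> ASBClassification:
    """Label one ASB High/Low/Unclassified with source-priority attribution.

    Candidate motifs are high-quality, matched (``matches``) and concordant
    with the call: CAR > 0.5 with MSD > 0, or CAR < 0.5 with MSD < 0 (strict;
    CAR == 0.5 or MSD == 0 is not concordant). Redundant motifs must already
    have been excluded. Attribution order is JASPAR (canonical), then
    accessory, then de novo; ties within a class break by |MSD| descending
    then motif name. Quality is High when the attributed score is in a peak,
    Low otherwise; with no candidate the ASB is Unclassified.
    """
    if not asb.is_asb:
        raise ValidationError(f"{asb.snp_id}: classify_asb requires is_asb == True")

    def concordant(s: SnpMotifScore) -> bool:
        return (asb.car > 0.5 and s.msd > 0) or (asb.car < 0.5 and s.msd < 0)

    candidates = []
    for s in scores:
        if s.motif_class == "redundant":
            continue
        q = qualities.get(s.motif_name)
        if q is None or not q.high_quality:
            continue
        if not s.matches or not concordant(s):
            continue
        cls = s.motif_class if s.motif_class in _CLASS_PRIORITY else (
            "canonical" if s.motif_source == "JASPAR" else "de_novo"
        )
        candidates.append((_CLASS_PRIORITY[cls], -abs(s.msd), s.motif_name, cls, s))
    if not candidates:
        return ASBClassification(
            snp_id=asb.snp_id, tf=asb.tf, cell_line=asb.cell_line, quality="Unclassified"
        )
    candidates.sort(key=lambda c: c[:3])
    _, _, _, cls, chosen = candidates[0]
    return ASBClassification(
        snp_id=asb.snp_id,
        tf=asb.tf,
        cell_line=asb.cell_line,
        quality="High" if chosen.in_peak else "Low",
        attributed_motif=chosen.motif_name,
        attributed_class=cls,
    )


_QUALITY_RANK = {"High": 0, "Low": 1, "Unclassified": 2}


def summarize_distinct(classified: pd.DataFrame) -> dict:
    """Distinct TF-SNP summarization of a classified ASB table.

    A (snp_id, tf) pair replicated across cell lines is counted once; the
    pair-level quality is the best across cell lines (High anywhere beats Low
    beats Unclassified). Raw row counts (replicates included) are also
    reported, as are per-TF breakdowns.
    """
    required = {"snp_id", "tf", "quality"}
    missing = required - set(classified.columns)
    if missing:
        raise ValidationError(f"classified table missing columns: {sorted(missing)}")
    out: dict = {
        "n_rows": int(len(classified)),
        "n_rows_per_quality": {q: 0 for q in _QUALITY_RANK},
        "n_distinct_pairs": 0,
        "n_distinct_per_quality": {q: 0 for q in _QUALITY_RANK},
        "per_tf": {},
    }
    if len(classified) == 0:
        return out
    vc = classified["quality"].value_counts()
    for q in _QUALITY_RANK:
        out["n_rows_per_quality"][q] = int(vc.get(q, 0))
    ranks = classified["quality"].map(_QUALITY_RANK)
    df = classified.assign(_rank=ranks)
    reduced = df.groupby(["snp_id", "tf"], sort=False)["_rank"].min().reset_index()
    inv = {v: k for k, v in _QUALITY_RANK.items()}
    reduced["quality"] = reduced["_rank"].map(inv)
    out["n_distinct_pairs"] = int(len(reduced))
    for q, cnt in reduced["quality"].value_counts().items():
        out["n_distinct_per_quality"][q] = int(cnt)
    for tf, sub in reduced.groupby("tf"):
        out["per_tf"][tf] = {
            "n_distinct_pairs": int(len(sub)),
            "n_distinct_per_quality": {
                q: int((sub["quality"] == q).sum()) for q in _QUALITY_RANK
            },
        }
    return out
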