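"""End-to-end orchestration: counts -> ASB inference -> motif discovery and
ingest -> SNP-motif scoring -> motif quality -> classification -> comparators.

Every stage writes a plain-text artifact into the output directory and the run
manifest records input hashes, parameters, per-stage row counts and timings.
Re-running with identical config and inputs reproduces identical artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import MotifQuality, classify_asb, spearman_car_msd, summarize_distinct
from .comparators import (
    build_nonasb_pool,
    conservation_counts,
    empirical_pvalue,
    sample_maf_matched,
)
from .discovery import assemble_motifs, build_kmer_profiles, read_reads_bed, select_binding_kmers
from .errors import ValidationError
from .inference import ASBCall, AllelicCount, ModelConfig, estimate_overdispersion, estimate_rm_bias, infer_asb
from .io import (
    Motif,
    load_genome,
    read_bed_peaks,
    read_counts_tsv,
    read_het_snps,
    read_jaspar_pfm,
    write_jaspar_pfm,
)
from .motifs import classify_nopeak_motif, cluster_motifs, fpr_threshold, score_het_snp, trim_motif_edges

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Validated configuration for a full pipeline run."""

    genome: str
    peaks: str
    snp_table: str
    counts: str
    jaspar_pfm: str
    output_dir: str
    reads: Optional[str] = None  # BED6 read intervals; enables de novo discovery
    tf: str = ""
    cell_line: str = ""
    seed: int = 0
    min_genotype_quality: float = 0.95
    hpd_level: float = 0.95
    n_iter: int = 5000
    n_burnin: int = 1000
    rm_bias: Optional[float] = None  # None -> estimate from the data
    dispersion_phi: Optional[float] = None  # None -> method-of-moments
    fpr: float = 0.05
    flank: int = 25
    fpr_samples: int = 20000
    cluster_threshold: float = 0.7
    similarity_k: int = 7
    min_kmer_support: int = 10
    kmer_k: int = 8
    kmer_window: int = 200
    enrichment_min: float = 2.0
    min_kmer_occurrences: int = 2
    min_kmer_reads: int = 150
    min_snps_per_motif: int = 5
    comparator_min_reads: int = 100
    comparator_rel_tol: float = 0.05
    comparator_n_sets: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("genome", "peaks", "snp_table", "counts", "jaspar_pfm", "output_dir") if k not in data]
        if missing:
            raise ValidationError(f"config missing required keys: {missing}")
        return cls(**data)

    def validate_paths(self) -> None:
        for key in ("genome", "peaks", "snp_table", "counts", "jaspar_pfm", "reads"):
            value = getattr(self, key)
            if value is None:
                continue
            if not Path(value).exists():
                raise ValidationError(f"config path {key}={value!r} does not exist")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def infer_all_asbs(
    counts_df: pd.DataFrame,
    snps,
    model_config: ModelConfig,
    tf: str = "",
    cell_line: str = "",
) -> list[ASBCall]:
    """Run ASB inference for every SNP present in the counts table."""
    raf_by_id = {s.snp_id: s.raf for s in snps}
    calls: list[ASBCall] = []
    for snp_id, group in counts_df.groupby("snp_id", sort=True):
        if snp_id not in raf_by_id:
            continue
        counts = [
            AllelicCount(
                snp_id=str(snp_id),
                replicate_id=str(r.replicate_id),
                ref_count=int(r.ref_count),
                alt_count=int(r.alt_count),
            )
            for r in group.itertuples(index=False)
        ]
        if sum(c.total for c in counts) < 1:
            continue
        calls.append(
            infer_asb(counts, raf_by_id[snp_id], model_config, tf=tf, cell_line=cell_line)
        )
    return calls


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest."""
    config.validate_paths()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {},
        "stages": [],
        "complete": False,
    }
    for key in ("genome", "peaks", "snp_table", "counts", "jaspar_pfm", "reads"):
        value = getattr(config, key)
        if value is not None:
            manifest["inputs"][key] = _sha256(value)

    t_all = time.monotonic()

    def stage(name: str, n_rows: int, t0: float) -> None:
        manifest["stages"].append(
            {"name": name, "rows": int(n_rows), "seconds": round(time.monotonic() - t0, 3)}
        )
        logger.info("stage %-22s rows=%-8d %.2fs", name, n_rows, time.monotonic() - t0)

    try:
        # --- ingest ---------------------------------------------------------
        t0 = time.monotonic()
        snps = read_het_snps(config.snp_table, min_quality=config.min_genotype_quality)
        genome = load_genome(config.genome)
        peaks = read_bed_peaks(config.peaks, tf=config.tf, cell_line=config.cell_line)
        counts_df = read_counts_tsv(config.counts)
        counts_df = counts_df[counts_df["snp_id"].isin({s.snp_id for s in snps})]
        stage("ingest", len(counts_df), t0)

        # --- bias estimation ------------------------------------------------
        t0 = time.monotonic()
        all_counts = [
            AllelicCount(str(r.snp_id), str(r.replicate_id), int(r.ref_count), int(r.alt_count))
            for r in counts_df.itertuples(index=False)
        ]
        rm_bias = config.rm_bias if config.rm_bias is not None else estimate_rm_bias(all_counts)
        if config.dispersion_phi is not None:
            phi = config.dispersion_phi
        else:
            phis = []
            for _, group in counts_df.groupby("snp_id"):
                if len(group) >= 3:
                    phis.append(
                        estimate_overdispersion(
                            [
                                AllelicCount(str(r.snp_id), str(r.replicate_id), int(r.ref_count), int(r.alt_count))
                                for r in group.itertuples(index=False)
                            ]
                        )
                    )
            phi = float(np.median(phis)) if phis else 0.0
        manifest["rm_bias"] = rm_bias
        manifest["dispersion_phi"] = phi
        stage("bias_estimation", len(all_counts), t0)

        # --- ASB inference --------------------------------------------------
        t0 = time.monotonic()
        model_config = ModelConfig(
            rm_bias_b=rm_bias,
            dispersion_phi=phi,
            n_iter=config.n_iter,
            n_burnin=config.n_burnin,
            hpd_level=config.hpd_level,
            seed=config.seed,
        )
        calls = infer_all_asbs(counts_df, snps, model_config, tf=config.tf, cell_line=config.cell_line)
        calls_df = pd.DataFrame(
            [
                {
                    "ID": c.snp_id,
                    "tf": c.tf,
                    "cell_line": c.cell_line,
                    "CAR": round(c.car, 6),
                    "hpd_lo": round(c.hpd_lo, 6),
                    "hpd_hi": round(c.hpd_hi, 6),
                    "isASB": c.is_asb,
                    "Total.counts": c.total_counts,
                }
                for c in calls
            ]
        )
        calls_df.to_csv(out / "asb_calls.tsv", sep="\t", index=False)
        stage("asb_inference", len(calls_df), t0)

        # --- motif acquisition ---------------------------------------------
        t0 = time.monotonic()
        jaspar = read_jaspar_pfm(config.jaspar_pfm)
        for m in jaspar:
            m.motif_class = "canonical"
        motifs: list[Motif] = list(jaspar)
        if config.reads:
            reads = read_reads_bed(config.reads)
            profiles = build_kmer_profiles(reads, genome, k=config.kmer_k, window_w=config.kmer_window)
            selected = select_binding_kmers(
                profiles,
                enrichment_min=config.enrichment_min,
                min_occurrences=config.min_kmer_occurrences,
                min_reads=config.min_kmer_reads,
            )
            nopeak = assemble_motifs(
                selected, min_kmer_support=config.min_kmer_support, sample_id=config.cell_line or "sample"
            )
            nopeak = [trim_motif_edges(m) for m in nopeak]
            nopeak = cluster_motifs(nopeak, threshold=config.cluster_threshold, k=config.similarity_k)
            kept = []
            for m in nopeak:
                cls = classify_nopeak_motif(m, jaspar, config.tf, threshold=config.cluster_threshold, k=config.similarity_k)
                m.motif_class = cls
                if cls != "redundant":  # redundant motifs leave the analysis here
                    kept.append(m)
            motifs.extend(kept)
            write_jaspar_pfm(kept, out / "nopeak_motifs.jaspar")
        stage("motif_acquisition", len(motifs), t0)

        # --- SNP-motif scoring ----------------------------------------------
        t0 = time.monotonic()
        score_rows = []
        scores_by_snp: dict[str, list] = {}
        for m in motifs:
            thr = fpr_threshold(
                m,
                fpr=config.fpr,
                window_len=2 * config.flank + 1,
                method="mc",
                seed=config.seed,
                n_samples=config.fpr_samples,
            )
            for s in snps:
                sc = score_het_snp(m, genome, s, peaks, flank=config.flank, threshold=thr)
                scores_by_snp.setdefault(s.snp_id, []).append(sc)
                score_rows.append(
                    {
                        "snp_id": sc.snp_id,
                        "motif": sc.motif_name,
                        "ref_score": round(sc.ref_score, 6),
                        "alt_score": round(sc.alt_score, 6),
                        "msd": round(sc.msd, 6),
                        "matches": sc.matches,
                        "in_peak": sc.in_peak,
                        "motif_class": sc.motif_class,
                        "motif_source": sc.motif_source,
                    }
                )
        scores_df = pd.DataFrame(score_rows)
        scores_df.to_csv(out / "snp_motif_scores.tsv", sep="\t", index=False)
        stage("snp_motif_scoring", len(scores_df), t0)

        # --- motif quality --------------------------------------------------
        t0 = time.monotonic()
        car_by_id = {c.snp_id: c.car for c in calls}
        qualities: dict[str, MotifQuality] = {}
        for m in motifs:
            pairs = [
                (car_by_id[sc.snp_id], sc.msd)
                for sid, lst in scores_by_snp.items()
                if sid in car_by_id
                for sc in lst
                if sc.motif_name == m.name and sc.matches and sc.in_peak
            ]
            qualities[m.name] = spearman_car_msd(
                pairs, min_snps=config.min_snps_per_motif, motif_name=m.name
            )
        pd.DataFrame(
            [
                {
                    "motif": q.motif_name,
                    "n_snps": q.n_snps,
                    "rho": q.rho,
                    "pvalue": q.pvalue,
                    "high_quality": q.high_quality,
                }
                for q in qualities.values()
            ]
        ).to_csv(out / "motif_quality.tsv", sep="\t", index=False)
        stage("motif_quality", len(qualities), t0)

        # --- ASB classification ---------------------------------------------
        t0 = time.monotonic()
        class_rows = []
        for c in calls:
            if not c.is_asb:
                continue
            cls = classify_asb(c, scores_by_snp.get(c.snp_id, []), qualities)
            class_rows.append(
                {
                    "ID": c.snp_id,
                    "tf": c.tf,
                    "cell_line": c.cell_line,
                    "CAR": round(c.car, 6),
                    "isASB": True,
                    "ASB_quality": cls.quality,
                    "motif": cls.attributed_motif or "",
                    "motif_class": cls.attributed_class or "",
                }
            )
        classified_df = pd.DataFrame(
            class_rows,
            columns=["ID", "tf", "cell_line", "CAR", "isASB", "ASB_quality", "motif", "motif_class"],
        )
        classified_df.to_csv(out / "classified_asbs.tsv", sep="\t", index=False)
        stage("asb_classification", len(classified_df), t0)

        # --- summary --------------------------------------------------------
        t0 = time.monotonic()
        summary = summarize_distinct(
            classified_df.rename(columns={"ID": "snp_id", "ASB_quality": "quality"})
        )
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        stage("summary", summary["n_rows"], t0)

        # --- comparator statistics ------------------------------------------
        t0 = time.monotonic()
        comparator: dict = {"skipped": None}
        high_ids = set(
            classified_df.loc[classified_df["ASB_quality"] == "High", "ID"]
        )
        with_maf = [s for s in snps if s.maf is not None]
        targets = [s for s in with_maf if s.snp_id in high_ids]
        if not targets:
            comparator["skipped"] = "no high-quality ASBs with MAF annotation"
        else:
            try:
                pool = build_nonasb_pool(with_maf, calls, min_reads=config.comparator_min_reads)
                sets = sample_maf_matched(
                    pool,
                    targets,
                    rel_tol=config.comparator_rel_tol,
                    n_sets=config.comparator_n_sets,
                    seed=config.seed,
                )
                snp_by_id = {s.snp_id: s for s in snps}
                obs = conservation_counts(targets)
                null_cons = []
                null_noncons = []
                for ids in sets.sampled_sets:
                    cc = conservation_counts([snp_by_id[i] for i in ids])
                    null_cons.append(cc.n_conserved)
                    null_noncons.append(cc.n_nonconserved)
                comparator = {
                    "skipped": None,
                    "n_targets": len(targets),
                    "n_pool": len(pool),
                    "n_sets": config.comparator_n_sets,
                    "observed_conserved": obs.n_conserved,
                    "observed_nonconserved": obs.n_nonconserved,
                    "p_conserved_greater": empirical_pvalue(obs.n_conserved, null_cons, "greater"),
                    "p_nonconserved_less": empirical_pvalue(obs.n_nonconserved, null_noncons, "less"),
                    "median_set": sets.median_set,
                }
            except ValidationError as exc:
                comparator["skipped"] = str(exc)
        with open(out / "comparators.json", "w") as fh:
            json.dump(comparator, fh, indent=2, sort_keys=True)
        stage("comparator_stats", 0 if comparator.get("skipped") else len(targets), t0)

        manifest["complete"] = True
    finally:
        manifest["total_seconds"] = round(time.monotonic() - t_all, 3)
        manifest["artifacts"] = {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
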