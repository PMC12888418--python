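# asbkit

Allele-specific transcription-factor binding (ASB) inference from ChIP-seq
allelic read counts, with motif-level mechanistic classification. The package
covers the full analysis path:

1. **Ingest** — heterozygous SNP tables (with genotype-quality filtering and
   per-cell-line reference allele frequencies, RAF), BED peak calls, JASPAR
   PFM motif sets, FASTA genomes, and allelic counts either tabular or
   extracted from indexed BAM alignments.
2. **ASB inference** — a beta-binomial Bayesian model of the latent allelic
   balance with copy-number (RAF) and reference-mapping-bias correction,
   sampled by random-walk Metropolis–Hastings on the logit scale. Outputs a
   corrected allelic ratio (CAR), a shortest highest-posterior-density (HPD)
   interval and an `isASB` call (HPD excludes 0.5).
3. **De novo motif discovery** — k-mer read-start profiles over genomic k-mer
   occurrences (no peak calls needed), enrichment-based k-mer selection, and
   greedy assembly into probability-matrix motifs.
4. **Motif analysis** — log-odds PWM scanning, FPR-calibrated match
   thresholds (exact enumeration or Monte Carlo), ±25 bp SNP-window scoring
   with the motif score difference (MSD = REF score − ALT score), de Bruijn
   sequence similarity, edge trimming, single-linkage motif clustering, and
   classification of discovered motifs as redundant / accessory / de novo
   against a known-motif database.
5. **Classification** — motif quality via the Spearman correlation between
   CAR and MSD across in-peak matching SNPs; High / Low / Unclassified ASB
   labelling with JASPAR → accessory → de-novo attribution priority; distinct
   TF–SNP summarization across cell lines.
6. **Comparator statistics** — MAF-matched resampling of never-ASB,
   high-coverage SNP sets, empirical p-values, conservation-score counts and
   Wilcoxon rank-sum tests.
7. **Synthetic fixtures** — a deterministic generator of miniature genomes,
   motifs, SNPs, peaks, counts and reads with planted motif-disrupting ASBs
   and a full latent truth table, so everything above is testable offline.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, property/invariant tests, and
`tests/test_acceptance.py` with the simulation-based acceptance criteria
(null calibration, parameter recovery, CNV correction, dual-route oracle
equivalence, motif machinery, end-to-end planted recovery).

## Command line

```sh
asbkit simulate --seed 0 --out-dir fixture/ --make-reads
asbkit infer    --counts fixture/counts.tsv --snps fixture/snps.tsv --out calls.tsv
asbkit discover --reads fixture/reads.bed --genome fixture/genome.fa --out nopeak.jaspar
asbkit score    --motifs fixture/motifs.jaspar --genome fixture/genome.fa \
                --snps fixture/snps.tsv --peaks fixture/peaks.bed --out scores.tsv
asbkit classify --calls calls.tsv --scores scores.tsv \
                --out-classified classified.tsv --out-quality quality.tsv
asbkit run-all  --config config.yaml            # full pipeline from YAML
asbkit count    --alignments rep1=a.bam --snps snps.tsv --out counts.tsv
asbkit compare  --snps snps.tsv --calls calls.tsv --targets ids.txt --out cmp.json
```

Exit codes: 0 success, 2 validation/configuration error, 3 runtime error.
`run-all` writes per-stage TSV artifacts plus a `manifest.json` recording
input hashes, parameters, row counts and timings; reruns with identical
inputs reproduce identical artifact checksums.

A minimal `run-all` YAML config:

```yaml
genome: fixture/genome.fa
peaks: fixture/peaks.bed
snp_table: fixture/snps.tsv
counts: fixture/counts.tsv
jaspar_pfm: fixture/motifs.jaspar
reads: fixture/reads.bed   # optional; enables de novo discovery
output_dir: out/
tf: TF1
cell_line: CL1
seed: 1
```

## Library example

```python
from asbkit.inference import AllelicCount, ModelConfig, infer_asb

counts = [AllelicCount("rs123", "rep1", ref_count=40, alt_count=12)]
call = infer_asb(counts, raf=0.5, config=ModelConfig(seed=1))
print(call.car, (call.hpd_lo, call.hpd_hi), call.is_asb)
```
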