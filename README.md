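# xspec

A toolkit for cross-species tumor genome analysis downstream of read
alignment: dual-caller consensus calling, orthogonal validation of candidate
mutations by allele-fraction rules, ROC evaluation of caller quality scores,
genome-wide mutation-burden extrapolation, substitution-spectrum and
trinucleotide-context analysis, and cross-species ortholog / cohort-frequency
comparison. A first-class synthetic-data module generates every input the
pipeline consumes with known ground truth, so the whole pipeline is testable
end to end without external data.

## Modules

| Module | What it does |
| --- | --- |
| `xspec.synthdata` | Synthetic reference FASTA, toy gene-model BED, planted germline/somatic truth sets, simulated caller VCFs, deep validation readcounts, ortholog/cohort/DE tables, toy signature matrices |
| `xspec.callsets` | VCF ingestion (SNVs, multi-allelic split), consensus/overlap reports, quality-quartile stratification, stratified validation-panel draws |
| `xspec.validation` | SOMATIC / GERMLINE / FAIL classification from tumor/normal allele fractions, validation rates with Wilson intervals, ROC/AUC |
| `xspec.mutspectrum` | Burden extrapolation and per-Mb rates, pyrimidine-normalized 6-class / 96-context spectra, dipyrimidine report, exon/intron/intergenic breakdown, cosine signature similarity |
| `xspec.crossspecies` | Best-score ortholog mapping, gene-set overlap with Fisher enrichment, per-gene cohort mutation frequencies and baseline-vs-resistant contrasts |

## Classification rules

Validation readcounts are classified with fixed allele-fraction cutoffs
(configurable; allele fraction = alt / (ref + alt)):

* **SOMATIC** — tumor AF ≥ 5% and normal AF < 2%
* **GERMLINE** — tumor AF ≥ 5% and normal AF ≥ 2%
* **FAIL** — tumor AF < 5%

## CLI

```bash
# generate a complete synthetic input set
xspec simulate --config sim.yaml --outdir sim/

# consensus of two caller VCFs
xspec consensus sim/callerA.vcf sim/callerB.vcf --out consensus.json

# stratified validation panel (overlap, unique-per-caller, per-quartile cap)
xspec panel sim/callerA.vcf sim/callerB.vcf --design 128,128,48 --seed 1 --out panel.tsv

# classify validation readcounts
xspec validate sim/readcounts.tsv --tumor-af-min 0.05 --normal-af-max 0.02 --out verdicts.tsv

# substitution spectrum + region breakdown
xspec spectrum variants.tsv --reference sim/reference.fa --bed sim/genes.bed --out spectrum.json

# burden extrapolation
xspec rate --n-called 13811 --validation-rate 0.23 --genome-size 1412464843

# cohort frequency comparison
xspec xspecies --baseline tcga.tsv --resistant resistant.tsv \
    --genes BUB1B,PINK1,COL16A1 --baseline-size 346 --resistant-size 78
```

Example `sim.yaml`:

```yaml
seed: 5
genome: {n_chroms: 1, chrom_length: 100000, gc_fraction: 0.5}
variants:
  n_somatic: 2000
  germline_rate: 0.005
  spectrum_weights: [0.1, 0.1, 0.6, 0.05, 0.1, 0.05]
  context_fractions: {TCA: 0.17, TCG: 0.10, TCC: 0.05}
callers:
  - {name: callerA, sensitivity: 0.8, false_positive_rate_per_mb: 4000, score_informative: true}
  - {name: callerB, sensitivity: 0.8, false_positive_rate_per_mb: 4000, score_informative: false}
validation: {depth: 1000, error_rate: 0.002}
cross_species: {n_fish_genes: 200}
```

## Conventions

* Coordinates are 1-based inclusive internally (VCF convention); BED input
  and output are 0-based half-open.
* Variant identity is `(chrom, pos, ref, alt)` with an optional `chr` prefix
  stripped; quality and depths never participate in matching.
* Burden extrapolation floors the expected count and per-Mb display values
  are truncated (not rounded) to two decimals; full precision is always
  retained programmatically.
* All generators take explicit seeds and are deterministic; no global RNG
  state is used.
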