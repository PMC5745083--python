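# flymosaic

Tools for quantifying the stochastic ON/OFF photoreceptor mosaic of the fly
retina and the analyses that link a regulatory single-base insertion to that
mosaic and to color preference:

- **`flymosaic.segmentation`** — automated R7 counting from two-channel
  (Rh3/Rh4) retina images: homomorphic denoising, Canny edge detection,
  convex-hull rough segmentation, morphological active-contour refinement,
  marker-based watershed, size/center-distance exclusion, and normalized
  two-channel classification into RH3/RH4/AMBIGUOUS calls with the
  per-retina %ON summary. Circular-ROI mean-intensity quantification is
  included.
- **`flymosaic.gwas`** — simulation of a panel × deficiency cross at the
  genotype level (homozygous reference preserved; homozygous alternate kept
  inside the deficiency interval, heterozygous outside; everything else
  missing), relationship-matrix PC covariates, per-variant OLS association,
  max(T) permutation for family-wise error, and Bonferroni thresholds.
- **`flymosaic.kmers`** — reverse-complement-canonical k-mer counting,
  consensus-distance orientation, read-level binding-site counts with
  McNemar's test, frequency-rank statistics against the canonical k-mer
  universe, positional-dependence grids, count-based PWMs and log-odds
  scoring, and single-base insertion arithmetic.
- **`flymosaic.popgen`** — Hudson (and Weir–Cockerham) FST, inverse-normal
  rank Z-scores, EHH decay profiles, physical-distance iEHH,
  IHS = log2(iEHH_derived / iEHH_ancestral), matched 1–2 bp indel control
  sets, and empirical percentile placement.
- **`flymosaic.behavior`** — T-maze preference index
  PI = (N_G − N_B)/(N_G + N_B), per-line mean ± SEM, and Welch group
  comparison.
- **`flymosaic.synthetic`** — seeded generators for every input: hexagonal
  Gaussian-spot mosaics with multiplicative illumination bias, inbred-line
  cohorts with a planted causal indel, Boltzmann-resampled SELEX read
  cycles, copying-model haplotype panels with tunable partial sweeps, and
  binomial two-choice trials.
- **`flymosaic.io` / `flymosaic.pipeline`** — minimal VCF v4.2, two-channel
  TIFF / paired PNG, FASTA/FASTQ (gzip-aware), TSV tables, and an
  end-to-end runner that writes a sha256 manifest.

## Command-line interface

Everything is exposed under one `flymosaic` entry point:

```sh
flymosaic simulate-retina --seed 1 --out out/sim
flymosaic count-retina --image out/sim/retina.tif --out out/counts
flymosaic simulate-cross --vcf lines.vcf --deficiency 3R:16200000-16400000 --out progeny.vcf
flymosaic gwas --vcf lines.vcf --pheno pheno.tsv \
    --deficiency 3R:16200000-16400000 --pcs 20 --perms 10000 --seed 1 \
    --out assoc.tsv
flymosaic selex-kmers --reads c0.fasta --reads c4.fasta --k 10 \
    --consensus CGCCCACGCA --out out/kmers
flymosaic ehh-scan --haps haps.vcf --focal 3R:16410775 --threshold 0.05 --out out/ehh
flymosaic fst --freqs freqs.tsv --pops NA,EU --out fst.tsv
flymosaic tmaze-pi --trials trials.tsv --out pi.tsv
flymosaic run-all --seed 1 --out out/pipeline   # synthetic end-to-end smoke run
```

## Conventions

Genome coordinates are 1-based inclusive (VCF convention); pixel
coordinates are 0-based (row, col). All generators are pure functions of
their configuration and seed.
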