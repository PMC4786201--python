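# methinfo

Information-thermodynamic analysis of cytosine DNA methylation.

`methinfo` treats per-cytosine methylation levels as Bernoulli random
variables and quantifies methylation change between samples in information
units: binary Shannon entropy per site, summed absolute entropy change per
genomic region (bits), the corresponding minimum dissipated energy under
Landauer's principle, and three information divergences (total variation,
Kullback-Leibler, squared Hellinger). The distribution of these quantities
over genome tiles is modelled with three-parameter Weibull and
generalized-gamma laws fitted by nonlinear least squares against the
empirical CDF; the fitted scale parameter's trend with region length yields
DNA persistence-length estimates via linear (long-fragment) and exponential
(entropic-spring, short-fragment) regressions. Sites and regions whose
divergence falls in the extreme tail of the fitted noise distribution are
called as differentially informative methylated positions/regions
(DIMPs/DIMRs) by signal-detection thresholding, with Fisher's exact test as
the classical comparator. A binary "methylation language" layer partitions
the pooled methylation string into word frameworks (PWFs), decomposes long
words into sentences, and fits the exponential word-length decay law with
its Helmholtz free-energy summary.

## Layout

| module | contents |
| --- | --- |
| `methinfo.methylome_io` | count-table readers (generic / Bismark-CX / methratio dialects), multi-sample union matrices, genome tiling, BED output |
| `methinfo.info_measures` | site entropy, region information, Landauer energy, TV/KL/HD divergences, per-tile summaries |
| `methinfo.dist_models` | Weibull and generalized-gamma CDFs, ECDF least-squares fitting, Stein adjusted R², AIC/BIC model selection |
| `methinfo.polymer_mechanics` | scale-vs-length trends and persistence-length estimation |
| `methinfo.signal_detection` | DIMP/DIMR calling, Fisher comparator, anchor-centred call-density profiles |
| `methinfo.methyl_language` | binarization, PWF partition/decomposition, length spectra, decay-law fits |
| `methinfo.simulate` | seeded generators for methylomes, divergence-structured sample pairs, scale trends and word strings |
| `methinfo.cli` | `methinfo` command-line entry point |

## CLI

```sh
# simulate a reference/query pair with 100 spiked sites
methinfo simulate pair --seed 1 --n-spiked 100 --out sim/

# per-tile information/divergence table
methinfo tile-info --ref sim/ref.tsv --query sim/query.tsv \
    --chrom-sizes sizes.tsv --tile-size 3000 --out tiles.tsv

# fit the noise model and call regions
methinfo fit-dist --input tiles.tsv --model weibull --column HD \
    --tile-size 3000 --out fit.tsv
methinfo dimr --tile-info tiles.tsv --divergence HD --alpha 0.05 \
    --out dimrs.bed

# site-level calls (fits the site-divergence null internally)
methinfo dimp --ref sim/ref.tsv --query sim/query.tsv --divergence HD \
    --alpha 0.05 --out dimps.bed

# persistence length from a table of (l, lambda) fits
methinfo persistence --input lambdas.tsv --model linear --unit bp --out lp.tsv

# methylation words and their length-decay law
methinfo pwf --inputs sim/ref.tsv --inputs sim/query.tsv --d 6 --out pwf.bed

# full pipeline from a YAML config, with an output manifest
methinfo run --config config.yaml --out run/
```

Coordinates are 1-based closed internally; BED files are written 0-based
half-open. Sites with zero coverage are treated as missing observations
(entropy 0 by convention, excluded from divergences), and strands are kept
separate throughout.

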