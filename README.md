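# sporesnp

Single-nucleus SNP filtering, intra-spore diversity statistics, and karyon
inference for multinucleate fungal spores.

Arbuscular mycorrhizal fungi carry hundreds of nuclei per asexual spore.
When individual nuclei are sorted, whole-genome amplified and sequenced,
the resulting per-nucleus variant calls are noisy: amplification produces
wildly uneven coverage and locus dropout, and each nucleus is haploid.
`sporesnp` implements the post-calling analysis for such data:

- **Filter chain** (`sporesnp.filtering`): site-level hard filtering on
  quality annotations (QD, FS, MQ, MQRankSum, ReadPosRankSum, QUAL, SOR;
  strict thresholds, boundary values pass), per-nucleus majority-rule
  haploid genotype calls, masking of unreliable cells (depth < 5 and/or
  allele fraction strictly inside (0.1, 0.9)), and removal of sites with
  more than 1/3 missing calls across nuclei.
- **Diversity statistics** (`sporesnp.diversity`): total / non-repeat /
  coding SNP counts and the SNPs-per-kilobase density over the non-repeat
  portion of the assembly, with exact interval arithmetic for the
  denominator.
- **Karyon inference** (`sporesnp.karyon`): average-linkage bipartition of
  nuclei on pairwise Hamming distance, a within-site permutation null for
  the partition score, and a verdict — homokaryon-consistent,
  heterokaryon-consistent, or undetermined — combining the partition
  evidence with SNP-density bands.
- **Synthetic spore simulator** (`sporesnp.synthetic`): reference models
  with repeat/coding masks, homokaryotic and heterokaryotic nucleus
  populations with known truth sets, and per-nucleus observations with
  overdispersed depth, dropout, per-read error and quality gating —
  everything needed to exercise and validate the pipeline without raw
  reads.
- **I/O** (`sporesnp.io`): minimal VCF v4.2 (per-sample GT/DP/AD), BED
  masks (0-based half-open), truth/report TSVs.

## Test

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` contains the end-to-end recovery criteria
(exact truth-set recovery on noiseless data, density recovery within 15%,
homokaryon noise floor, ≥95% karyon classification accuracy); the whole
suite runs in a couple of minutes on one CPU.

## CLI

```sh
# end to end on a synthetic spore described in a YAML config
sporesnp all --config config.yaml --out-dir run/

# individual stages
sporesnp simulate --config config.yaml --out-dir fixture/
sporesnp filter --vcf fixture/observations.vcf --out-dir out/
sporesnp density --vcf fixture/observations.vcf \
    --reference-tsv fixture/reference.tsv \
    --repeats-bed fixture/repeats.bed --coding-bed fixture/coding.bed \
    --out-dir out/
sporesnp karyon --vcf fixture/observations.vcf \
    --reference-tsv fixture/reference.tsv \
    --repeats-bed fixture/repeats.bed --out-dir out/ --seed 1
```

Example config:

```yaml
seed: 11
simulate:
  genome_size: 1000000
  n_contigs: 5
  repeat_fraction: 0.2
  coding_fraction: 0.1
  n_nuclei: 19
  mode: heterokaryon
  divergence_per_kb: 0.5
  mean_depth: 30
  error_rate: 0.005
  dropout_rate: 0.1
mask_rule:
  combine: AND       # or OR; the masking sentence is ambiguous
max_missing_fraction: 0.333333333333333  # default is exactly 1/3
```

Every run writes a `manifest.json` (seed, config hash, stage counts), so a
result is reproducible from its manifest. `filter_report.tsv` records the
per-stage site/cell removals, including a separate count of SNPs where
every non-missing call is ALT (possible assembly-consensus artifacts).

## Notes on conventions

- VCF positions are 1-based; BED intervals are 0-based half-open; all
  internal arithmetic is 0-based half-open.
- Only biallelic records are supported (`max_alternate_alleles = 1`);
  multi-allelic records are rejected with an explicit error.
- All simulator randomness flows through `numpy.random.default_rng(seed)`;
  identical seeds give byte-identical fixtures.
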