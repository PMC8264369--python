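# popdiv

Population-genomic analysis toolkit for SNP panels contrasting a
high-diversity ("weedy") pool against a bottlenecked ("cultivated") pool:

- **variant_io** — VCF 4.2 in/out (invariant sites supported), GATK-style
  hard filters (QUAL/QD/FS/MQ/SOR; per-genotype DP/GQ/RGQ masking for
  invariant sites), MAF ≥ 0.05 / missingness ≤ 0.50 site selection.
- **diversity** — pixy-style nucleotide diversity π (ratio of summed
  mismatches over summed comparisons, invariant sites included), H_O/H_E,
  and pairwise F_ST (Hudson ratio-of-sums default, Weir–Cockerham 1984
  optional).
- **ld_decay** — composite (unphased genotype-correlation) LD r², distance
  binned decay curves, half-of-maximum decay distance (raw or smoothed).
- **popstruct** — ADMIXTURE-style Q-matrix group assignment (argmax
  component with a ≥ 0.80 coefficient, otherwise MOSAIC) and PCA with
  Patterson scaling, mean imputation and percent variance explained.
- **phylo** — diploid allele-sharing p-distances (pairwise deletion),
  Saitou–Nei neighbor joining with deterministic tie-breaking, bootstrap
  supports (site resampling, default 1000 replicates), Newick output.
- **sweep_scan** — 100-kb / 10-kb sliding windows, per-window π_w, π_c,
  F_ST and π-ratio, joint empirical top-5% outlier calling (thresholds
  overridable), region merging, candidate-gene extraction from GFF3/BED.
- **synthetic_data** — Balding–Nichols two-pool generator with planted
  sweeps, feral admixture (known Q), founder-mosaic haplotypes for LD
  decay, SLAF-like per-site missingness; writes VCF + truth fixtures.
- **pipeline** — YAML-configured orchestration with provenance headers and
  truth-comparison reporting for synthetic runs.

## Tests

```sh
python -m pytest tests/
```

`tests/test_acceptance.py` holds the acceptance criteria. One family is
expected to fail by design: `TestCriterion5SweepRecovery::test_precision`
asserts a precision bound that is geometrically unattainable under the
stated window/quantile parameters (see the test's docstring); it is kept
failing rather than weakened.

## CLI

```sh
popdiv simulate --out-dir fixture --n-weedy 20 --n-cultivated 80 \
    --n-variant-sites 20000 --n-invariant-sites 5000 \
    --sweep chr1:1000000-1150000 --missing-max 0.5 --seed 1
popdiv filter --vcf fixture/genotypes.vcf --out filtered.vcf
popdiv diversity --vcf filtered.vcf --populations fixture/populations.tsv --out div.tsv
popdiv ld --vcf filtered.vcf --out ld.tsv
popdiv structure --qmatrix fixture/q_true.tsv --out groups.tsv
popdiv phylo --vcf filtered.vcf --replicates 1000 --seed 1 --out tree.nwk
popdiv sweep --vcf filtered.vcf --populations fixture/populations.tsv --out-prefix sweep
popdiv run-all --config pipeline.yaml
popdiv compare-truth --config pipeline.yaml --truth-dir fixture --out report.json
```

Exit codes: 0 ok, 1 user error, 2 internal error. Subcommand help:
`popdiv <cmd> --help`.

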