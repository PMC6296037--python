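# niptscreen

Trisomy screening from low-coverage whole-genome sequencing of cell-free
DNA (NIPT).  In non-invasive prenatal testing, cfDNA from maternal plasma —
a mixture of maternal and placental (fetal) fragments — is sequenced at low
coverage; a fetal trisomy inflates the fraction of reads mapping to the
affected chromosome by roughly half the fetal fraction.  Calling that
excess reliably requires a well-behaved control group of euploid samples,
careful reduction of technical variability, and statistics that compare
the test sample with the controls.

`niptscreen` provides the full workflow as composable building blocks:

* **Binning** — `bin_bam_sample` counts aligned reads of a
  coordinate-sorted, indexed BAM into 50 kb bins (0-based half-open,
  assignment by leftmost aligned base), optionally per strand;
  `compute_gc_table` derives per-bin GC content from a reference FASTA.
* **Control groups** — `as_control_group` plus `add_samples_controlgroup`,
  `remove_sample_controlgroup` and `remove_duplicates_controlgroup`
  maintain ordered collections with a homogeneous correction status.
* **Variation reduction** — `gc_correct` (weighted-bin or LOESS GC
  correction) and `chi_correct` (chi-squared variation reduction, χ²VR:
  bins whose between-control variability exceeds chance expectation are
  down-weighted by their variance-inflation factor χ²/df).
* **Prediction** — three statistics of the chromosomal fraction
  *f* = reads(chr) / total autosomal reads:
  * standard **Z-score**: *z* = (*f*<sub>sample</sub> − μ̂) / σ̂ with μ̂, σ̂
    the control mean and (n−1) SD;
  * **NCV** (normalized chromosome value): the same standardization applied
    to the ratio reads(chr)/Σ reads(D), where the denominator set D is
    chosen by `prepare_ncv` through exhaustive subset search to minimize
    the control-group coefficient of variation;
  * **RBZ** (regression-based Z): `perform_regression` predicts the
    chromosome's fraction from other chromosomes' fractions (forward and
    reverse strands as separate predictors) by forward-stepwise linear
    regression on a train split of the controls, then standardizes the
    observed/predicted ratio with the test split's CV (or a counting-noise
    theoretical CV when that is larger); four independent models by
    default.
  A score outside −3…3 is the conventional trisomy call; chromosomes 13,
  18 and 21 are excluded as predictors/denominators by default.
* **Quality control** — `match_control_group` (Match QC: mean sum of
  squared fraction differences against each control, flagged when more
  than 3 SD from the controls' own scores; or selection of the
  best-matching subset) and `diagnose_control_group` (leave-one-out
  Z-scores for every control; samples with more than one aberrant score
  are proposed for removal).
* **Synthetic data** — `simulate_binned_sample`/`simulate_control_group`
  generate multinomial bin counts on a scaled genome with a smooth GC-bias
  response, bin-level overdispersion, strand splitting and a
  fetal-fraction-scaled trisomy signal, carrying exact expected fractions
  as ground truth; `write_toy_bam` realizes explicit per-bin read ledgers
  as indexed BAM files.

## Worked example

Simulate a control group and a trisomy-21 sample at 10 % fetal fraction,
then score it:

```sh
niptscreen simulate --n-controls 25 --trisomy 21:0.10 --seed 7 \
    --sample-out sample.json --group-out controls.json
niptscreen predict z sample.json controls.json --chromosome 21
```

```json
{
  "chromosome": "21",
  "control_group_statistics": {
    "SD": 4.630272341111066e-05,
    "Shapiro_P_value": 0.385392487937612,
    "mean": 0.016580754551731802
  },
  "n_controls": 25,
  "sample_fraction": 0.017486517370349598,
  "z_score": 19.561761207342975
}
```

The control samples map 1.658 % of their autosomal reads to chromosome 21
(SD 4.6×10⁻⁵; the Shapiro–Wilk P of 0.39 is above 0.05, so the control
fractions can be treated as normally distributed).  The test sample's
1.749 % exceeds that by 19.6 control SDs — far outside the −3…3 range, a
clear trisomy-21 call.  The regression-based score agrees:

```sh
niptscreen predict rbz sample.json controls.json --chromosome 21 --seed 7
```

```
Regression-based Z, chromosome 21:
  model 1: RBZ  20.326  CV 0.00294 (Practical CV)  test-set mean 1.0002  Shapiro_P 0.495  predictors [22+, 22-, 2+, 14-]
  model 2: RBZ  15.634  CV 0.00376 (Practical CV)  test-set mean 0.9996  Shapiro_P 0.866  predictors [22+, 10+, 20-, 17-]
  model 3: RBZ  20.217  CV 0.00288 (Theoretical CV)  test-set mean 1.0006  Shapiro_P 0.831  predictors [10+, 22+, 20-, 19+]
  model 4: RBZ  10.326  CV 0.00523 (Practical CV)  test-set mean 0.9997  Shapiro_P 0.027  predictors [22+, 1-, 11+, 1+]
```

All four models score well above 3.  Each line reports the coefficient of
variation of the test split (and whether the practical or the theoretical,
counting-noise CV was used), the test-set mean of observed/predicted
ratios (close to one, as it should be), the Shapiro–Wilk P of those
ratios, and the selected predictors (chromosome with `+` = forward,
`-` = reverse strand).

Full pipelines — binning a BAM, GC correction, χ²VR, prediction and QC in
one run — are driven by a YAML config through `niptscreen run`; see
`niptscreen --help` for the subcommands (`bin`, `gc-table`,
`control-group`, `correct`, `ncv-template`, `predict`, `qc`, `simulate`,
`run`).

## Documentation

`docs/methods.md` describes the statistical model, the correction
algorithms, the synthetic-data generator and the numerical design choices
in detail.
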