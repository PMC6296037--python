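# Methods

## Screening model

A sequenced cfDNA sample is reduced to read counts in fixed-width genomic
bins (default 50 000 bp, 0-based half-open intervals; a read belongs to
the bin containing its leftmost aligned base).  The quantity of interest
is the *chromosomal fraction*

    f_c = reads on chromosome c / total reads on autosomes 1–22,

computed over all strands; X and Y are binned and may be corrected, but
they never enter the autosomal denominator and no prediction statistic
targets them.  In a pregnancy with fetal fraction *ff* (the share of cfDNA
of placental origin), a fetal trisomy of chromosome c raises the expected
f_c by a factor of approximately 1 + ff/2: the placental contribution
carries three copies of c instead of two, and a placental fragment from c
is therefore 3/2 times as likely as in the euploid case.

Detection is a comparison with a control group of presumed-euploid
samples processed identically.  Three statistics are provided; each treats
the control group as an i.i.d. sample from the null and reports the
Shapiro–Wilk P-value of the control values so the user can judge the
normality assumption (values above 0.05 are conventionally acceptable;
the P-value is reported, never auto-enforced).

* **Z-score.**  z = (f_sample − mean(f_controls)) / sd(f_controls), with
  the (n−1) sample SD.  |z| > 3 is the conventional trisomy call
  (nominal two-sided rate 0.27 % under normality; with n controls the
  exact null is a scaled t with n−1 degrees of freedom, ≈ 0.36 % at
  n = 100).
* **NCV.**  The same standardization applied to the ratio
  R = reads(c) / Σ_{d∈D} reads(d).  The denominator set D is chosen once
  per control group (`prepare_ncv`) by exhaustive enumeration of all
  non-empty subsets of the candidate autosomes up to `max_denominators`
  (default 9), minimizing the coefficient of variation sd/mean of the
  control ratios.  Candidates exclude the chromosome of interest and, by
  default, the common trisomy candidates 13, 18 and 21 (a trisomic
  denominator would contaminate the reference).  An optional train/test
  split (default 60/40) selects D on the train controls and estimates the
  reference mean/SD/CV on the held-out test controls to avoid optimizing
  and evaluating on the same data.  Exact CV ties break toward the
  lexicographically smallest chromosome set, making the search
  deterministic.  A subset count above 10⁶ is refused with advice to
  lower `max_denominators`.
* **RBZ (regression-based Z).**  Chromosomal fractions are correlated
  across chromosomes (shared technical factors); the fraction of the
  chromosome of interest can therefore be *predicted* from the others.
  Per model (default 4), the controls are randomly split into train
  (default 60 %) and test sets; up to `n_predictors` (default 4)
  predictor fractions — each (autosome, strand) pair, excluding the
  chromosome of interest and the default-excluded candidates — are chosen
  by forward-stepwise selection, adding at each step the predictor that
  most reduces the residual sum of squares of an ordinary least-squares
  fit on the train set.  On the test set the ratios
  VR_i = observed_i/predicted_i yield the practical CV = sd(VR)/mean(VR)
  and the test-set mean (close to one when the model generalizes).  The
  reported CV is max(practical, theoretical) unless `force_practical_cv`;
  the *theoretical CV* is the counting-noise floor
  sqrt(1/E[reads on c] + 1/E[reads on predictor set]) (Poisson/binomial
  approximation, expectations taken over the test controls) — a
  practical CV below this floor indicates an over-fitted model, in which
  case the floor is the honest uncertainty.  The score is
  RBZ = (VR_sample − 1)/CV.  Four predictors keep the models
  parsimonious for control groups of ~100 samples; the per-model splits
  are drawn from one seeded generator, so a fixed seed reproduces the
  result bit for bit.

The fraction denominator deliberately includes the chromosome of interest
(standard Z-score convention); sample SDs use n−1 normalization
throughout.

## Variation reduction

**GC correction** removes the smooth dependence of bin counts on GC
content.  Both methods build their correction from *usable autosomal
bins* — bins whose reference N fraction is ≤ 0.2; bins dominated by
assembly gaps (centromeres, telomeres) carry no signal and are zeroed
rather than dropped, so vector geometry is stable.  Corrections are
computed per strand when counts are strand-separated, and from each
sample's own counts (a per-sample bias profile); X/Y receive the
autosome-derived correction only when `include_XY` is set, with the two
correction-status lists tracking autosomes and sex chromosomes
separately.

* *Weighted-bin*: bins are grouped by GC fraction rounded to 0.01 (one
  percentage point — at 50 kb bins an autosomal genome populates each
  group with hundreds of bins); a group g with at least 10 usable bins
  gets weight w_g = m/m_g, where m is the global mean count of usable
  bins and m_g the group mean, so every retained group's corrected mean
  equals m exactly.  Groups below the size floor, or with zero mean, are
  zeroed.
* *LOESS*: a locally weighted regression of usable-bin counts on GC
  fraction (span 0.75) supplies fitted values; corrected count =
  raw × m/fitted, with fitted values floored at 10⁻⁶·m to avoid division
  blow-ups at sparse GC extremes.

**Chi-squared variation reduction (χ²VR)** targets genomic regions whose
*between-sample* variability exceeds counting expectation (fragile sites,
mapping artifacts).  Control samples are first scaled so each total
autosomal count equals the group mean (the statistic compares samples, so
they must sit at a common depth).  Per bin b, over the scaled controls:
χ²_b = Σ_s (x_sb − E_b)²/E_b with E_b the control mean (bins with
E_b = 0 are skipped), df = n−1, and the normal-approximation score
(χ²_b − df)/sqrt(2 df).  Bins with score > 3.5 (a z-style cutoff,
independent of df; configurable) are flagged, and their counts are
divided by the variance-inflation factor χ²_b/df in the test sample and
in every scaled control.  Two consequences used as tests: flagged-bin
counts only ever shrink (χ²/df > 1 whenever the score is positive), and
recomputing χ² on the corrected controls returns exactly df for every
flagged bin.  The test sample never contributes to E_b or χ²_b — a
trisomy must not dilute its own evidence; it only receives the per-bin
divisors.  χ²VR requires an identical correction status between sample
and group and may follow GC correction or run on uncorrected counts, but
never precede a GC step.  When strands are separated, each strand's bin
series is tested and flagged independently.

**Match QC** measures control-group representativeness: per control c,
SS_c = Σ over autosomes (and strands, when separated) of
(f_sample − f_c)²; the match score is the mean of the SS_c.  The
reference distribution is built leave-one-out — each control scored
against the remaining controls — and a match score more than 3 SD from
that reference flags the group as unsuitable for the sample.  Subset mode
instead returns the n controls with the smallest SS_c as a
sample-specific control group.  Autosomal fractions only, consistent with
the prediction denominator.

**Diagnostics** score every control against the others with the same
standardization as the Z statistic, per chromosome and strand.  Entries
with |z| > 3 are aberrant; a sample with more than one aberrant entry is
a removal candidate.  Curation itself is left to the user — automated
pruning loops are deliberately out of scope.

## Synthetic data generator

The generator emulates the count structure of low-coverage cfDNA
sequencing on a *scaled genome*: per-chromosome bin counts proportional
to the real chromosome lengths at one 50 kb bin per 500 kb of genome
(~5 750 autosomal bins, chromosome 21 ≈ 96 bins), so the full pipeline
runs in milliseconds per sample while relative chromosome fractions — the
quantities every statistic consumes — match the real genome.  Defaults
describe a typical screening run and are fixed once:

| parameter | default | rationale |
|---|---|---|
| total_reads | 10 000 000 | mid-range of the 5–20 M reads/sample regime of low-coverage NIPT |
| gc_bias β | 0.5 | count weight ∝ 1 + β(gc − 0.5): a moderate, clearly detectable smooth bias |
| overdispersion | 3×10⁻⁴ | extra relative variance of gamma-perturbed bin weights; gives a bin-level variance/mean ratio ≈ 1.5 at the default depth and a chromosome-21 fraction CV ≈ 0.3 %, matching well-corrected real data |
| Y weight | ×0.01 | female-fetus pregnancies dominate; only residual mismapping reaches Y |
| strands | separated | forward/reverse splits are binomial 50/50 |

Counts are drawn multinomially over all bins; a trisomy scales the
affected chromosome's expected weight by 1 + ff/2; gap bins (N fraction
1, 2 % of bins in the synthetic GC tables) receive weight 0; optional
chromosome-level inflation fabricates low-quality outlier samples, and an
optional per-bin extra-variance map (shared across a group's samples)
plants region-specific overdispersion for χ²VR tests.  Every sample
carries its closed-form expected fractions as ground truth.  Toy BAM
files realizing explicit per-bin ledgers (reads spread across each bin,
including its first base) exercise the binning path end to end.

What the generator does *not* model: fragment-length and end-motif
structure, maternal copy-number variants, mappability and blacklist
effects, batch- or flow-cell-level correlation between samples, and
GC-bias profiles that differ between samples.  Passing tests therefore
demonstrate the statistics' correctness and calibration under clean
multinomial-with-overdispersion conditions, not robustness to every real
artifact — that is what the QC tools are for on real data.

Under these conditions the suite verifies, among others: Z/NCV/Match
QC/χ² agreement with brute-force oracles to 10⁻¹² relative; the NCV
search against full enumeration; euploid |Z| > 3 rates at the nominal
0.27 % (10 000 replicates against 100 controls); trisomy-21 detection
(Z > 3) in ≥ 95 % of replicates at 4 % fetal fraction, and all four RBZ
models > 3 at 10 %; and recovery of planted 3×-variance bins by χ²VR.
Problem sizes (scaled genome, 100-sample groups, 200 detection
replicates) were chosen as the smallest at which these rates are stable.

## Numerical and interface choices

* Reference names are normalized by stripping a leading "chr";
  anything other than 1–22/X/Y is skipped with a logged count, never an
  error.  Duplicate-flagged reads are kept by default and no
  mapping-quality filter is applied (`--exclude-duplicates`,
  `--min-mapq` opt in), since neither filter is part of the method
  definition.
* Serialization is plain text: samples and control groups as JSON
  (optionally gzipped), GC tables and χ² reports as TSV.  Workflow
  reports are JSON with sorted keys plus a human-readable rendering, and
  embed a manifest (version, seed, thresholds, inputs); given fixed seeds
  the report bytes are reproducible.  On a mid-workflow failure the
  partial report is still written together with an error block.
* Exit codes: 2 input errors, 3 degenerate statistics, 4 configuration
  errors (including a chi-before-GC correction order, rejected before any
  compute), 5 status mismatches.
* Duplicate identity in control groups is the sample id, the user-facing
  handle; count equality would be fragile under floating-point
  correction.
* Shapiro–Wilk P-values are computed with the standard algorithm (scipy)
  and reported as NaN for fewer than 3 values or a constant vector.
* Stepwise selection drops rank-deficient (collinear) candidates with a
  warning rather than failing.

## Known limitations

* Sex-chromosome aneuploidies are not called; fetal fraction is not
  estimated (the trisomy signal scale must be judged externally).
* The theoretical CV is a counting-noise floor, not a full error model;
  with strongly overdispersed data the practical CV dominates anyway.
* The weighted-bin GC correction's group width (0.01) and size floor
  (10 bins) are tuned for ~50 kb bins on genome-scale data; very small
  toy genomes can zero sparse GC groups.
* χ²VR's normal approximation needs a handful of controls (≥ 3 enforced;
  ≥ 20 recommended) and assumes near-Poisson baseline counts; heavily
  overdispersed cohorts will see many bins down-weighted, which is the
  intended behaviour but reduces effective depth.
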