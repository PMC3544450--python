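# Methods

This note documents the statistical model behind `mirserum`, the
defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical conventions that matter when
reading results.

## Data model and conventions

The primary object is a Cp matrix: quantification-cycle values for a
panel of miRNA assays across serum samples. A cell is either a finite
Cp in (0, 40] cycles or *undetected*; undetected is an explicit state
(stored as NaN) and is never imputed anywhere in the pipeline. The
imputation-free choice is deliberate: limit-of-detection substitution
(e.g. scoring censored cells at Cp 35) biases location statistics in a
direction that depends on the censoring fraction, while the ≥60%
detection gate bounds the information lost by omission.

Sign conventions, fixed everywhere:

- lower Cp ⇔ more template ⇔ higher expression;
- after normalization, lower ΔCp ⇔ relatively more abundant within the
  sample;
- differential statistic T = mean ΔCp(disease) − mean ΔCp(control), so
  T < 0 means upregulated in disease (direction `UP`);
- paired log2 fold change = ΔCp(post) − ΔCp(pre), so values > 0
  (linear fc > 1) mean more abundant pre-surgery, i.e. in the disease
  state. The algebraically equivalent-looking exponent order
  "pre − post" would invert this meaning under the lower-Cp-is-more
  convention; the implementation uses post − pre so that "fold change
  > 2" always reads "more than twofold higher with the tumor in
  place". The opposite order is available via the `exponent` knob for
  literal comparisons with other software.

## QC and censoring

Three assay-level rules convert unreliable reactions to undetected, in
a fixed order so that every censored cell is attributed to exactly one
rule: (1) more than one melting-temperature peak; (2) Cp above the
fixed 35-cycle cap; (3) Cp within 5 cycles of the plate's negative
control. Rules 2 and 3 coincide when the negative control never
amplifies — an undetected negative control is conservatively treated
as the 40-cycle instrument maximum — but they diverge when a negative
control amplifies early, and both are enforced (the strictest
reading). The negative-control rule is applied per plate; a single
shared control reproduces per-run behavior. The filter is idempotent
and never resurrects a censored cell.

Hemolysis distorts circulating miRNA content (red cells release
miR-451 and relatives), so hemolyzed samples are excluded outright;
the flag is an input, and no hemoglobin-based scoring is attempted.

## Calibration and normalization

Interplate calibrators are replicate assays present on every plate.
The per-plate offset is (mean calibrator Cp on the plate) − (grand
mean of per-plate calibrator means), subtracted from every numeric
cell of the plate; with one plate this is the identity.

Global-mean normalization centers each sample on the mean Cp of *its
own detected miRNAs*: ΔCp(m, s) = Cp(m, s) − mean over detected m′ of
Cp(m′, s). "Expressed miRNAs" is read as the per-sample detected set —
the standard form of the method and the one robust to panel dropouts;
restricting to miRNAs detected in all samples is a documented
alternative rather than the default. Two consequences are asserted as
invariants after every normalization: each sample's detected ΔCp mean
is zero to 1e-9, and the pipeline is invariant to any per-sample
additive Cp shift (which subsumes plate offsets uniform within a
sample — calibration and normalization compose cleanly). The global
mean is computed before the ≥60% detection gate; the gate governs
which miRNAs are *tested*, not how samples are scaled.

## Permutation test

The test statistic is the difference of group means of detected ΔCp —
the simplest location statistic that reports fold direction and is
exactly enumerable. Two-sided p-values use |T|. The Monte-Carlo null
permutes group labels, applying one shared permutation per iteration
to all miRNAs: this preserves the inter-miRNA correlation of the joint
null at no cost to the per-miRNA marginal null, and is cheap (the
whole 742 × 56 × 10,000 computation is three matrix products). The
add-one estimator p = (1 + #{|T*| ≥ |T|}) / (1 + B) keeps p valid and
strictly positive (floor 1/(B+1)). Permutations that empty a group of
detected cells for some miRNA are excluded from that miRNA's
numerator and denominator. BH correction runs over exactly the gated,
tested family. The exhaustive enumerator (all C(n, k) label
assignments, guarded at ≤ 20 samples and ≤ 200,000 assignments) is
the package's own oracle and is tested to agree with Monte-Carlo
p-values within three binomial standard errors.

The detection gate boundary is inclusive (exactly 60% is tested).
Default significance threshold for the candidate funnel is adjusted
p < 0.05; selection on adjusted rather than raw p follows from the
fact that all reported p-values are BH-corrected. Both thresholds are
parameters.

The three-group analysis runs one-way ANOVA per gated miRNA on
detected ΔCp, BH-corrects the ANOVA family, and evaluates Tukey HSD
pairwise contrasts at 0.05 for miRNAs passing BH 0.05. The pattern
label is a pure function of the three pairwise flags; note the
taxonomy is asymmetric by design (there is a CIS_VS_BOTH label but no
OSCC counterpart), so a very large OSCC-only shift classifies as NONE
rather than OSCC_SPECIFIC — OSCC_SPECIFIC describes the regime where
only the OSCC-vs-control contrast clears the HSD.

## Paired analysis and candidate selection

Per patient, log2 fc = ΔCp(post) − ΔCp(pre); pairs with an undetected
member are missing and excluded, with the number of evaluable pairs
reported as the denominator of all fractions. The fold threshold is
strict (> 2-fold; exactly 2.0 does not count) and the recurrence
fraction threshold is inclusive (≥ 50%), which makes the
pre/post-swap antisymmetry exact: swapping timepoints maps f → 1/f and
exchanges fraction_up with fraction_down identically. At the 50%
boundary a miRNA can be recurrently up *and* down (fractions exactly
½ each); such rows are flagged ambiguous and warned about rather than
silently resolved.

A candidate must pass both analyses with concordant direction: BH
p < 0.05 in the cohort and the matching recurrence flag in the pairs.
Relaxing either threshold can only add candidates (tested as a
monotonicity property).

## Clustering and ROC

Samples are clustered on the 50 miRNAs with the highest SD of detected
ΔCp (ties broken lexicographically by id for determinism), using
average linkage on Pearson correlation distance (1 − r) computed on
pairwise-complete observations with at least three shared miRNAs per
pair. Pearson distance is the heatmap-standard choice and is invariant
to per-sample affine rescaling; Euclidean is available. Trees export
as newick with branch lengths from merge heights.

AUC is computed by the trapezoid rule over the empirical ROC (ties
stepped simultaneously), which equals the Mann–Whitney concordance
probability with ties counted ½ — asserted against a brute-force
pair-counting oracle. Marker orientation is chosen automatically so
AUC ≥ 0.5 and the flip is recorded. The operating point maximizes
Youden's J with ties broken toward higher specificity. Confidence
intervals are stratified percentile bootstrap (resampling within
class, 2.5/97.5 percentiles, default 2,000 draws): assumption-light,
and validated by a coverage study — at the study geometry (30 vs 26)
with a binormal marker of true AUC Φ(δ/√2) = 0.8, the interval covers
the truth in ≈94% of 200 replicates. Reported biomarkers require AUC
strictly above 0.8.

## Synthetic cohorts

The generator is additive-normal on the Cp scale with
left-truncation-as-missing at the detection limit:

Cp(m, s) = baseline(m) + patient(s) + plate(plate(s)) + ε(m, s),

with baseline(m) ~ U(20, 34), patient ~ N(0, 0.5²), plate ~ N(0,
0.3²), ε ~ N(0, 0.8²) (all cycles), values above 35 emitted as
undetected. Disease shifts are applied on the Cp scale so a 1-cycle
shift is exactly a 2-fold abundance change; up-shifted miRNAs get
lower Cp in disease samples. Defaults mirror the study design the
pipeline targets: 742 assays, 30 disease (14 CIS + 16 OSCC) vs 26
control samples, 10 pre/post pairs sharing their patient effect, two
plates filled round-robin (so both plates contain both groups), three
calibrator assays at a fixed 22-cycle level with quarter noise. The
noise scales are a realistic reading of serum panel replication
(within-assay SD under one cycle, patient-to-patient spread around
half a cycle); no public Cp-level data were available to fit them.
All draws derive from one master seed via independent substreams, so
any stage reproduces in isolation; the paired cohort uses its own
substreams of the same master.

What the generator does *not* emulate — hence what green tests do not
show about real data: the true (unknown, likely heavy-tailed and
miRNA-dependent) dispersion of serum Cp values; correlated miRNA
co-regulation; PCR efficiency differences between assays; melt-curve
waveforms (multi-Tm is an integer flag); hemolysis chemistry (a
boolean flag); batch structure beyond additive plate offsets. Passing
acceptance tests demonstrate the *procedure* is correct and calibrated
under the stated model, not that any particular real cohort would
yield the same candidate counts.

The spiked-condition constructor places its 20 shifted miRNAs at
evenly spaced panel indices, alternating up/down, so that spikes
sample the entire baseline range — including assays near the detection
limit, where censoring attenuates or removes the signal. That is the
realistic hard case: a down-shifted miRNA whose baseline sits within
about 1.5 cycles of the limit loses most disease-sample detections and
may fail the 60% gate, which is why spike recovery is specified as an
ensemble average (≥90% over 20 seeds) rather than per-seed perfection.

## Problem sizes and determinism

Default analysis sizes: 10,000 permutations (p floor 1e-4; the BH
threshold for ~740 tests needs ~1.3e-4, so the floor resolves the
family), 2,000 bootstrap draws, 50 clustering miRNAs. Ensemble checks
(type-I calibration, FDR, spike recovery, clustering separation) use
20 seeds with 2,000 permutations per seed — permutation resolution
1/2001 is far below every threshold those checks involve. The
coverage study uses 200 replicates × 1,000 draws. The full-size
pipeline (742 × 56 plus 10 pairs at 10,000 permutations and 2,000
bootstrap draws per candidate) runs in well under a minute on one CPU.

All stochastic stages (simulation, permutation, bootstrap) take their
generators from a single master seed through `numpy` seed-sequence
spawning; identical configuration plus inputs give byte-identical
output files, which the test suite asserts.

## Known limitations

- No moderated-variance (empirical-Bayes) testing and no covariate
  adjustment (age, sex, smoking); the permutation test conditions on
  exchangeability of samples across groups.
- Undetected-cell omission, while unbiased under the gate, reduces
  power for near-LOD assays relative to censored-likelihood models.
- Single pre/post pair per patient; no longitudinal modeling.
- The ANOVA/Tukey stage assumes approximate normality of ΔCp within
  groups, which censoring violates near the LOD; it is a descriptive
  companion to the permutation test, not the selection criterion.
- ROC operating points are in-sample; no cross-validation, and no
  multi-marker panel classifiers.
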