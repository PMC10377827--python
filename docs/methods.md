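# Methods

This note records the models, conventions and design choices behind
`mirqpcr`, in the spirit of a statistical-software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## Measurement model

A qPCR array reports, per assay *m* and sample *s*, a cycle threshold
Ct(m, s) ∈ [0, 45], or "Undetermined" when fluorescence never crossed
the detection threshold. Lower Ct means higher abundance; one PCR cycle
is one factor of two in template (perfect amplification efficiency is
assumed throughout — the package deliberately does not model per-assay
efficiencies, which the underlying array chemistry does not report).

Reactions with raw Ct > 35 cycles are treated as undetected and excluded
from analysis; the boundary is inclusive (Ct = 35.0 is kept). Expression
tiers summarise a profile over target assays only: high Ct ≤ 25,
moderate 25 < Ct ≤ 30, low 30 < Ct ≤ 35, undetected otherwise. Both
tier boundaries are closed on the upper edge, and the four counts
partition the targets.

## Quality control

**Hemolysis.** Erythrocytes are rich in miR-451a, while miR-23a-3p is
comparatively stable in serum, so the index
ΔCt = Ct(miR-23a-3p) − Ct(miR-451a) rises when a serum sample is
contaminated by red-cell lysis. A sample passes iff ΔCt < 5 cycles
(strict inequality). If either pair Ct is undetermined the index is
reported missing and the sample fails — the indicator cannot vouch for
it. The index is invariant under adding a constant to both Cts.

**RNA purity.** A260/280 must lie in [1.9, 2.1] and A260/230 in
[2.0, 2.2], bounds inclusive. Missing ratios are flagged unknown, not
failed. Spectrophotometric hemolysis screening at 414 nm is accepted as
optional sample metadata only; no threshold is enforced because none is
standardised.

QC failures flag samples rather than aborting, unless strict mode is
requested; this keeps contaminated synthetic samples analysable end to
end in tests.

## Normalization

Three interchangeable reference statistics convert raw Ct to
ΔCt(m) = Ct(m) − reference, defined only for detected assays
(undetected values are never imputed):

1. **Global Ct mean** (primary): the mean Ct of *all* detected assays —
   targets, endogenous controls and spike-in included. Over the detected
   set the resulting ΔCt average is exactly zero. Requires ≥ 2 detected
   assays.
2. **Reference genes**: mean Ct of detected endogenous controls
   (SNORD61, SNORD68, SNORD72, SNORD95, SNORD96A, RNU6B); undetected
   controls are dropped with a warning, all-undetected is an error.
3. **Spike-in**: the cel-miR-39 Ct; an undetected spike-in signals
   extraction failure and is an error, not a flag.

All three cancel any constant per-profile Ct shift, so per-sample RNA
input and extraction offsets drop out of ΔΔCt — *provided the shift does
not move any assay across the detection boundary*. When it does, the
detected set changes, and with it the global mean. This boundary
coupling is a real property of mean-centric normalization, not an
implementation artifact; the shift-invariance tests therefore scope
baselines and offsets to ranges where no assay can cross Ct 35 or the
hard censor. In noisy data the same coupling makes the global-mean
reference slightly jittery whenever many assays sit near Ct 35 (each
flip of a borderline assay moves the detected-set mean by roughly
(35 − mean)/n), which is why parameter recovery under noise is measured
through the reference-gene route (whose reference assays sit far from
the boundary and carry no planted effect), while the global-mean route
is verified exactly on noiseless cohorts.

The global mean is a plain arithmetic mean — no trimming or
winsorizing — and is computed per profile over that profile's detected
assays. Whether a shared across-sample detection set should be used
instead is not standardised; per-profile detection is the default here.

## Differential expression

ΔΔCt(m) = ΔCt_test(m) − ΔCt_ref(m) for assays detected in both
profiles; assays missing on either side are labelled `not_evaluable`
and excluded from all signature sets. Fold change FC = 2^(−ΔΔCt) and the
signed fold regulation FR = FC if FC ≥ 1, else −1/FC, so |FR| ≥ 1
always, no change maps to +1, and reversing a contrast flips the sign
(FR(A vs B) = −FR(B vs A) except at FC = 1, where both are +1).

Classification applies thresholds at *printed precision* (two
decimals): up iff round(FR, 2) ≥ 2, down iff ≤ −2. This matters when
ingesting published tables, where entries printed as exactly 2.0 are
counted among the over-expressed.

Signature rules:

- **high-stringency**: |FR| ≥ 10 in at least one case-vs-control
  contrast.
- **progression**: FR(T2D vs control) > FR(IFG vs control) strictly,
  and FR(T2D vs control) ≥ 2. This is a predicate, not a curated list:
  applied to a published table it generally selects more miRNAs than a
  study's curated shortlist; the tests verify that named candidates
  satisfy it, not that they are its unique output.
- **condition-specific**: |FR| ≥ 2 in the focal contrast while the
  other contrast is below threshold (or the miRNA is absent from it —
  absence from a printed differential table is read as "unchanged"),
  with any sub-threshold trend pointing the same way.

Normalization concordance between two methods reports, over shared
evaluable miRNAs, the fraction with identical labels, the fraction with
identical FR signs, and the count where the mean-centric |FR| does not
exceed the other method's (mean-centric normalization is expected to be
the more conservative).

No per-miRNA hypothesis testing is performed: the pooled design yields
one profile per group and hence no within-group replication to test.

## Pooling

Equimolar pooling combines equal RNA masses, which averages
*concentrations*, so pooling is modelled on the linear scale:
pooled Ct(m) = −log2(mean_s 2^(−Ct(m, s))) over the samples where *m*
amplified; a miRNA undetermined in every sample stays undetermined.
Pooled Ct always lies between the per-sample min and max, and pooling
identical profiles is the identity.

## Synthetic cohorts

The generator draws Ct(m, s) = baseline(m) − effect_g(s)(m) + offset(s)
+ noise(m, s), then censors values above a hard cut-off (default 40) to
undetermined. A positive effect means higher expression, i.e. lower Ct.
Draw order is fixed (baselines → offsets → noise) from a single
seeded NumPy generator, so a seed fully determines the cohort.

Defaults emulate a three-group serum study:

| parameter | default | rationale |
|---|---|---|
| groups | 10 control / 10 IFG / 10 T2D | matched-cohort discovery design |
| panel | 372 targets, 6 controls, 1 spike-in | serum/plasma array format |
| tier design | 3 high, 35 moderate targets | serum profiles are sparse: a handful of abundant miRNAs, a moderate band, a long weak tail |
| baseline ranges | high U(22, 24.8), moderate U(25.3, 29.5), low U(30.2, 39) | places the undetected fraction near 40–45% of the panel |
| offset sd | 0.5 cycles | per-sample RNA input / extraction variation |
| noise sd | 0.25 cycles | typical qPCR technical replicate scatter |
| censoring | soft 35 / hard 40 | detection rule vs instrument limit |
| planted effects | 15 miRNAs, log2 effects ≈ −5.7 … +7.2 | realistic spread of serum fold regulations in both directions, several rising from the IFG to the T2D group |
| hemolysis pair | Ct(23a) pinned 2 cycles above Ct(451a) | clean-serum index ≈ 2, comfortably inside the < 5 pass band |

Assays carrying planted effects are assigned to the moderate tier so
that effects of several log2 units cannot push them out of detection.
Hemolysis contamination of chosen samples lowers Ct(miR-451a) by a
configurable shift (default 6 cycles), driving the index past the
threshold.

The ground-truth object exposes two expectations per contrast: the
naive closed form FR = ±2^|Δeffect| (what an effect-free reference —
spike-in or reference genes — recovers exactly), and a method-aware
expectation for the global mean that adds the shift the planted effects
impose on each pooled profile's detected-set mean, computed with plain
array arithmetic independent of the pipeline code path.

What the generator does *not* emulate: PCR efficiency differences,
melt-curve artefacts, inter-plate calibration, carrier effects of
vesicle packaging, or correlated biological variation between miRNAs.
Passing recovery tests therefore demonstrate the correctness of the
analysis chain under the stated noise model, not the field performance
of the assay.

## Clinical statistics

Eligibility screening applies strict-inequality exclusion thresholds
(CRP > 6 mg/L, ESR > 30 mm/h, BMI > 30 kg/m², HbA1c > 8%,
triglycerides > 175 mg/dL, eGFR < 60 mL/min/1.73 m²) plus boolean flags
(smoking, alcohol, drug use, microalbuminuria); missing fields are
reported unknown rather than violated. Group summaries are median and
IQR with type-7 (linear interpolation) quartiles — the convention is a
choice, so comparisons against published summaries should allow
tolerance. Kruskal–Wallis uses scipy's tie-corrected H and chi-square p;
an exact p is additionally available by exhaustive enumeration of all
distinct partitions of the pooled data into the observed group sizes
(multinomial count; practical to total n ≈ 12). The chi-square
approximation's error at n = 12 fluctuates by dataset, so the
convergence test asserts the median error over several seeded datasets
rather than a single draw. Significance is conventionally read at
p < 0.05 but only reported, never enforced.

## Fixtures and the packaged panel

The packaged fixtures transcribe the per-contrast fold-regulation
tables of a published three-group serum study at printed precision (two
decimals, Unicode minus normalised); no attempt is made to back-infer
unrounded values. A supplementary two-row fixture carries the
sub-threshold IFG values for the two T2D-specific candidates, which the
printed tables omit because they only list |FR| ≥ 2. The default
372-target panel is the union of all mature IDs appearing in those
tables plus the hemolysis indicator pair, padded with clearly marked
synthetic IDs (`syn-miR-XXXX`) to the nominal panel size — the
commercial array's full assay list is proprietary. Problem sizes used
in the tests and the acceptance script (372-assay panels, 30-sample
cohorts, exact permutation at n ≤ 12) were chosen to exercise every
code path at full panel scale while completing in seconds.

## Known limitations

- Pooled designs forfeit within-group variance; nothing in the package
  can (or tries to) assign p values to per-miRNA contrasts.
- The ±2 and ≥10 thresholds are conventions, not calibrated error
  rates.
- Mean-centric normalization couples the reference to the detected set
  (see above); with many assays near the detection boundary the
  reference-gene or spike-in routes are more stable.
- Printed-table ingestion works at two-decimal precision; counts of
  borderline entries (FR printed as exactly 2.0) depend on that
  convention.
- The instrument well layout is abstracted away; inputs are assay-level
  tables, not plate exports.
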