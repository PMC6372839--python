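# Methods

This note documents the models, numerical choices, and known limits of
the `oxshift` pipeline. Nothing here states an empirical result that the
test suite does not itself compute.

## The measurement model

The pipeline assumes LC-MS metabolomics intensities with multiplicative
error structure. For feature *i* in sample *s* (condition, time *t*,
replicate *j*):

    parent_is  = B_i · 2^{f_i(t)} · OD(t) · I_s · ε_is
    reference_is = R · I_s · ε'_is

where `B_i` is the feature's base level, `f_i(t)` the true log₂
fold-change trajectory, `I_s` a per-injection instrument factor shared
by both channels, and ε, ε′ independent unit-mean lognormal errors.
Because `I_s` multiplies both channels identically, the parent/reference
ratio removes it exactly — this is the entire point of spiking a fully
¹³C-labeled reference extract into every sample, and it is preserved as
an exact (not statistical) invariance of the generator and the
normalizer. The parent signal carries the OD factor because intracellular
pools scale with the amount of biomass extracted; dividing the ratio by
OD₆₀₀ undoes it.

### Normalization chain and its order of operations

Ratio → OD correction → division by the *same replicate's* t = 0 value →
log₂ → arithmetic mean over replicates. The order matters: averaging
per-replicate log-ratios is the geometric, not arithmetic, mean of fold
changes (two replicates at 4× and 16× average to log₂FC = 3, not
log₂(10) ≈ 3.32). A unit test freezes this order.

Missingness: a signal below `low_signal_floor` (default 10⁴ a.u., the
level below which integration is unreliable on the assumed instrument)
masks that single (replicate, time) cell, applied to **both** channels —
a too-weak reference is as unreliable as a too-weak parent. A replicate
whose baseline is masked contributes nothing for that feature; a feature
with no usable baseline in a condition is excluded with a logged reason.
Multi-batch studies may map a feature to a priority batch
(`batch_priority`), which then supplies all of that feature's data —
no cross-batch averaging — mirroring re-measurement campaigns where a
later iteration supersedes low-quality early signals.

## Repeated-measures ANOVA

One within factor (time, categorical — no linear/quadratic trend is
assumed), subjects = replicates, closed-form sums of squares, F on
(t−1, (t−1)(n−1)) degrees of freedom. Statistics run on the scale each
layer is measured on: ratio/OD-corrected intensities for metabolites,
TPM for transcripts, log₂ LFQ intensities for proteins. Fold-change
filtering, by contrast, always uses the baseline-normalized log₂ series.

- Unbalanced data: complete-case subjects (a replicate missing any time
  level is dropped for that feature). This keeps the classical
  decomposition exact; mixed models are out of scope.
- No sphericity correction is applied; the choice is recorded in the
  result table's metadata (`attrs["sphericity_correction"]`).
- Degenerate inputs: zero total variance → F = 0, p = 1; zero error with
  a nonzero time effect → p = 0 with a `degenerate` flag. The
  degeneracy threshold is relative to SS_total, so the test is invariant
  to rescaling the data.
- The anaerobic control arm is never tested: its sampling is sparser by
  design and not statistically comparable.

BH FDR is the step-up q(i) = min_{k≥i} p(k)·m/k, one family per omic
layer per call. Dual significance uses strict comparisons
(|FC| > threshold, FDR < threshold), defaults 1.5-fold for metabolites
and 2-fold for genes at FDR 0.01.

## Synthetic studies: what they emulate, what they do not

Defaults are fixed once and describe the assumed experiment: OD₀ = 0.35
with one doubling per 120 min; t = 0, 1, 5, 10, 15, 30, 45, 60, 120 min;
3 replicates (4 where a test requires the denser recovery design);
base level 10⁶ a.u., reference level 10⁶ a.u., injection CV 0.1,
per-entry feature CV 0.1, detection floor 10⁴ a.u.

**Impulse trajectories.** A product of two logistics: a rise with
midpoint t_peak/2 and a fall from h_peak toward h_final with midpoint
t_peak + 4.6/fall_rate, so the fall contributes ~1 % at the peak. The
curve is then anchored affinely so f(0) = h0 and f(t_peak) = h_peak hold
exactly. This one form covers peak-and-recover, depletion-and-recover,
and (with h_final = h_peak) monotone steps. Note that when h_final is
close to h_peak and the rise is slow, the curve keeps creeping upward
after t_peak; profiles meant to peak sharply on the grid should use a
steeper rise_rate.

**Expression kinetics.** mRNA follows an impulse on the log₂ scale;
protein solves dP/dt = k_tl·M(t) − k_deg·P with P(0) at the pre-shift
steady state k_tl·M(0)/k_deg, integrated by fixed-step RK4 at ≤ 1-min
steps (deterministic; the 120-min horizon makes adaptive stepping
unnecessary). The `degradation_down` mode multiplies k_deg by
`deg_induction_fold` (default 4) for t > 0: with flat mRNA and an
unchanged rate constant the steady state never moves, so induced
degradation is the only way a protein can fall while its transcript is
flat — which is exactly the phenotype this mode exists to emulate.
Protein noise is additive Gaussian on the log₂ scale with a standard
deviation matched to the multiplicative feature CV
(σ_log2 = √ln(1+CV²)/ln 2).

**Label switch.** Labeled fraction follows first-order incorporation
1 − e^{−k(t−t_switch)}; labeled mass is spread across isotopologue bins
m = 1..C by a binomial rule with per-carbon probability equal to the
labeled fraction, conditioned on m ≥ 1. This is a mixing convenience,
not an atom-mapping model; the analysis only consumes the ≥ 2-carbon
aggregate, which is insensitive to the within-bin split for the rate
comparison. Noise defaults to zero so pool conservation is exact.

**What a green test does not establish.** The generator has no
chromatographic drift, no retention-time misassignment, no
heteroscedastic low-signal behavior beyond the hard floor, no
correlated batch effects, no natural-abundance isotope contamination,
and replicates are exchangeable. Green pipeline tests certify the
computational chain, not robustness to those instrument realities.

## Absolute quantitation

Calibration lines are fit with a free intercept (blanks are imperfect);
R² ≥ 0.98 marks a curve usable in linear mode, below which the
isotope-ratio internal-standard route is required — this operationalizes
"nonlinear signal response". The ¹³C internal-standard formula assumes
equal instrument response of the labeled and unlabeled forms; this is
stated, not corrected for. Negative back-calculated concentrations are
floored at 0 and flagged `below_blank`; estimates outside the standards
are flagged `extrapolated`. Units are concentration-preserving: what the
standards are in, the estimate is in (mM for the NMR route).

## ¹³C incorporation rate

The rate is the OLS slope of the labeled fraction over post-switch
points within a 10-min window. A saturating process makes any linear
summary window-dependent: on 1 − e^{−kt} the 10-min slope lies between
0.63k and k. Since the scientific claim of interest is an
order-of-magnitude comparison between arms measured with the same
window, the simple estimator is preferred over exponential fitting;
point estimates only, no uncertainty model (single-replicate data).

## Carbon balance

percent_product = 100·C_product/(C_glucose·potential) with molar
potentials from pathway stoichiometry (ethanol 2, acetate 2, pyruvate 2,
lactate 2 — all via the two three-carbon units of Entner–Doudoroff
glycolysis; gluconate 1, succinate 1, shikimate 1). Biomass carbon uses
the final-minus-initial OD gain × 0.41 g CDW L⁻¹ OD⁻¹ × 0.48 g C / g
CDW over 72.06 g C per mol glucose. CO₂ is excluded by design, so the
unaccounted remainder includes respiration; a negative remainder is
flagged `overclosure` rather than clipped.

## Regulation classification

Thresholds reuse the pipeline's printed cutoffs: "changed" = 2-fold,
"flat" = 1.5-fold. Precedence is transcriptional_up →
post_transcriptional_down → transcript_down_protein_flat → none; a gene
that could satisfy two descriptions receives the first. Peak location
breaks ties toward the earlier time. Transcript log₂FC is
log₂(mean TPM(t)/mean TPM(0)) — a deliberate, fully owned replacement
for count-model (GLM) differential expression, adequate because TPM
values here are abundant and the design is a dense within-culture time
course.

## Known limitations

- Listwise deletion discards partial replicates for the ANOVA even when
  the normalizer kept their other time points.
- The impulse anchoring slightly reshapes the tail when h0 ≠ 0 or the
  rise/fall windows overlap; anchored points are exact, intermediate
  values are the documented form, not data.
- The labeled-fraction estimator ignores pool-size changes during the
  switch window.
- No uncertainty propagation from calibration fits into reported
  concentrations.
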