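# Methods

This note documents the models, rules and numerical choices behind
`omipipe`, and what the synthetic test bed does and does not establish.

## The problem being modelled

In an ED chest-pain population where prehospital STEMI cases bypass the ED,
occlusion MI (OMI: an acute MI with an occluded or near-occluded culprit
artery, TIMI flow 0–1) occurs in roughly 2% of visits and accounts for
about a third of all MI. Much of it presents with ST deviation below the
STEMI thresholds, so a rule-based ECG screen has structurally limited
sensitivity. The pipeline asks how much sensitivity a learned risk model —
an ECG encoder fused with tabular data — can recover at the *same
specificity* as the rule.

## Synthetic cohort

The generator's defaults are the study conditions; they are fixed once and
all tests and the reproduction script run under them.

**Latent classes.** Each visit draws a latent class: OMI (prevalence
0.019), non-occlusion MI (NOMI, 0.046), or no MI. Demographics, the 23
history/medication flags and the troponin log-normals are parameterized by
class from the printed counts of a 24,511-visit chest-pain cohort (467 OMI
/ 1122 NOMI); for the residual class the probabilities follow by
subtraction. Initial hs-cTnT is log-normal matched to the printed medians
and IQRs — no-MI 7 (4–15) ng/L, OMI 105 (29–441), NOMI 51 (24–120) — with
an assay floor of 3 ng/L. Mortality at 30/180/365 days uses one nested
uniform draw per patient so the cumulative indicators are monotone.

**Waveforms.** Each beat is a sum of five Gaussians (P, Q, R, S, T) with a
fixed per-lead gain table over the 8 independent channels (I, II, V1–V6);
III, aVR, aVL and aVF are derived exactly from I and II, so the lead
identities hold to machine precision on every emitted ECG. Sampling rate
defaults to 500 Hz (a common clinical rate; the duration is 10 s); the
cohort-scale runs in the tests and the reproduction script use 100 Hz to
keep memory and encoder cost proportionate — the beat template is smooth at
either rate and all measurement tolerances are met at both. The ischemic ST
shift is a smooth plateau from just after the S wave to the T-wave onset
(cosine ramps), so a median-beat measurement recovers the configured offset
without ringing. LBBB and ventricular pacing widen the QRS Gaussians
(×2.5), LVH scales the R amplitude (×1.8).

**OMI ECG phenotype.** An OMI case elevates one contiguous territory:
inferior (channel II, which propagates to III/aVF through the lead
identities), anterior (V2–V3) or lateral (I, V5, V6). With probability
`subtle_omi_fraction` = 0.6 the peak elevation lies between 0.05 mV and
95% of the applicable STEMI threshold — the rule cannot see it by
construction; a quarter of the subtle cases (`ecg_silent_given_subtle` =
0.25) carry no ST shift at all, representing ECG-occult occlusions that
only troponin and context can flag. This is what separates the ECG-only
model from the ECG+troponin model in the ablation: without an ECG-silent
stratum the encoder saturates and the troponin increment vanishes.
Non-subtle cases exceed the threshold by 0.05–0.30 mV. 2.5% of no-MI
visits receive benign (early-repolarization-like) above-threshold
elevation, which keeps the comparator's specificity near 97.5% and makes
the matched-specificity threshold meaningful; 4% of NOMI are
rule-positive, matching the printed 3.7%.

**Registry.** Each latent OMI draws one annotation branch
(R1 : R2 : R3 : R4 = 0.70 : 0.10 : 0.12 : 0.08, roughly the printed 91%
angiography share) and receives registry fields that satisfy it; NOMI cases
are guarded against satisfying any branch (troponin capped at 990 ng/L when
revascularized, no-angiography criteria suppressed); no-MI cases cannot
satisfy any branch because all branches require the discharge diagnosis. A
small fraction of angiographed NOMI receives an ungradable TIMI report and
ends in needs-review, and ~0.2% of AMI registries are wiped to model the
unclear-outcome exclusion. Labs are masked missing-at-random (hs-cTnT
0.8% … glucose 5%), independent of the latent class.

**What the generator does not emulate.** Realistic QRS/T morphology beyond
amplitude and width control, rhythm disorders, reciprocal ST depression,
noise bursts and electrode artifacts, inter-visit correlation, or
class-conditional missingness. Passing tests therefore demonstrate that
the *pipeline machinery* is correct and that the evaluation protocol
behaves as designed — not that the encoder architecture would reach any
particular performance on real ECGs.

## Annotation

Branches are evaluated in the fixed order R1 → R4 with first match wins;
since all branches yield the same status, precedence affects only the
reported `rule_fired`. "Urgent PCI" means revascularization within 7 days
of the visit (configurable). The troponin cut is strict (> 1000 ng/L).
Needs-review is a terminal machine status standing in for human
adjudication of ungradable TIMI reports; such visits are excluded from
model training and evaluation but counted in the cohort summary. A STEMI
discharge diagnosis is *not* an exclusion. Percentages are printed to one
decimal, rounding half away from zero.

## STEMI comparator

R peaks are detected on lead II (amplitude threshold at 60% of range with a
250 ms refractory distance); beats are aligned on R and the per-sample
median over at least three beats forms the median beat. The baseline is
the PR segment mean (−120…−60 ms before R). The J point is the QRS offset:
the first sample after R where the slope magnitude stays below 10% of the
peak QRS slope for 10 ms. ST deviation is read at J + 60 ms by default
(configurable 0/40/60/80 ms): measuring at J + 0 sits on the S-wave tail
of the beat template and vendor analysis programs commonly measure
40–80 ms after J, so the offset default trades guideline literalism for an
unbiased reading; the thresholds are unchanged. Thresholds: 0.1 mV in ≥ 2
contiguous leads, except V2–V3 (0.25 mV men < 40 y, 0.2 mV men ≥ 40 y,
0.15 mV women); contiguity groups are inferior {II, III, aVF}, lateral
{I, aVL, V5, V6}, anterior {V1–V4}. LBBB/LVH/ventricular pacing yield
`not_applicable`; in full-cohort analyses that verdict is counted negative,
and the reduced-cohort analysis excludes those patients. Only the index
ECG is evaluated. A failed measurement (flatline, too few beats) is
reported as a negative verdict at the cohort level rather than an error.

## Encoder

A residual 1-D convnet on the 8 independent leads (V1–V6, I, II): conv
stem (kernel 7, stride 2), one residual block per channel entry (kernel 5,
stride 2, projected shortcut when shape changes), global average pooling, a
linear 50-unit bottleneck whose activations are the embedding, ReLU, and a
1-unit logistic head. The 50-dim representation is an explicit bottleneck
rather than the penultimate classifier layer. Implementation is plain
numpy with hand-written backprop (gradient-checked against finite
differences) and Adam (lr 1e-3, global gradient-norm clip 5).

Training samples random 2.5 s crops and balances classes within each
mini-batch (batch 64, half per class with replacement) — necessary at a 2%
event rate. Extra same-visit ECGs enter training with the index label;
they are never used at feature-extraction time. After each epoch the
tuning-set AUC of crop-averaged head probabilities is computed (2 crops
during selection for speed); the best epoch's weights are kept with
patience 5. At evaluation, embeddings and probabilities are averaged over
10 evenly spaced overlapping crops; crop averaging is applied to
*embeddings* for feature extraction and to *probabilities* for
encoder-only scores. The default cohort-scale network is deliberately
small ((16, 24, 32) or (32, 32, 48, 64) channels) so a full run trains in
about a minute on one CPU; no transfer-learning initialization is used,
though checkpoints can be saved and reloaded.

## Fusion and preprocessing

Feature blocks in fixed order: history (age, sex, 23 flags), ECG embedding
(50), POC labs (3 values + 3 missingness indicators), initial troponin
(1 + 1). Missingness indicators are retained as features (their
correlation with the outcome is ~0 by construction); imputation uses
training-row means. Troponin and POC labs get a maximum-likelihood
Yeo-Johnson transform then standardization; all other scalars are
standardized; zero-variance columns pass through with a warning. Every
statistic is fitted on training rows only, and a feature vector naming any
registry field is rejected outright. The classifier is L2 logistic
regression; the penalty grid (13 points, 1e-3…1e3, expressed per 1000
training rows so the fit is invariant to row duplication) is selected on
tuning AUC.

## Evaluation protocol

Stratified 50/25/25 split by outcome with largest-remainder integer
allocation (each split within one patient of the exact fraction). The
model threshold is the smallest score whose tuning-set specificity reaches
the comparator's tuning specificity (exact matching is unattainable on
finite data, so "at least" with minimal threshold). CIs are percentile
bootstrap over patient resamples, B = 1000, 95%; resamples where a metric
is undefined are skipped and counted. Paired comparisons bootstrap the
difference on shared resamples. AUC equals the Mann–Whitney probability
with ties counted half (verified against exhaustive pair counting).
Subgroups (sex; excluding LBBB/LVH/VP) reuse the global threshold.

## Problem sizes

Unit and property tests use single ECGs at 500 Hz and cohorts of a few
hundred visits at 100 Hz. The cohort-scale comparisons (tests and
`scripts/acceptance.py`) use n = 3000 visits, 100 Hz, a (16, 24, 32)
encoder, ≤ 10 epochs and three seeds, reporting medians; one such run
takes about a minute. At this scale a validation split holds only ~11–15
OMI cases, so per-seed sensitivities are noisy — which is why the
comparisons are stated as medians over seeds and the bootstrap CIs are
wide; the qualitative conclusions (information ordering of AUCs; model
sensitivity above the rule's at matched specificity) are stable.

## Known limitations

* The generator's ECG class-separation is controlled by a handful of
  amplitude parameters; absolute AUCs on synthetic data say nothing about
  real-data performance.
* The STEMI rule engine implements one specific threshold variant and
  measurement offset; vendor programs differ, so rule sensitivities are
  comparable only within this pipeline.
* Percentile bootstrap (not BCa) can undercover slightly for extreme
  proportions at small n.
* The troponin branch guard caps NOMI max-troponin below the rule
  threshold when revascularized, a simplification that slightly distorts
  the NOMI troponin tail.
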