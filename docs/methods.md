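# Methods

## Scope and model

`phconn` implements a pattern-level analysis of drug-induced changes in
whole-brain functional connectivity. The unit of inference is the
participant: each subject is scanned under several conditions of a
repeated-measures pharmacological design, and the question is whether a
classifier can separate two conditions from the spatial pattern of each
node's overall connectedness. The analysis chain is

1. node time series (parcellated BOLD) → nuisance regression → band-pass,
2. tapered sliding windows → weighted Pearson adjacency per window,
3. signed weighted degree centrality per node, density-normalised,
4. subject-wise mean-centred feature vectors → GP classification with
   leave-one-subject-out (LOSO) cross-validation, permutation inference,
   Bonferroni correction, and linear-kernel weight maps,
5. optionally, ordinal GP regression across ≥3 rank-ordered conditions.

## Preprocessing

Nuisance regression projects each node series onto the orthogonal
complement of [intercept | regressors] by OLS; the intercept is always
included because node means carry no signal of interest. The band-pass is
an order-2 Butterworth (second-order sections) applied forward–backward,
i.e. zero-phase, with mirror ("even") padding of one settle-length; the
0.01–0.1 Hz defaults bracket the coherent low-frequency band at TR = 2 s.
Filter family, order and padding are implementation choices — only the
band itself is externally specified — and the realised frequency response
is what the tests assert against (gain ≥ 0.9 at 0.05 Hz, ≤ 0.2 at 0.2 Hz
on 150-volume series). The pipeline order is regression first, filtering
second. Parcellation of 4D images averages voxels within each integer
atlas label, unweighted; empty regions and grid mismatches are hard
errors, and node order strictly follows the supplied label list (no
silent reordering anywhere in the package — a silent reorder would corrupt
weight maps invisibly).

## Windowing and features

The taper is W(t) = exp(−t²/2s²) on integer offsets t ∈ {−T/2..T/2}, with
T = 120 volumes (240 s at TR = 2 s, long enough for stable "core"
networks) and s = T/6 = 20. Windows are placed at centers c_k = s/2 + k·s,
k = 0..⌈L/s⌉−1, and clipped at the series boundary with the taper
truncated accordingly; every clipped window retains at least T/2 samples.
For L = 150 this yields exactly eight windows. Note the step is s, not 2s:
stepping by 2s cannot produce eight windows of a 150-volume series, and
the placement here is chosen to reproduce the stated window count; s is
measured in volumes.

The taper enters as *observation weights* in a weighted Pearson
correlation (weighted means, weighted covariance, normalisation by
weighted standard deviations) rather than by multiplying the signal —
this preserves the correlation scale while down-weighting window edges.
Correlations are used raw: no Fisher z-transform, no thresholding, no
rectification; degree centrality sums signed weights with the diagonal
excluded. Density is defined as the mean absolute off-diagonal weight —
"density" has no standard definition for signed weighted graphs, and the
absolute mean is scale-matched to DC and cannot cancel to zero on
realistic data. DC/density is exactly invariant to uniform scaling of the
adjacency, which also makes it insensitive to uniform correlation
attenuation by additive measurement noise.

Feature sets take one sample per subject × condition × window. Subject-wise
centering subtracts each subject's mean over *all* of that subject's
samples in the comparison (both conditions pooled; all C conditions for
ordinal sets). Centering per condition would erase the class signal;
pooled centering removes subject-level offsets while leaving the
between-condition contrast intact. A consequence for C = 3: the three
condition means per subject sum to zero, so along any latent direction the
third condition is geometrically pulled toward the midpoint of the other
two (see "Ordinal behaviour" below).

## Gaussian-process models

Both models use the linear kernel k(x, x′) = θ·(x·x′). This is required
for weight-map extraction and is the natural choice when samples are few
and features many. With a linear kernel the GP has an exact weight-space
dual — f(x) = x·w, w ~ N(0, θI) — and all fitting happens there
(d = 116 ≪ n samples), which is algebraically identical to the kernel
formulation and much faster.

**Binary GPC.** Probit likelihood p(y|f) = Φ(yf). The posterior mode is
found by damped Newton iterations on the convex objective; the Laplace
approximation is the Gaussian at the mode with the negative-Hessian
precision A = I/θ + XᵀWX. The predictive probability integrates the
probit link exactly through the Gaussian: Φ(μ*/√(1+σ*²)). θ is optimised
by bounded scalar search on the Laplace marginal likelihood over
log θ ∈ log θ₀ ± 8, where θ₀ = 1/mean‖x‖² sets unit latent scale. At the
mode w = θXᵀα holds exactly, with α the likelihood gradient — these dual
coefficients are the per-sample weights ("class typicality" weighting)
that define the g-map.

Accuracy of the Laplace approximation: against dense quadrature over the
1-D weight posterior, predictive probabilities agree within 5·10⁻³ in the
moderate-evidence regime (overlapping classes, θ·‖x‖² ≲ 0.1·n). For
strongly separable toys the latent posterior is skewed and Laplace is
conservative (predictions pulled toward 0.5) by up to a few 10⁻²; this is
the approximation's documented behaviour, not an implementation error,
and it does not affect accuracy-based inference (thresholding at 0.5 is
invariant to monotone shrinkage).

**Ordinal GP.** Cumulative probit with ordered cut-points b₁ < … < b_{C−1}
and unit latent noise (a free noise scale is redundant with θ under a
linear kernel). Thresholds are parameterised as (b₁, log-gaps), so strict
monotonicity is structural; (log θ, b) are optimised jointly by
Nelder-Mead on the Laplace marginal likelihood (≤200 evaluations),
initialised at standard-normal quantiles of the empirical class
frequencies. Class probabilities integrate the latent Gaussian through
the interval boundaries in closed form.

## Cross-validation and inference

LOSO folds hold out whole subjects. Per fold, the held-out subject's
window probabilities are averaged within each condition and thresholded
at 0.5 (ties predict −1, deterministically), giving n_subjects × 2 test
items — 32 for the default 16-subject cohort, so accuracies are multiples
of 1/32. Two hyperparameter policies are exposed: `per_fold`
(re-optimise θ on each training fold; the default for reported
accuracies) and `shared` (optimise once on the full data, hold fixed
across folds). The permutation engine always uses `shared`, applied
*identically* to observed and permuted labels, which keeps the test
exactly exchangeable while making the 99-permutation × 50-seed
calibration runs tractable; under label exchangeability the choice of
statistic cannot bias the p-value, only its power.

Permutations swap the two condition labels within subject (independent
fair coin per subject), respecting the repeated-measures exchangeability
unit; global shuffles would break subject pairing. The p estimator is the
add-one rule (1 + #{perm ≥ observed})/(n_perm + 1), which cannot return
zero and matches a reporting floor of 10⁻³ at n_perm = 1000. Bonferroni
correction multiplies by the configured family size (default: the number
of contrasts in the run).

Univariate follow-up: per-node one-sample t-tests on per-subject mean DC
deltas (equivalent to paired t-tests), two-sided, uncorrected at
p < 0.05 — supplementary description, not the primary inference.
Zero-variance nonzero deltas are flagged degenerate (t = ±∞, p = 0)
rather than silently dropped. A helper correlates per-subject posterior
probabilities with an external covariate (e.g. plasma drug
concentration) by Pearson correlation.

## Synthetic cohort

The generator emulates the study design the analysis is meant for:
16 subjects × 150 volumes per condition at TR = 2 s on 116 AAL nodes
(labels from the bundled fixture; the fixture's MNI centroids are
approximate synthetic stand-ins used only for map export). Defaults, with
rationale:

| parameter | default | meaning |
|---|---|---|
| `effect_size` δ | 1.0 | scale of the planted covariance shift; δ=1 yields LOSO accuracies ≈ 0.85–0.9, the magnitude real pharmacological contrasts report; δ=2 is an overwhelming effect (accuracy ≈ 1) |
| `subject_sd` | 0.1 | scale of each subject's random SPD congruence perturbation A = I + (σ/√N)G; creates the between-subject variance that subject-wise centering exists to remove |
| `ar_coeff` | 0.4 | AR(1) coefficient of the temporal colouring; modest BOLD-like autocorrelation at TR = 2 s without confounding the band-pass test |
| `noise_sd` | 1.0 | white measurement noise; attenuates correlations roughly uniformly, which density normalisation cancels |
| `nuisance_amp` | 1.0 | amplitude of eight smooth nuisance signals (six motion-like, CSF, WM) mixed into all nodes; the same signals are provided as the regression table |
| `drift_amp` | 0.5 | linear + half-cosine drift per node, removed by the band-pass |

The baseline covariance is a one-global-factor plus per-role-factor model
with unit variances (all couplings positive, as dominant BOLD
correlations are). An "active" condition multiplies inter-cortical
couplings by 1 − 0.25δ and couplings among subcortical/cerebellar nodes
by 1 + 0.25δ (variances and mixed pairs untouched), then repairs to the
SPD cone by eigenvalue flooring at 10⁻⁶ of the largest eigenvalue. This
plants the cortical-to-subcortical centrality shift the analysis should
recover; `planted_dc_delta` computes the implied per-node change of
density-normalised DC from the generating correlations with exactly the
analysis' own centrality rules, giving ground truth for weight-map
validation. Per-condition effect multipliers default to 1.0 for the
ketamine-like conditions, 0.4 for the risperidone-pre-treated condition
(strong modulation) and 1.0 for the lamotrigine-pre-treated condition (no
modulation), mirroring the qualitative pharmacology the design targets.
Besides the canonical shift, conditions can be configured as `distinct`
(the same shift on a permuted role assignment — a recoverable pattern off
the main axis), `opposing` (attenuation/amplification blocks swapped) or
`mixture` (each subject's run drawn from baseline or the shifted
covariance at random — a class with no location of its own).

What the generator does *not* emulate: hemodynamic response convolution,
cardiac/respiratory physiological noise, head motion and scrubbing,
scanner artefacts, spatial structure within regions, and real-data
heterogeneity of drug response. Passing tests therefore demonstrate that
the pipeline recovers planted covariance-level effects under realistic
sampling noise and subject variability — not that it would attain any
particular accuracy on real data.

## Validation scenarios and problem sizes

The full-size checks (`phconn.benchmarks`, exercised by the acceptance
test suite and `scripts/acceptance.py`) use the study geometry throughout:
null calibration runs 50 seeds × (1 observed + 99 permuted) LOSO analyses
with δ = 0 and asserts mean accuracy in [0.45, 0.55] and a ≤0.05
p-value rate in [0.01, 0.10]; effect recovery sweeps δ ∈ {0, 0.5, 1, 2}
(20 seeds each, shared-θ policy) and asserts monotone mean accuracy with
δ = 2 at or above the 87.5 % headline magnitude; weight-map fidelity is
assessed at δ = 2 — the regime in which the classifier the map derives
from is itself reliable — where sign agreement on the 20 strongest
ground-truth nodes is ≥ 90 % (at δ = 1, with accuracy ≈ 0.9, mid-rank
node signs are materially noisier: mean agreement ≈ 0.78). Two-condition
cohorts are generated for two-condition analyses; this is a size choice
only and does not alter any statistic.

## Ordinal behaviour and a known negative result

With a graded planted effect (0, δ, 2δ at δ = 1) the LOSO ordinal
confusion matrix is strongly diagonal-dominant. A middle class with *no*
intermediate structure — drawn from the same distribution as the upper
extreme — is **not** driven below chance in the central diagonal cell by
this generator: the sum-to-zero subject centering places any third
condition near the midpoint of the latent axis, and the threshold
equilibrium of the cumulative probit splits the merged middle/extreme
cluster roughly evenly, so the central cell sits near 0.4–0.6 rather than
below 1/3. Alternative non-intermediate constructions (patterns off the
ordinal axis, opposing shifts, per-subject mixtures) land at ≈ 0.3–0.8.
Below-chance central identification of a non-intermediate class appears
to require the kind of heterogeneous, weakly discriminable response
structure found in real pharmacological data, which this generator
deliberately does not fabricate. The corresponding validation check
states the below-chance expectation and is allowed to fail; the behaviour
is documented here rather than engineered around.

## Numerical choices and degenerate inputs

- Newton iterations stop at gradient ∞-norm < 10⁻¹⁰ (binary) / 10⁻⁹
  (ordinal) with step-halving line search; the objectives are convex so
  warm starts change runtime, never results. All fits are deterministic.
- Correlations are clipped to [−1, 1] and symmetrised against rounding;
  diagonals are set exactly to 1 (adjacency) or excluded (centrality).
- Zero-variance nodes inside a window, zero network density,
  rank-deficient nuisance designs, empty atlas regions, missing
  subject × condition cells, non-finite features, single-class training
  folds and constant covariates are all hard, named errors.
- Probability ties at exactly 0.5 predict the −1 class, deterministically.
- Eigenvalue flooring (SPD repair) uses 10⁻⁶ of the largest eigenvalue —
  deterministic and order-independent.
- All stochastic steps take explicit seeds; the pipeline derives
  per-contrast permutation seeds from the study seed.

## Limitations

Degree centrality cannot localise which specific couplings change, only
each node's aggregate connectedness; correlation is blind to phase-lagged
or nonlinear coupling; a single window scale is used; only Bonferroni
correction is provided; EP or MCMC inference and nonlinear kernels are
out of scope (the weight map requires the linear kernel). The bundled
centroids are approximate and for visualisation only. Real-data claims
require real data: the synthetic validation bounds implementation
correctness, not scientific effect sizes.
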