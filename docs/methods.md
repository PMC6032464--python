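# Methods

## The model

Tissue is described as a single well-mixed compartment exchanging
tracer with arterial plasma:

    dCt/dt = Ktrans' Cp(t) − kep Ct(t),   kep = Ktrans'/v,

so Ct(t) = Ktrans' ∫₀ᵗ Cp(τ) exp(−kep (t − τ)) dτ. Externally Ktrans is
reported in ml/100 ml/min and the distribution volume DV in ml/100 ml;
internally both are converted to per-second rate and fractional volume
(divide by 6000 and 100 respectively). No separate plasma-volume term
is included: with a hepatocyte-specific agent (Gd-EOB-DTPA) the
distribution volume already aggregates plasma, interstitium and
intracellular space, and a pure one-compartment description is the
appropriate granularity. Consequences worth keeping in mind:

- **Concentration proxy.** Relative enhancement S(t)/S₀ − 1 stands in
  for concentration with no relaxivity calibration; the analysis
  therefore assumes signal linearity in concentration over the working
  range. Both tissue and blood curves use the same proxy, so the
  proportionality constant cancels from Ktrans and DV up to
  water-exchange and T2* effects, which are ignored.
- **S₀ estimator.** Arithmetic mean of all pre-contrast frames (five
  under the default schedule). Averaging reduces the ~1/SNR
  multiplicative bias that a single noisy baseline frame would inject
  into every concentration value.
- **AIF.** Candidate aortic curves (five slices by default) are merged
  by excluding candidates whose peak is below half the best peak —
  a stated convention standing in for operator judgement in the
  semi-automatic procedure — then averaging, followed by hematocrit
  correction Cp = Cb/(1 − Hct) with Hct fixed at 0.45 (configurable).

## Forward evaluation and fitting

Cp is treated as piecewise linear between samples; the convolution is
integrated in closed form on each inter-knot interval and accumulated
by the one-step recursion y(t₊) = y(t)·e^(−kep·h) + q, which is exact
for piecewise-linear inputs and costs O(n). For kep·h < 10⁻⁶ the
interval kernel switches to its series expansion to avoid cancellation.
Times before injection map to zero concentration; the integration
starts at t = 0.

Fitting is bounded nonlinear least squares (trust-region reflective,
tolerances 10⁻⁸) over Ktrans ∈ [0, 1000] ml/100 ml/min and DV ∈
(0, 100] ml/100 ml, on all frames jointly (an optional helper averages
the five frames of each burst phase instead). Initialization comes
from the linearized integral form of the ODE — Ct = Ktrans'·∫Cp −
kep·∫Ct is linear in (Ktrans', kep) and solved by least squares on
cumulative trapezoidal integrals — plus two additional starts at
0.3× and 3× the initial Ktrans to guard against local minima under
sparse burst sampling. An identically-zero tissue curve returns
Ktrans = 0, converged, with DV reported as the mid-range placeholder 50
(DV is structurally unidentifiable when no tracer arrives).

The model-free plasma-flow estimate discretizes Ct = f·(Cp ⊛ R) on a
uniform grid (default step: the median post-injection frame spacing),
inverts the lower-triangular convolution matrix by truncated SVD
(singular values below `reg` × the largest are dropped; default
reg = 0.15, and 0.01 suffices on dense noiseless grids), and reports
the peak of the recovered impulse response f·R(t) as plasma flow
(R(0) = 1 for a causal residue function). This map is for ROI guidance
only and is not part of the reported kinetic parameters.

## Acquisition schedule

Burst sampling: phases of five frames over 30 s. The packaged schedule
places the pre-contrast phase at −30 s (time zero = injection), the
arterial-dominant phase at 20 s (frame midpoints 23–47 s, bracketing a
bolus arriving at 20 s and peaking near 30 s), and late phases starting
at 60, 120, 180, 240, 330, 420, 510 and 600 s — 50 frames. The absolute
timing of the arterial-dominant phase is set per patient by a
monitoring scan in practice; 20 s is this package's fixed choice for
simulation and fitting.

## Synthetic cohorts

The generator's defaults are the study conditions: 11 patients,
21 lesions (at most two per patient), responder fraction 8/21, fixed
Hct 0.45, baseline SNR 20, and per-group per-visit (mean, SD) for DV
and Ktrans equal to the published group statistics. Design choices:

- **Marginals.** Draws are moment-matched so the sampled mean/SD equal
  the configured values exactly: a truncated normal (solved for
  location/scale on the type bounds) for cells with CV < 0.8 — all DV
  cells — and a moment-matched lognormal for high-variability cells —
  all Ktrans cells, several of which have SD > mean, which no normal
  truncated to positive values can attain (truncated-normal CV < 1).
- **Within-patient correlation.** A patient's lesions share a latent
  Gaussian factor (correlation 0.3 by default) per visit and
  parameter, imposed through a Gaussian copula so the marginals stay
  matched. Visits are otherwise independent.
- **Covariates.** Ang2 couples to the patient-mean DV latent with a
  latent correlation chosen to target a lesion-level Spearman
  correlation of 0.6; VEGF (rising across visits) and c-KIT are drawn
  independently of the kinetics.
- **Signals.** Tissue curves are synthesized through the forward model
  driven by a deterministic population AIF (gamma-variate first pass,
  peak relative enhancement 3, slow bi-exponential washout), mapped to
  signal as S = S₀(1 + C) and degraded with additive Gaussian noise of
  SD S₀/SNR. Aortic candidates get the same treatment per slice.
- **Outcomes.** Final mRECIST categories are drawn within each group at
  the observed mix (CR:PR = 5:3 among responders, SD:PD = 11:2 among
  non-responders), so grouping by outcome reproduces the group labels.

What the generator does **not** emulate: spatial structure and
partial-volume effects (a block phantom exists only to test ROI
extraction), motion, scanner drift, arterial-phase mistiming,
non-Gaussian or spatially correlated noise, signal saturation at high
gadolinium concentration, and any real coupling between lesion size and
kinetics. Passing end-to-end tests therefore demonstrates correctness
of the computational chain under the stated statistical model, not
robustness to those real-world effects.

## Response prediction

mRECIST is implemented exactly as the four category definitions
(CR: no arterial enhancement; PR: ≥ 30% diameter-sum decrease vs
baseline; PD: ≥ 20% increase vs nadir; SD: otherwise), without the
consensus guideline's additional minimum-absolute-increase clause, and
with a 10⁻⁹ relative tolerance so boundary cases are classified
consistently under rescaling. The prediction rule is
"responder if DV ≤ cutoff", boundary inclusive.

The packaged per-visit cutoffs are 40, 30 and 17 ml/100 ml. The
mean + 2 SD construction applied to the responder day-10 statistics
(8.6 ± 4.7) gives 18.0, not 17; the package keeps the operating values
as defaults and exposes `cutoff_mean_plus_2sd` separately rather than
forcing the two to agree. Diagnostic metrics with empty denominators
(e.g. PPV with no positive predictions) are reported as explicitly
undefined (`None`), never NaN. Reported percentages use round-half-up;
clinical utility indexes are computed from exact fractions and rounded
to three decimals.

## Statistics

- **Friedman** (three visits, within lesions): tie-corrected statistic
  on within-row mid-ranks; for n ≤ 8 rows the p-value is exact, from
  the full (k!)ⁿ permutation distribution computed by dynamic
  programming over column rank sums; otherwise the χ²(k−1)
  approximation.
- **Mann–Whitney U** (responders vs non-responders): exact enumeration
  for tie-free pooled samples up to 25, else tie-corrected normal
  approximation with continuity correction.
- **Spearman** (kinetics vs angiogenesis markers): mid-ranks for ties;
  exact permutation p for n ≤ 9, else the t approximation. Per-patient
  marker values are duplicated across that patient's lesions before
  correlating — this matches the study's stated procedure and is
  pseudo-replication; treat those p-values accordingly.
- **Mixed repeated-measures ANOVA** (marker changes across time):
  hand-computed sums of squares for the between-group / within-time
  design (cross-checked against pingouin in the tests); zero error
  mean square with a non-zero effect is reported as F = ∞, p = 0.
- No multiple-testing correction by default (α = 0.05 throughout);
  Holm adjustment is available but off.
- Descriptive SDs use the population (divide-by-n) convention by
  default — the convention under which the packaged cohort's interval
  statistic reproduces as 2.7 ± 2.0 days — configurable to sample SD.

## Validation problem sizes

The test suite exercises: forward-model equivalence with 0.1-s-grid
quadrature over 100 random parameter draws; noiseless recovery to 1% on
a 5×5 (Ktrans, DV) grid over Ktrans 2–40 ml/100 ml/min and DV 10–60
ml/100 ml; median bias < 10% at SNR 20 over 50 replicates; and an
end-to-end synthetic study of 500 lesions (250 patients) in which
fitted DV group means agree with the configured means within two
standard errors in all six group × visit cells and the responder
Friedman test rejects at α = 0.05. The end-to-end acceptance check is
keyed on DV, the study's primary biomarker: DV is estimated nearly
unbiasedly from burst sampling, whereas Ktrans at the extreme published
values (means above ~100 ml/100 ml/min with SDs approaching 200) is
bias-limited — at kep of several per minute the tissue curve
equilibrates between bursts and Ktrans is only weakly identified, the
same limitation the study itself reports for its high Ktrans values.
Exact-test p-values are verified against full brute-force enumeration
for all rank tests at n ≤ 6, and the Mann–Whitney type-I error is
calibrated over 2000 null simulations at the study's group sizes
(8 vs 13).

## Known limitations

- Relative enhancement saturates at high gadolinium concentration in
  real acquisitions; the linear proxy overestimates nothing in
  simulation but will bias real AIF peaks low, inflating fitted
  parameters.
- The deconvolution uses plain truncated SVD without a causality or
  smoothness prior; oscillatory impulse responses at high noise are
  possible and only the peak is consumed downstream.
- The exact Friedman enumeration grows as (k!)ⁿ states; it is intended
  for k = 3 and the small n of this design.
- Per-lesion kinetic draws are independent across visits given the
  group; real lesions have serially correlated physiology, so
  within-lesion trajectories are noisier in simulation than in
  clinical data.
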