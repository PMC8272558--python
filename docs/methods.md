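# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments can show. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Blood relaxometry (3 T)

Longitudinal relaxation of arterial blood follows a two-site
(erythrocyte/plasma) fast-exchange form,

    R1(Hct, sO2) = a·Hct + b + c·Hct·(1 − sO2)    [s⁻¹],

with a = 0.4055, b = 0.3955, c = 1.1. The (a, b) pair is the least-squares
line through the arterial calibration points this package targets
(T1 = 1.85/1.75/1.64 s at Hct = 0.36/0.43/0.53 and arterial saturation);
widely used bovine-blood calibrations (e.g. 1/T1 = 0.52·Hct + 0.38) sit
≈ 0.1 s lower across this range, so the calibration choice matters at the
0.05 s level and the coefficients are exposed as overridable arguments and
mirrored in the run config. The deoxyhemoglobin term c is a literature
order of magnitude; at arterial saturations (sO2 ≥ 0.98) it moves T1 by
< 0.03 s. Transverse relaxation uses a Luz–Meiboom-style exchange
relation, R2 = r0 + r1·Hct + k·Hct(1−Hct)(1−sO2)², with r0 = 4.0,
r1 = 10.0, k = 165 s⁻¹, giving T2 ≈ 0.12 s at Hct 0.43 — T2 decreasing in
hematocrit is the channel through which hematocrit lowers labeling
efficiency. Only 3 T arterial blood is modelled; venous blood and other
field strengths are out of scope.

## PCASL labeling-efficiency simulation

One pulse period of the unbalanced train is discretized at 10 µs (sampled
at interval midpoints so each sample-and-hold segment integrates exactly):
a Hanning RF envelope of 0.5 ms within a 1.22 ms period, peak scaled so the
period-average |B1| equals the protocol "mean B1" (a Hanning window
averages to half its peak, so e.g. 1.4 µT mean → 6.83 µT peak); gradient at
the protocol maximum during the pulse and a constant negative rephasing
lobe in the gap solving the period-average constraint
(Gmax·tp + g·(T−tp))/T = Gmean, i.e. g = −3.675 mT/m for the 0.7/7 mT/m
train and −1.939 mT/m for the 0.7/4.5 mT/m train. A geometry whose
rephasing lobe would have to be positive or exceed the hardware maximum is
rejected.

A spin moving at constant velocity along the gradient axis is propagated by
exact rotation operators about the instantaneous effective field
(off-resonance γ·G(t)·z(t); a homogeneous field is assumed at the labeling
plane) with interleaved T1/T2 relaxation, from 5 cm upstream to 2 cm
downstream of the plane. Efficiency is read out at the exit plane as
α = (Mz_control − Mz_label)/(2·M0), with a stabilization check comparing
the exit readout against the 1.5 cm checkpoint after T1 decay over the
intervening transit; velocities failing it by > 0.02 are flagged.
Halving the time step moves α by < 0.005 at every tested velocity
(convergence test), and the simulator agrees with an independent
continuous-wave (average-field) flow-driven adiabatic inversion oracle.

**Control condition.** By default the control is taken as ideal
(Mz_control = M0), i.e. the classic label-only inversion-efficiency
readout. The literal π-alternating control of an unbalanced train has
aliased resonance planes at odd multiples of 1/(2·γ̄·Gmean·Δt) ≈ 1.375 cm
from the labeling plane; for the multi-PLD train (max gradient 4.5 mT/m)
these fall inside the 0.5 ms Hanning pulse's excitation band, and a spin
crossing them acquires a strong velocity-dependent perturbation that
published smooth efficiency curves for these trains do not carry. The full
two-condition simulation remains available (`control="simulated"`); for
the single-PLD train (max gradient 7 mT/m, aliases near the pulse's
spectral null) both readouts agree closely.

**Laminar and vessel averaging.** For fully developed laminar flow the
flux-weighted velocity density is p(v) ∝ v on [0, 2·v̄]; α is linearly
interpolated on the simulated 3–100 cm/s grid with α(v<3) held at α(3), and
the average is taken by fine-grid quadrature. Per-subject effective
efficiency is the flow-volume-weighted mean over the four inflow arteries
(two internal carotids, two vertebrals). Pulsatility is ignored — the
vessel table already carries cardiac-cycle-averaged velocities.

**Velocity response.** With these conventions at Hct 0.43, the
laminar-averaged efficiency change for a 27 → 38 cm/s rise in mean velocity
is −3.4% (single-PLD train) and +1.2% (multi-PLD train). The single-PLD
train's response is negative because its adiabatic margin
ω1²/(γ·Gmean·v) reaches ≈ 1 near 76 cm/s — the top of the laminar span at
v̄ = 38 — so α(v) declines over the upper half of the averaged range; the
stronger-B1 multi-PLD train keeps its margin and gains efficiency. The
pointwise (non-averaged) responses are +0.1% and +3.3%. Group-level
reference values for this quantity in the source literature are larger
(≈ 4–5%) and internally inconsistent with the same study's per-subject
numbers (0.7 ± 1.2% and 2.4 ± 2.0% for a 25% velocity rise); this package
reports what the stated train parameters and averaging convention produce.

## ASL quantification

All kinetic models take protocol-card times in ms and convert once; CBF is
mL/100 g/min externally and f = CBF/6000 s⁻¹ internally.

- **General kinetic model (continuous labeling).** Piecewise form with
  amplitude 2·M0b·α·f·T1app·e^(−ATT/T1b); T1app is fixed at the tissue T1
  (1.3 s) — flow-independent, since f/λ ≪ 1/T1 at physiological perfusion —
  which keeps ΔM exactly linear in CBF.
- **Single-PLD inversion** is the consensus closed form; it equals the
  kinetic model with T1app = T1b and a fully delivered bolus, under which
  ATT cancels. Its CVR bias on the phantom arises from the decay-rate
  mismatch (label decays at T1,tissue after arrival, not T1b): shortening
  ATT post-vasodilator lengthens tissue residence, depressing post CBF and
  hence CVR.
- **Multi-PLD MAP fit.** At fixed ATT the model is linear in CBF, so the
  fit profiles a closed-form non-negative amplitude over a 10 ms ATT grid
  (0–3 s) with parabolic sub-grid refinement; deterministic and fully
  vectorized. Priors: Gaussian on ATT (mean 1.3 s, sd 1.0 s) plus an
  optional ridge on CBF; sd ≤ 0 gives the exact flat-prior/least-squares
  limit (cross-checked against `scipy.optimize.least_squares`). A
  fixed-mean prior tighter than ≈ 1 s visibly biases the pre/post ATT
  ratio toward 1 and inflates CVR, so the pipeline default adds one
  spatial pass that re-centres the prior on the 3³-neighbourhood mean of
  the previous estimate (the light analogue of spatially regularized
  Bayesian fitting), which removes the bias (fitted ATT ratio 0.902 for
  truth 0.90 at the default noise).
- **VSASL** is inverted exactly; its α is a protocol constant (0.9) for
  the eddy-current-compensated implementation, and any global T1b error
  cancels out of CVR (tested).
- **M0 calibration.** Blood M0 = PD / ((1 − e^(−TR/T1,tissue))·λ) with
  TR = 2000 ms, T1,tissue = 1.3 s, λ = 0.9 mL/g (divisor ≈ 0.785). Edge
  partial-volume voxels: the mask is eroded by one voxel and the rim
  refilled by iterative nearest-interior local-mean extrapolation;
  interior voxels are bitwise untouched.

## Dynamic PET

The one-compartment solution is computed by an exact exponential
integrator with trapezoidal input on a 50 ms grid and averaged over each
frame of the 30×1/10×3/12×5/12×10/12×30 s schedule (frame-integrated
evaluation; midpoint evaluation moves the fitted flow by < 2%, tested).
The fit profiles a closed-form K1 = f over a 240-point log-spaced
k2 = f/λp grid with parabolic refinement, weights ∝ frame duration
(post-reconstruction count statistics), and recovers λp = K1/k2 with
bounds [0.3, 1.2] enforced by a constrained scalar refit at the violated
bound. The AIF is the frame-wise mean over the carotid mask — no spill-in/
spill-out correction and no delay/dispersion correction (limitations; the
synthetic carotid voxels carry the true input). A 5×5 in-slice median
filter with within-mask truncation suppresses impulse noise in the CBF
map.

## CVR and statistics

CVR is computed voxelwise in native phantom space; voxels with
non-positive baseline CBF are excluded, then values outside the
within-mask 1st–99th percentile band (linear interpolation between order
statistics, strict inequality) are excluded from summaries — per subject.
ROI summaries average non-excluded voxels. Group comparisons: two-tailed
paired t tests with a Kolmogorov–Smirnov check of the differences against
a fitted normal, Pearson r with a Fisher-z interval, and a max-statistic
sign-flip permutation test for voxelwise family-wise error control
(Gaussian 3 mm FWHM mask-renormalized smoothing before testing;
corrected p = rank of observed |t| in the null max-|t| distribution
including the identity; exact FWE under sign exchangeability). The
max-statistic approach replaces threshold-free cluster enhancement by
design — far less machinery, exact control, at some sensitivity cost for
spatially extended effects.

## Synthetic cohort

A layered ellipsoid phantom (GM shell, WM core, CSF ventricles, carotid
cylinders outside the brain) carries per-class truth: GM CBF 60, WM 22
mL/100 g/min; GM CVR 42%, WM 38%; ATT 1.2/1.45 s with a posterior
(+25% max) gradient so regional ATT reaches ≈ 1.5 s and beyond in WM;
vasodilation multiplies CBF by (1 + CVR/100) and ATT by 0.90; vessel mean
velocity rises 27 → 38 cm/s and total flow by 51%; hematocrit ~
N(0.43, 0.05²), saturation ~ N(0.999, 0.004²); n = 19 by default. The
quantification mask is perfused tissue (GM+WM) — CVR is undefined at zero
perfusion, so the CSF ventricles stay in the anatomy but outside the
statistics. Smooth within-class variability (5% sd, shared pre/post so
truth CVR is exact) and subject-level multipliers (10%/10%/5% sd on
CBF/CVR/ATT) provide realistic heterogeneity. All draws come from
`default_rng([seed, subject_index])`, so every artifact is reproducible
bitwise from the recorded seed.

Acquisitions are generated by the same forward models the estimators fit —
no model mismatch by default — so noiseless runs are exact roundtrips and
noisy runs isolate estimator behaviour. ASL noise is additive Gaussian at
temporal SNR 20 (GM mean |ΔM| over noise sd), chosen so the voxelwise
full-brain CVR map spreads (≈ 11–17 points across techniques) match the
spreads reported for these sequences in vivo (12–19%); PET frame noise is
Gaussian with variance ∝ (brain-mean activity)/(frame duration), scale 1.0,
giving ≈ 1.5% GM CBF error, consistent with PET's reference role. The AIF
is a gamma-variate bolus (onset 10 s, peak 35 s) with a slow recirculation
tail. What passing tests do **not** show about real data: no partial
volume, motion, dispersion, arterial-signal contamination, off-resonance,
or reconstruction effects are modelled, and the in-vivo single-PLD CVR
deficit (−15% relative to PET) is larger than the pure
tissue-decay-mismatch mechanism reproduced here (≈ 3 CVR points).

## Experiments

`experiment1` quantifies every subject with the consensus constants
(α = 0.85, T1b = 1.65 s); `experiment2` with per-subject estimates
(Bloch-simulated flow-weighted α; T1b from hematocrit). The acquisition
data are identical, so the two modes differ exactly through the (α, T1b)
substitution: closed-form CBF maps rescale globally, VSASL CVR is
unchanged, PET is untouched. Runs record software version, mode, seed, and
config in the report.

## Problem sizes

Unit and property tests run on 20–24³ phantoms with 2–4 subjects and a
20 µs Bloch step; the acceptance computations use the full 3–100 cm/s
velocity grid at 10 µs steps, and the permutation-level check uses 200
null datasets × 500 sign-flips on a 6×6×2 grid of 8 subjects — desk-scale
versions of the full-size analyses, chosen so the whole suite completes in
a few minutes.
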