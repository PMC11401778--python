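# Methods

## Scope and model structure

The package simulates pulsatile, whole-cycle coronary flow and pressure for
one epicardial vessel with downstream microcirculation, to estimate FFR from
an OCT lumen-area profile. The model is zero-dimensional (lumped): no wave
propagation, no inertance in the epicardial segment, one transmural layer.
Its state is deliberately small — two pressure states (distal epicardial
node, shared venous node) plus the algebraic epicardial chain — so a
simulation converges in a few cardiac cycles and milliseconds of CPU.

### Epicardial chain

The resampled lumen profile (uniform 0.2 mm grid, linear interpolation)
becomes one resistive element per frame with Poiseuille coefficient
k_i = 8πμ·Δx·(A_i⁻² + A_{i+1}⁻²)/2 (trapezoidal in 1/A²), μ = 3.5 mPa·s.
A single quadratic element ½ρ(1/A_MLA − 1/A_rec)², ρ = 1060 kg/m³, acts at
the exit of the MLA; the recovery area A_rec is the taper-interpolated
reference area 5 mm distal to the MLA (bounded by the ROI end). The drop is
written K_conv·Q·|Q| so it stays dissipative under transient flow reversal.
All three constants (μ, ρ, recovery distance) are config-exposed; the loss
decomposition follows the classical viscous-plus-separation framework, and
the resulting coefficient magnitudes for cohort-mean geometry (K_visc of a
few mmHg·s/mL, K_conv of a few mmHg·s²/mL²) fall in the expected range.

### Side branches and microcirculation

Healthy vessel caliber is assumed to taper linearly between the
operator-entered proximal and distal reference areas (an automatic
suggestion from the 90th-percentile areas of the proximal/distal 10 mm is
offered but always overridable, mirroring manual entry in practice).
Downstream conductance scales allometrically with reference area,
g(A) = g_ref,10 (A/10)^{7/6}; side-branch flow is the continuous leak given
by the decrement of g along the taper, attached at each segment boundary.
This conserves conductance exactly: distal bed + Σ leaks = g(A_prox).
Every path (leaks and distal bed) splits its resistance 75/25
proximal/distal around one shared venous node, matching the observed
R_micro,prox/R_micro ≈ 34.7/46.2. Compliances sit at the distal epicardial
node (C_dist) and the venous node (C_micro); their defaults are the
cohort-mean values 1.1 and 4.5 µL/mmHg scaled linearly with the bed's
conductance relative to the cohort-mean bed (1/46.2 mmHg per mL/s) — the
scaling law is not derivable from first principles here and is
config-exposed.

### Myocardial–vascular interaction

Interstitial pressure is assumed to fall linearly from LV cavity pressure at
the endocardium to zero at the epicardium; a one-layer bed therefore feels
0.5·P_LV. Two mechanisms act on the venous node:

1. capacitive coupling — C_micro is referenced to 0.5·P_LV, so rising LV
   pressure pumps volume out of the intramyocardial compartment;
2. a collapsible outlet (vascular waterfall) — venous outflow is
   g_out·max(P_v − max(P_RA, 0.5·P_LV), 0).

The second mechanism is this package's own design choice. With the
cohort-scale compliances above, the venous time constant is only ~20–50 ms,
so capacitive coupling alone produces a mostly transient impediment and
systolic inflow would exceed diastolic inflow — the opposite of measured
coronary physiology. The waterfall supplies the sustained systolic back
pressure that capacitance at this scale cannot, and with it the simulated
inflow is diastolic-dominant (diastolic/systolic mean-flow ratio ≈ 1.5 for
cohort-mean geometry). It can be disabled (`venous_waterfall: false`) to
recover the purely capacitive variant.

### Cardiac driver

Paired aortic/LV pressures come from a minimal open-loop driver: a
double-Hill time-varying-elastance LV (activation fractions 0.269/0.452 of
the cycle, exponents 1.9/21.9, normalized to peak 1) filling from a constant
venous pressure, an aortic valve with characteristic impedance and blood
inertance, a proximal aortic root compliance-plus-inertance element whose
ringing at valve closure produces the dicrotic notch, and a two-element
Windkessel. A closed-loop full-circulation model is intentionally not
reproduced: the coronary network consumes only Pa(t) and P_LV(t), and the
only patient-matched quantities are heart rate and mean aortic pressure
(peripheral resistance is adjusted by secant iteration to 0.1 mmHg, well
inside the 0.5 mmHg contract; ≤ 50 iterations; 10 warm-up cycles; internal
Euler substep 0.1 ms, output grid ~1 kHz chosen to divide the cycle
exactly). The default parameter set was tuned once to give a physiologic
trace at HR 75 / mean 90 mmHg (systolic ≈ 116, diastolic ≈ 65 mmHg,
diastolic LV pressure ≈ 4–8 mmHg, notch present) and is versioned as
`DEFAULT_DRIVER_PARAMS`. Measured aortic traces are ingested from 2-column
CSV, resampled to the solver grid; the LV trace is then synthesized from the
driver and phase-locked by circular cross-correlation.

## Numerics

The interior epicardial chain is quasi-steady and linear except for the one
quadratic element, so it is reduced exactly — one tridiagonal solve with
four right-hand sides per network — to affine maps of every needed flow in
(Pa, Pd, Pv, d), where d is the expansion drop. Per time step the quadratic
closure is a scalar root (solved in closed form) and the two compliance
states advance by implicit Euler (dt = 1 ms default) with a fixed-point
iteration on d to 1e-12 mmHg; the waterfall makes the 2×2 step matrix
piecewise constant (outlet open/collapsed), both inverses precomputed.
Chain flow balance at the solution holds to solver precision (~1e-10 mL/s,
checked every step). Cycles repeat until the cycle-mean Pd changes by less
than 1e-4 relative (max 50); all node pressures start at mean Pa, and the
periodicity requirement makes results independent of initialization.
Halving dt changes simFFR by < 1e-4. The per-instant chain solver
(`solve_epicardial`) exposes the same algebra for a single boundary state
and verifies per-node conservation against `newton_tol`; the time loops are
numba-compiled with an equivalent pure-Python fallback.

Degenerate inputs are guarded explicitly: non-positive lumen areas, a
correction driving the effective radius below zero (error names the
offending position), reversed reference ordering, landmark misalignment in
pullback merging, out-of-range heart rate or target pressure, and simFFR
outside (0, 1.05]. An MLA below ~1 mm² (the OCT catheter scale) logs a
warning that severity will tend to be underestimated, as do profiles far
above (ectasia) or uniformly below (diffuse disease) the reference taper —
these are known failure modes of reference-based assessment, flagged rather
than corrected.

## Calibration

`calibrate_conductance` root-solves g_ref,10 per territory (Brent, bracket
0.005–0.5 mL/s/mmHg) so the territory-mean simulated inflow equals the
territory-mean observed flow — "align overall average flow" is read as
matching means, the simplest single-scalar reading. `calibrate_lumen_
correction` evaluates a candidate grid (default 0, −0.05, −0.075, −0.1 mm),
regresses observed on simulated distal pressure (OLS with intercept; a
through-origin flag exists) and picks the slope closest to 1, ties toward
the smaller |k|; a grid rather than continuous optimization matches how such
an empirical constant is actually chosen and keeps the procedure exactly
reproducible. Driver waveforms are cached per (HR, mean Pa) across repeated
simulations of the same vessel.

## Synthetic data: what it does and does not emulate

`synth_lumen_profile` builds a linearly tapering vessel with a Gaussian-bump
focal stenosis (depth = fraction of local reference area removed; width =
Gaussian σ), optional second lesion and ectatic variants, and additive
frame-level area noise, deterministic per seed. `synth_cohort` draws
geometry and hemodynamics from distributions centred on the study cohort
(ROI 50 ± 13 mm clipped to 30–75, a_prox 10.57 ± 2.68 mm², distal/proximal
ratio 0.54 ± 0.08, HR 75 ± 8 bpm, mean Pa 83 ± 14 mmHg, LAD share 28/48)
with stenosis depth uniform on [0.25, 0.95] so observed FFR spans roughly
0.4–0.97; observations (Pd, Q, FFR) are produced by running the simulator at
the ground-truth parameters (g_ref,10 = 0.064/0.043, k_lumencorr = −0.075)
and adding 5% multiplicative flow noise and 1.5 mmHg additive Pd noise.
Hyperemic heart rate is not reported for the study cohort; 75 ± 8 bpm is a
plausible adenosine-hyperemia range.

Because observations come from the same model family, passing calibration
recovery shows identifiability of (g_ref,10, k_lumencorr) under measurement
noise — not accuracy against real vessels. The generator does not emulate
OCT segmentation error structure, catheter-crossing artifacts in tight
lesions, eccentric or non-Gaussian lesion shapes, or inter-patient
microvascular variability beyond the conductance law; agreement statistics
on synthetic cohorts therefore say nothing about clinical accuracy. The
parameter-recovery check follows its stated condition (flow noise only):
with the additional 1.5 mmHg Pd noise the 0.025 mm k-grid becomes
statistically unidentifiable at n = 20, which is the expected behaviour of a
slope criterion near its noise floor, not a defect of the procedure.

Note also a scale difference visible in examples: a focal Gaussian lesion
with cohort-mean MLA (2.62 mm²) yields simFFR ≈ 0.92, higher than the
cohort-mean simFFR of 0.80, because real lesions are longer and more diffuse
than a 3 mm σ bump; severity in the synthetic world is controlled by depth
and width together.

## Statistics module

Exact binomial (Clopper–Pearson) intervals from beta quantiles; diagnostic
metrics with undefined denominators reported as undefined rather than zero;
the FFR threshold 0.80 is closed (0.80 is positive). Bland–Altman uses
simulated − measured differences and mean ± 1.96·SD with the n−1 SD.
Pearson confidence intervals use the Fisher z transform. ROC AUC uses the
Mann–Whitney identity with ties at 0.5 (midranks); DeLong's paired test uses
placement values with the unbiased covariance, reporting the comparison as
undefined when the paired variance degenerates. For FFR-like markers the
score direction '<' (smaller predicts positive) is explicit rather than
implied by sign flips.

## Problem sizes used in the shipped checks

Verification runs use 20 randomized networks for the steady-flow oracle,
5-point severity ladders, a 5×5 HR×pressure driver grid, and 20 cohorts of
20 vessels for calibration recovery — sizes at which every check completes
in seconds while exercising both territories, the full severity range and
both outlet regimes.

## Known limitations

No bifurcation-resolved side branches (flow just proximal to a large branch
is underestimated, just distal overestimated); one transmural layer; no
wave-propagation effects (early-diastolic flow oscillations absent); no
shortening-induced intramyocardial pressure; reference-taper entry is
subjective in diffusely diseased or ectatic vessels; tight-lesion lumens are
taken at face value even though a crossed imaging catheter may hold them
open. Cohort-level clinical agreement cannot be reproduced without the
undeposited patient data; the package ships the published calibration
constants as defaults instead.
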