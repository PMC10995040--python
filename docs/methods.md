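# Methods

This note describes the models implemented in `coroperf`, the choices made
where the design was genuinely open, and what the synthetic test conditions
do and do not demonstrate about real clinical data.

## 1. Aortic pressure waveform (4-phase parametrization)

The aortic-root pressure over one heartbeat is a continuous, piecewise
polynomial of time built from routine clinical measures only (age, sex,
height, weight, HR, brachial P_sys/P_dia, LV mass). The cycle is split at
the systolic shoulder (T_sh), the incisura (T_i), the dicrotic notch
(T_notch) and the cycle end (T):

| Phase | Interval | Polynomial | Conditions |
|---|---|---|---|
| I upstroke | [0, T_sh] | cubic | P(0)=P_min, P'(0)=0, P(T_sh)=P_sh, P'(T_sh)=k |
| II augmentation | [T_sh, T_i] | parabola | vertex (T_peak, P_peak), through (T_sh, P_sh) |
| III notch | [T_i, T_notch] | parabola | vertex (T_notch, P_notch), matches phase II at T_i |
| IV diastole | [T_notch, T] | line | (T_notch, P_notch) → (T, P_min) |

Key parameters and their provenance:

- `T = 60/HR`; `T_notch = T / (1 + R_ds)` with the diastolic/systolic
  ratio `R_ds = 2.537e-4 HR² − 0.057 HR + 4.3`. The ratio regression
  determines both durations given the period; the split formula
  `T/(1+R_ds)` is the only reading consistent with
  T_systole + T_diastole = T.
- `T_sh = T_notch/3`, `T_peak = T_notch/2` (reflected-wave arrival),
  `T_i = T_notch − IVRT`, `IVCT = 0.05 s`.
- `IVRT [ms] = 0.267·LVIM + 51.45 + 0.412·(age − 54)` — a double
  regression: IVRT vs indexed LV mass at mean age 54, age-corrected with
  the slope of the healthy-population IVRT-vs-age line. LVIM uses the
  Du Bois body-surface area `0.007184·h^0.725·w^0.425` (h in cm, w in kg);
  the Du Bois constants are the standard ones.
- `P_min = P_dia`; `P_peak = P_sys − 10 mmHg` (men) or `− 8 mmHg` (women),
  the brachial-to-aortic systolic drop.
- Augmentation pressure `ΔP`: the sex-specific polynomial in age, HR and
  height is interpreted as an augmentation **index in percent of pulse
  pressure** (typical adult values 20–30), so
  `ΔP = AIx/100 · (P_peak − P_min)`. Reading the regression output as a raw
  ratio would give ΔP far exceeding the pulse pressure, which is
  impossible. Negative AIx (young, tall subjects outside the regression
  population) is clamped to 0 with a warning.
- `P_notch = 1.1667·P_mean − 12.629` with the simplified mean
  `P_mean = 0.5 (P_peak + P_min)`.
- `k = 75 mmHg/s` smooths the phase I→II transition; configurable,
  defaulted exactly at that value.

**Closure of phase I.** The three stated conditions underdetermine a
four-coefficient cubic. We close the system with `dP/dt(0) = 0`, which
makes P_min a genuine minimum and the curve slope-free at the periodic
seam. This is a modelling choice of this package; any other fourth
condition would produce a slightly different upstroke. With this closure
the cubic is monotone on [0, T_sh] whenever
`0 ≤ k ≤ 3 (P_sh − P_min)/T_sh` (the Hermite monotonicity condition),
which holds for all defaults; the test suite asserts it.

Derivative continuity is deliberately **not** enforced at the other
joints: sharp transitions (e.g. the incisura) are physiological.
Value-continuity holds to 1e-9 mmHg by construction (closed-form
coefficients), as does periodicity.

## 2. Effective pressure for non-contracting models

Models without cardiac contraction would wrongly produce systolic-dominant
coronary flow under a prescribed pressure inlet. The effective pressure
subtracts a surrogate of ventricular chamber pressure:

- ejection `[0, T_i]`: `P_eff = 0.3·P_ar` (the surrogate takes 0.7·P_ar,
  a single global factor; no transmural variation is modelled),
- mid-diastole `[T_notch, T − IVCT]`: `P_eff = P_ar` exactly,
- isovolumic relaxation `[T_i, T_notch]`: parabola with vertex
  `(T_notch, P_notch)` through `(T_i, 0.3·P_ar(T_i))`,
- isovolumic contraction `[T − IVCT, T]`: parabola with vertex
  `(T − IVCT, P_ar(T − IVCT))` ending at `0.3·P_ar(T)`.

The construction is continuous and periodic (`P_eff(T) = 0.3·P_min =
P_eff(0)`). One consequence worth stating: because the IC parabola has
zero slope at its vertex while diastole falls linearly, `P_eff` exceeds
`P_ar` by at most `a_IV²·IVCT²/(4·ΔP_IC)` (≈0.01 mmHg for typical inputs)
over the first ~1 ms after T − IVCT. "P_eff ≤ P_ar pointwise" therefore
holds only up to this quantified, analytically bounded excess; the tests
assert exactly that bound.

## 3. Rest → hyperemia mapping

Adenosine hyperemia is represented by per-quantity linear maps
`X_stress = α X_rest + β` with frozen defaults from a 100-patient paired
database: HR (0.92, 26.00, R=0.89), P_sys (0.73, 31.10, R=0.78),
P_dia (0.73, 21.25, R=0.70). Heart rate rises for any valid resting HR;
systolic pressure falls for resting values above ~115 mmHg — both matching
the drug's known effects. The defaults cannot be re-derived here (the
source data are not public); what the package provides is the full
re-fitting *procedure* for any paired dataset:

1. per-record differences `ΔX = X_rest − X_stress`;
2. IQR cleaning: a record is kept iff
   `Q1 − f·IQR < ΔX < Q3 + f·IQR` with **f = 0.5** — deliberately stricter
   than the conventional 1.5 — and strict inequalities, so a record
   exactly on a fence is removed. The factor is exposed as a knob.
   Quartiles use linear interpolation between order statistics (the
   common median-unbiased variant); the estimator only affects borderline
   records. Degenerate case IQR = 0: the open interval would discard
   every record including the bulk the rule is meant to keep, so records
   with ΔX equal to the collapsed quartile are kept (in particular all
   records when every ΔX is identical).
3. ordinary least squares of X_stress on X_rest; R is Pearson's r.

Cleaning is idempotent only in the weak sense that re-cleaning the kept
set removes a (possibly empty) further subset; this is documented
behaviour, not assumed away.

## 4. Synthetic cohort

The generator emulates the *structure* of the paired clinical database:
rest values uniform within bounded physiological ranges (HR 55–90 bpm,
P_sys 100–160, P_dia 60–100 mmHg), stress values from the true linear maps
plus Gaussian measurement noise (defaults 8 bpm, 10 and 7 mmHg — scatter
comparable to the reported correlation strengths), and a Bernoulli
fraction (default 10%) of gross outliers shifted by ±20 noise SDs.
Patient records sample age 40–80 y, height 150–190 cm, weight 50–110 kg,
LV mass 100–250 g; systolic pressure is sampled jointly with diastolic so
the pulse pressure is at least 20 mmHg (narrower is not physiological and
could not survive the brachial-to-aortic correction). All randomness
derives from a single seed via per-quantity/per-index substreams.

What this does *not* emulate: the real joint distribution of covariates,
heteroscedastic measurement error, or autoregulation-induced nonlinearity.
Passing tests demonstrate correctness of the algorithms under the stated
generative model, not clinical accuracy.

## 5. Three-compartment Darcy perfusion

The microcirculation of the LV free wall is homogenized into three
compartments (small arteries ~300 µm, arterioles ~75 µm, capillaries
~5 µm) with pressures p_1..p_3 governed by

    −∇·(K_i ∇p_i) = (inter-compartment exchange) + source/drain terms,

with exchange `β_12 (p_1 − p_2)`, `β_23 (p_2 − p_3)`, venous drain
`γ (p_3 − p_veins)` and arterial source g [1/s] into compartment 1.
Parameters (constant in space and time): K_i = 2e-9 m² Pa⁻¹ s⁻¹,
β_12 = 2.5e-5, β_23 = 1.25e-5, γ = 3e-5 Pa⁻¹ s⁻¹, p_veins = 5 mmHg.
Since K_i is stated in conductivity units, the diffusion operator is
`∇·(K∇p)`; an inverse there would invert the units.

Numerics: cell-centered finite volumes on a structured voxel grid
(second-order for homogeneous coefficients), zero-flux conditions on all
external faces (no perfusion crosses epicardial/endocardial surfaces in
the homogenized picture — boundary data are otherwise unspecified),
pressures in Pa internally and mmHg at every interface
(133.322 Pa/mmHg). The coupled sparse system is solved by LU
factorization with iterative refinement; accuracy is certified by the
normwise backward error `‖Ax−b‖/(‖A‖‖x‖+‖b‖) ≤ 1e-10` (the naive
`‖Ax−b‖/‖b‖` is meaningless when conductance scaling pushes ‖b‖ far
below ‖A‖·‖x‖). Verified invariants: exact global mass balance
(∫g dV = ∫γ(p_3 − p_veins) dV to 1e-8 relative), the maximum principle
p_1 ≥ p_2 ≥ p_3 ≥ p_veins for g ≥ 0, the uniform-source closed form
p_3 = p_veins + g/γ (chain upward), and agreement with an independent
dense brute-force assembly to 1e-10.

**MBF.** Myocardial blood flow is defined from the venous drain:
`MBF = γ (p_3 − p_veins) · 6000/ρ` in mL/min per 100 g, with tissue
density ρ = 1.05 g/mL. This is one consistent reading (drainage equals
supply at steady state); it is stated openly as this package's definition.

**Blinded calibration.** A single multiplicative factor λ on
(β_12, β_23, γ) is bisected (geometrically, on λ ∈ [1e-4, 1e4]) until the
coupled resting inflow per gram matches the population target
1 mL min⁻¹ g⁻¹ for angiographically normal arteries, to 0.5% relative.
Inflow is monotone in λ, so bisection is robust; the iteration log is
returned. Hyperemia multiplies all three conductances by 4 — by
homogeneity of the series combination
`C_tot = (1/β_12 + 1/β_23 + 1/γ)⁻¹`, the total conductance is exactly
4× its resting value. The further literature target of a microvascular
pressure *distribution* is not numerically published; the per-compartment
pressure-drop shares are exposed as a diagnostic
(`DarcyState.pressure_drop_fractions`) but not calibrated against.

## 6. Coronary tree surrogate and FFR

The 3D Navier–Stokes arterial model is **replaced** by a quasi-static
Poiseuille resistive tree — declared loudly: every segment contributes
`R = 8µL/(πr⁴)` (blood viscosity 3.5e-3 Pa s), a stenosis is the series
resistance of its narrowed and nominal portions (no expansion/turbulence
losses, so computed FFR drops are conservative), and the forest (left and
right inlets; right-ventricular branches omitted) is solved exactly by
two-pass Thévenin elimination. Kirchhoff balance is checked at every
junction to 1e-10 relative with an absolute floor of `100·ε·|p|/R_min`
(the irreducible flow noise from ε-level pressure roundoff — relevant
only near zero net flow).

The default healthy tree has 11 segments (LM → LAD prox/mid/dist +
diagonal; LCX → OM + distal; RCA prox/mid/dist) with typical epicardial
dimensions (lengths 1–4 cm, radii 1.2–2.25 mm).

**Coupling.** Leaves discharge into their perfusion territory (LAD 40%,
LCX 30%, RCA 30% of the slab, split along x) at the territory-mean
compartment-1 pressure; the territory outflow returns to the slab as a
uniform source over the territory's voxels. Both subproblems are linear,
so the per-instant fixed point in the three terminal pressures is affine.
A plain Picard iteration between the subproblems **diverges** whenever
the territory microvascular resistance exceeds the tree resistance (here
by ~two orders of magnitude), so the fixed point is solved exactly: three
unit-source Darcy responses are precomputed per parameter set (then reused
for every instant of a beat via one LU factorization), the network's
affine response is probed, and a 3×3 system yields the terminal
pressures. The solution is verified against its defining equation in the
pressure domain to 0.1% of the microvascular head (in practice ~1e-10);
instantaneous mass conservation between tree outflow and Darcy source is
exact by construction.

Because each territory's leaves share one Darcy sink, parallel branches
within a territory partially bypass a stenosed branch; landmark FFR at
leaf-distal nodes is therefore less sensitive to isolated distal stenoses
than a per-outlet microvascular model would be. This is a consequence of
the declared territory-level coupling; FFR values are method-consistent
for this surrogate, not reproductions of patient-specific 3D results.

**One beat** is simulated quasi-statically at dt ≤ 1 ms with
`P_eff(t)` at both inlets. The per-beat left-inlet flow is predominantly
diastolic (fraction ≈ 0.73 under default stress conditions), as expected
once the ventricular surrogate suppresses systolic driving pressure.
`FFR(x) = P(x)/P_inlet` is evaluated at the peak-diastolic instant — for
the constructed waveforms that is exactly T_notch, since pressure decays
monotonically after the notch. Landmarks per major artery are the distal
nodes of the deepest leaf of each territory (distal LAD at the apex, end
of the LCX mainline, distal RCA before its terminal bifurcation).

## 7. Pipeline order and problem sizes

The end-to-end pipeline runs: derive rest parameters → build rest
waveforms → map to stress → **calibrate at rest** (undilated tree,
time-averaged resting P_eff) → dilate radii ×1.225 and quadruple
conductances → simulate one hyperemic beat → report landmark FFR, mean
MBF, inflow and the calibration factor. Calibration deliberately uses the
resting configuration; dilation and conductance scaling apply only to the
hyperemic beat.

Default problem sizes: a 20×20×10 slab of 2 mm voxels (32 mL, 33.6 g —
a left-ventricular free-wall scale) for calibration and the acceptance
run; the test suite uses smaller slabs (6×6×4 to 10×10×6) where the
asserted properties are grid-independent. One beat at dt = 1 ms costs a
few seconds thanks to the precomputed linear responses.

## 8. Known limitations

- No patient geometry: voxel slab and synthetic tree stand in for
  segmented anatomy; per-patient clinical endpoints are out of scope.
- One-way quasi-static coupling; no inertial/advective hemodynamics, no
  poroelastic contraction, no autoregulation.
- Stenosis model lacks expansion losses → conservative FFR drops.
- Territory-level sinks blunt landmark-FFR sensitivity to stenoses with
  intra-territory parallel bypasses (see §6).
- The rest→stress maps are population lines with substantial dispersion
  (R 0.70–0.89); no covariate adjustment.
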