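# Methods

`fieldcycle` re-implements, against a synthetic instrument backend, the
computational chain of a magnetic-field-cycling (MFC) NMR workflow: mapping
and setting the sample field, shimming a mu-metal shield to nanotesla
residuals, extracting the relaxation dispersion (NMRD) of
[1-13C]pyruvate, budgeting hyperpolarization losses during sample
transfer, and quantifying SABRE-SHEATH chemical exchange. This note
records the models, the parameters that matter, and the choices made where
the design was open.

## Field mapping and shuttle kinematics (`fieldmap`)

Positions along the shuttle axis are stored in stepper microsteps
(0 = outside/homing position, 33 000 = B0 isocenter); the conversion to
millimetres is the exact rational 1747.2/48000 = 0.0364 mm/ustep fixed by
the drive's velocity specification, so full travel is 120.12 cm.

Calibration tables are piecewise-linear inverses restricted to the largest
strictly monotone sub-range of the measured profile (the stray-field rise);
the plateau near the isocenter and any wiggles are excluded, and queries
outside the calibrated range raise instead of extrapolating — a stray field
extrapolated beyond its measurement is meaningless and unsafe as a set
point. Within the grid, field profiles are interpolated with cubic splines
(component-wise, recombined to a magnitude) because the stray field is
smooth.

Setting a target field uses three regimes with exactly one active actuator
each:

| regime   | range                | actuator                              |
|----------|----------------------|---------------------------------------|
| zshim    | <= 3.16 uT           | Z-shim coil offset (108 nT/mA line)   |
| solenoid | 3.16 uT – 12 mT      | solenoid current at the 3.34% position|
| stray    | > 12 mT              | shuttle position in the B0 stray field|

Targets below the ~6.2 nT shim floor are treated as "shimmed zero"
(offset 0). The 12 mT boundary is taken on the field axis; at the measured
~7.1 mT/A it corresponds to ~1.69 A of solenoid current.

Shuttle moves follow the closed-form trapezoidal velocity profile
(acceleration 6552 mm/s², v_max 1747.2 mm/s by default), triangular when
the distance is below v_max²/a. This is the idealized kinematic lower
bound; measured shuttle times additionally contain drive overhead and
friction that the module deliberately does not model. Composing position(t)
with the interpolated field profile yields the field-vs-time trace used by
the transfer-loss integral.

## Shimming (`shimming`)

Each of the nine shim coils (X, Y, Z offsets; dY/dx, dZ/dx, dZ/dy, dY/dy,
dZ/dz gradients; one d²Z/dz² term) is calibrated from a symmetric ±I scan
pair, mu(z) = (B₊ − B₋)/(2|I|), which cancels the background and any
response term odd in I. Simulative tuning minimizes

    L = Σ_sample ‖B_b(z) + Σ_i I_i mu_i(z)‖² + α Σ_i I_i²

with the analytic gradient dL/dI_i = 2 Σ B·mu_i + 2 α I_i, using scipy's
trust-constr followed by one exact Newton step (the loss is quadratic in
the currents, so the step lands on the stationary point and removes
trust-region truncation). At α = 0 the solution equals the
normal-equations least squares of the stacked 3m×9 linear system; that
closed form is kept as an independent oracle in the tests, never as the
implementation path.

The regularization weight α (nT²/mA²) is not dictated by the physics;
the default 1e-2 keeps the penalty far below the unshimmed loss
(~10⁵ nT² per sample point) while suppressing degenerate large-current
solutions. 95% confidence intervals come from the inverse Hessian,
cov = σ̂²(MᵀM + αI)⁻¹ with σ̂² the residual variance on 3m−9 degrees of
freedom, scaled by a Student-t quantile (t rather than normal, with
dof = 3m−9; the distinction is negligible at m ≳ 10 samples). A Hessian
with condition number above 1e12 triggers a logged ridge fallback and
flags the CIs unreliable. All-zero coil responses are dropped from the
design with a warning.

Iterative tuning is coordinate descent on the X, Y, Z offset currents only
(their fields are nearly constant over the sample range, so they shift the
offset without degrading homogeneity), in the fixed order X → Y → Z per
sweep, with steps shrinking geometrically from 0.1 mA to 0.01 mA; moves
are accepted only if they reduce the probed ‖B‖, and the loop stops below
2 nT (default) or at the evaluation budget. On linear probes the result is
order-independent; the order is fixed only for reproducibility.

The Z-shim field schedule is an ordinary least-squares line through a
current sweep (nominally 108 nT/mA); target fields convert to currents by
inverting that line.

## Relaxation dispersion (`relaxometry`)

Per-field decays are fitted globally with

    s(t) = A1 exp(−t/τ1) + A2 exp(−t/τ2) + y0,

one (A1, τ1, y0) triple per field, a single shared amplitude fraction
A2/A1 and shared slow constant τ2. T1 at each field is τ1. To keep the
slow component identifiable it is initialized at 5% amplitude and τ2 is
bounded below by twice the largest initial τ1 estimate; within the sampled
delay window the slow term is nearly flat, so τ2 itself is only loosely
pinned while the per-field τ1 is robust (the order-invariance test
tolerances reflect this). Weighting is inverse-variance when signal errors
are supplied, unit otherwise.

The dispersion model is the three-term sum

    R1(B) = Δω₁²τ_C1/(1+(ω_C τ_C1)²) + Δω₂²τ_C2/(1+(ω_C τ_C2)²)
          + (1/5)(ω_C δ_CSA)² τ_CSA/(1+(ω_C τ_CSA)²),   ω_C = γ(¹³C)·B,

implemented exactly in this form with no spin-number or dipolar
prefactors. γ(¹³C) = 2π × 10.7084 MHz/T is a fixed constant (¹H and ¹⁵N
provided for reuse). Two consequences of this literal form are accepted
rather than patched: the fitted Δω values are phenomenological coupling
constants (too large for literal scalar couplings), and the model's
absolute T1 at high field does not reproduce measured pyruvate values —
the model is therefore validated against its own term-by-term arithmetic
and against parameter recovery, not against absolute T1.

Fitting notes: τ_C2 is parameterized as a ratio of τ_C1 in (0, 1), which
removes the label-swap degeneracy between the two inner-sphere terms;
nearly equal correlation times raise an identifiability warning.
Throughout the accessible field range ω_C τ_CSA ≪ 1 (extreme narrowing),
so the data constrain only the product δ_CSA²·τ_CSA; τ_CSA is therefore
held fixed at its prior value (default 3.5 ps) and only δ_CSA is fitted.
Freeing it is possible via the `fix` argument but leaves the pair on an
unresolvable ridge.

T1(B) lookups use a shape-preserving PCHIP interpolation of log R1 vs
log B, clamped to the endpoint values outside the measured range — no
overshoot between points and no extrapolation. The INEPT bookkeeping is
the elementary identity: averaging time to fixed SNR scales as 1/SNR² and
repetition time as the T1 of the polarization source, giving a
g²·(T1_slow/T1_fast) measurement-time reduction (≈59.4, "about 60-fold",
for g = 2.53, 45.5 s vs 4.9 s).

## Transfer losses (`transfer`)

Neglecting thermal repolarization, the retained polarization over a
field-vs-time profile is P(T)/P(0) = exp(−∫₀ᵀ dt/T1(B(t))). The integrand
is integrated by the composite trapezoid rule on the profile grid with the
field linear in time between samples, with per-segment subdivision doubling
until the result changes by < 1e-6 relative (up to 14 refinement levels);
profile fields are clamped at a 1 nT floor before the T1 lookup so the
integrand never queries below the shimmed-zero regime. External interfaces
speak percent, internal math fractions; back-calculation of the
polarization at dissolution is observed/(1 − loss).

Scenario comparison reports retained percent per profile and pairwise
differences in percentage points. The synthetic transfer profiles are
stylized stand-ins (polarizer stray decay → ambient segment → NMR stray
ramp over 19.5 s, with magnets raising the floor of designated segments to
10 mT); their contract is the pointwise-dominance ordering of scenarios,
not reproduction of any measured retention figure, which depends on
unpublished measured profiles.

## Exchange kinetics (`exchange`)

All selective-inversion series are fitted jointly with
A1 exp(−k τ) + A2 exp(−R τ) sharing one fast rate k (exchange) and one
slow rate R (relaxation); amplitudes are free and may be negative. The fast
rate is initialized from the half-decay time of the widest-range series.
Identifiability guards: rates closer than 3× warn; a fitted k faster than
the delay-grid resolution warns (the fit has effectively collapsed to a
single exponential); vanishing slow amplitudes flag R as unconstrained.

With two equivalent equatorial ligand sites,

    k_d = k/(0.5 + [Ir]/[Py]_free),   k_a′ = ([Ir]/[Py]_free)·k_d,
    [Py]_free = [Py]_total − n_bound·[Ir]  (n_bound = 3),

generalizing 0.5 → 1/n_exchangeable for other complex geometries.
Uncertainty on k propagates first-order (the concentration ratio is taken
as exact). At the reference conditions (k = 5.77 s⁻¹, 4 mM Ir, 50 mM
pyridine) this gives 38 mM free pyridine, k_d = 9.53 s⁻¹ and
k_a′ = 1.00 s⁻¹.

The PTF-sweep readout fits a local quadratic around the discrete maximum
(±2 points) and reports its clamped vertex plus the half-width of the 5%
near-flat region; zero crossings come from sign changes with linear
interpolation. The mechanistic two-compartment simulator (uniform
relaxation R, forward rate k_a′, backward rate k_d) exists to exercise the
fitting chain: its non-trivial kinetic eigenvalue is k_a′ + k_d (+R), and
since k_d + k_a′ = k·(1+x)/(0.5+x) with x = [Ir]/[Py]_free, a fitted fast
rate λ converts back to the effective rate as (λ−R)(0.5+x)/(1+x). A pure
±1 inversion populates only the difference eigenmode; partial-inversion
patterns are used when both rates must be visible to the fit.

## Synthetic instrument (`synthetic_data`)

One root seed feeds fixed per-generator substreams
(`numpy.random.SeedSequence` spawn keys), so the draw count of one
generator never perturbs another and every output is a pure function of
(config, seed).

* **Shield background** — smooth low-spatial-frequency components over
  10 000 usteps (36.4 cm, 200 points), normalized so the mean magnitude
  equals 551.4 nT exactly; the perturbation amplitude is calibrated by
  bisection so the magnitude's relative SD matches the configured 8%; the
  z component is kept small (XY-dominated field); 1 nT magnetometer noise.
* **Coils** — three near-uniform offset coils (Z at 108 nT/mA), five
  gradient coils linear in z on their named component with coil-specific
  cubic/quadratic flavor, one zero-mean quadratic Z coil; each carries a
  1% coil-specific ripple so no two responses are collinear and the 9-column
  design is full rank. A nonlinearity knob scales the response by
  (1 + εI) — odd in I, hence cancelled exactly by the symmetric ±I
  calibration — and a drift knob adds a linear field drift across a scan.
* **NMRD** — per-field T1 from the three-term model; decay traces with
  configurable shared-τ2 fraction (default 5%), thermal baseline
  proportional to B, and 2% multiplicative noise; the shared τ2 defaults
  to 3× the largest T1 in the field set so it is genuinely the slow
  component. A direct dispersion-curve generator (R1 with 2% multiplicative
  noise at 30 log-spaced fields, 7.8 uT – 9.4 T) feeds the model-fit
  recovery studies.
* **Transfer** — the three scenario profiles described above.
* **Exchange** — four series from the shared biexponential with
  inversion-pattern amplitudes (inverted site −1, spectator +1 at τ = 0),
  16 delays over 0–50 s placed geometrically so the early points resolve
  the ~5.8 s⁻¹ fast component, 2% additive noise.
* **Solenoid** — layered finite-solenoid on-axis field (6 × 273 turns over
  300 mm); the infinite-solenoid limit of the default geometry is
  ~6.9 mT/A, consistent with the ~7.1 mT/A calibration.

What the generators do *not* emulate: mu-metal hysteresis and degaussing,
instrument spikes, temperature-dependent shifts, the measured transfer
profiles, or the friction that slows the real shuttle. Passing tests
therefore demonstrate correctness of the analysis chain under the stated
statistical structure, not agreement with any particular instrument.

## Problem sizes used in the checks

The recovery studies run at the sizes the analysis was designed around:
50 seeded repeats of the 30-field dispersion round trip, 100 repeats of
the 16-delay exchange round trip, 200 random shim instances for the
normal-equations oracle, and 1000 linear-Gaussian replicates for CI
coverage. At the stated 2% noise and 16-delay design the seed-to-seed
spread of the recovered exchange rate is ≈0.26 s⁻¹, matching the fit's own
reported standard error; medians over repeats recover k well inside
±0.19 s⁻¹.

## Known limitations

* The dispersion model, used as printed, does not reproduce measured
  absolute T1 at high field; retention percentages computed from it are
  internally consistent but not instrument-accurate.
* The shared slow decay constant τ2 is only weakly identified when the
  sampled delays are short compared to it; per-field T1 is unaffected.
* Shim CIs assume a linear coil response; the nonlinearity/drift knobs
  exist in the generator but no fitted values are shipped.
* The iterative tuner's coordinate descent assumes a probe whose magnitude
  has no spurious local minima in single-coil directions — true for linear
  responses, unverified beyond them.
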