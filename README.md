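# fieldcycle

Analysis toolkit for magnetic-field-cycling (MFC) NMR experiments with
hyperpolarized tracers. An MFC system shuttles a sample between the high
field of an NMR magnet and a variable low field (a shimmed mu-metal shield
with an internal solenoid, or the magnet's stray field), which makes the
field dependence of relaxation and of polarization transfer directly
measurable. `fieldcycle` implements the computational side of that
workflow for people running such systems:

* **Field mapping** — field-profile containers, invertible
  field-to-position and field-to-current calibration tables, sample-range
  homogeneity statistics, and the trapezoidal shuttle kinematics that turn
  a move into a field-vs-time trace.
* **Shimming** — regularized least-squares optimization of nine shim-coil
  currents, `L = Σ‖B_b + Σ I_i μ_i‖² + αΣI_i²`, with analytic gradients,
  Hessian-based 95% confidence intervals, and an iterative X/Y/Z
  fine-tuner that drives the residual field below 2 nT.
* **Relaxometry (NMRD)** — global biexponential decay fitting with a
  shared slow component to extract per-field T1, and the three-term
  dispersion model

      R1(B) = Δω₁²τ_C1/(1+(ω_C τ_C1)²) + Δω₂²τ_C2/(1+(ω_C τ_C2)²)
            + (1/5)(ω_C δ_CSA)² τ_CSA/(1+(ω_C τ_CSA)²)

  with ω_C = γ(¹³C)·B, fitted to R1(B) curves such as that of
  [1-13C]pyruvate.
* **Transfer losses** — the retained-polarization path integral
  P(T)/P(0) = exp(−∫dt/T1(B(t))) over a transfer profile, scenario
  comparison (with/without transfer magnets), and back-calculation of the
  polarization at dissolution.
* **Exchange kinetics** — global shared-rate biexponential fitting of
  SABRE selective-inversion kinetics, conversion of the effective exchange
  rate k into the dissociation and association rate constants
  (k_d = k/(0.5 + [Ir]/[Py]_free), k_a′ = ([Ir]/[Py]_free)·k_d), and
  polarization-transfer-field sweep readout.
* **Synthetic instrument** — seeded generators for every input kind
  (shield background maps, coil responses, dispersion data, transfer
  profiles, exchange traces), so the full pipeline runs and is tested
  without hardware.

See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

```python
import numpy as np
from fieldcycle import (GeneratorConfig, derive_rate_constants, fit_nmrd,
                        gen_nmrd_curve, snr_time_reduction)
from fieldcycle.relaxometry import RelaxModelParams

# SABRE exchange: effective rate 5.77 1/s at 4 mM Ir catalyst and
# 50 mM pyridine (3 ligands bound per complex)
rates = derive_rate_constants(k=5.77, conc_ir_mM=4.0,
                              conc_py_total_mM=50.0, n_bound=3)
print(f"free pyridine: {rates.conc_py_free_mM:.1f} mM")
print(f"k_d = {rates.k_d:.2f} 1/s,  k_a' = {rates.k_a_prime:.2f} 1/s")

# time saved by detecting 13C through 1H polarization transfer
print(f"INEPT time reduction: {snr_time_reduction(2.53, 45.5, 4.9):.1f}x")

# regenerate a noisy 30-field dispersion curve and refit the model
init = RelaxModelParams(100.0, 1000.0, 1e-6, 1e-8, 50.0, 3.5e-12)
curve = gen_nmrd_curve(cfg=GeneratorConfig(seed=1))
fit = fit_nmrd(curve, init=init)
print(f"recovered dw2 = {fit.dw2:.1f} rad/s (truth 736.9)")
print(f"recovered dCSA = {fit.dcsa_ppm:.1f} ppm (truth 46.1)")
```

Output:

```
free pyridine: 38.0 mM
k_d = 9.53 1/s,  k_a' = 1.00 1/s
INEPT time reduction: 59.4x
recovered dw2 = 733.1 rad/s (truth 736.9)
recovered dCSA = 47.4 ppm (truth 46.1)
```

The free-pyridine pool is the total minus three bound ligands per complex;
the dissociation rate constant k_d ≈ 9.5 s⁻¹ and effective association
rate k_a′ ≈ 1 s⁻¹ follow from the two-equatorial-site relation. The ~59×
factor is the measurement-time saving from the squared INEPT signal gain
combined with repeating at the faster ¹H relaxation rate. The last two
lines show a seeded generate-and-refit round trip of the dispersion model
recovering the coupling constant Δω₂ and the chemical shift anisotropy
δ_CSA within their uncertainties.

## Command line

A thin CLI wraps the library:

```sh
fieldcycle simulate shield --seed 1 --out data/      # synthetic inputs
fieldcycle simulate coils  --seed 1 --out data/coils
fieldcycle shim --background data/background.csv --coils data/coils \
                --alpha 0.01 --sample-cm 5 --out shim.json
fieldcycle plan-field --target 5e-3 --current-table table.json
fieldcycle nmrd-fit --decays decays.csv --out params.json
fieldcycle transfer-compare --scenarios scenarios.yaml
fieldcycle exchange-fit --data exchange.csv --ir-mm 4 --py-mm 50 \
                        --out rates.json
```

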