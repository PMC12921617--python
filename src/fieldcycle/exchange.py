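"""SABRE-SHEATH chemical-exchange kinetics and PTF-sweep readout.

In SABRE, substrate (pyridine) reversibly binds an Ir complex carrying
parahydrogen-derived spin order.  After hyperpolarization, selective
inversion of either the free or the bound pyridine resonance followed by a
variable evolution delay tracks magnetization exchange between the two
sites.  All series are fitted globally with a shared biexponential

    s(tau_e) = A1 exp(-k tau_e) + A2 exp(-R tau_e)

where k is the effective exchange rate and R an effective relaxation rate.
With two equivalent equatorial pyridine ligands per complex, k converts to
the dissociation rate constant and the effective association rate:

    k_d  = k / (0.5 + [Ir]/[free Py])
    k_a' = ([Ir]/[free Py]) * k_d

(the factor 0.5 reflects the two-site degeneracy; [free Py] =
[Py]_total - n_bound [Ir] with n_bound = 3 ligands per complex).

A mechanistic two-compartment exchange simulator and the readout of a
polarization-transfer-field (PTF) sweep (optimum field, zero crossings)
complete the module.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.linalg import expm

#: Canonical names of the four kinetics series: inversion target x observed
#: site.
SERIES_NAMES = ("free_inv_free", "free_inv_bound",
                "bound_inv_free", "bound_inv_bound")


@dataclass
class ExchangeDataset:
    """Selective-inversion exchange kinetics: up to four integral series."""

    tau_e_s: np.ndarray
    series: dict  # name -> integrals array, names from SERIES_NAMES
    temperature_K: float = 288.0

    def __post_init__(self):
        self.tau_e_s = np.asarray(self.tau_e_s, dtype=float)
        if np.any(self.tau_e_s < 0):
            raise ValueError("delays must be non-negative")
        if self.tau_e_s.size >= 2 and not np.all(np.diff(self.tau_e_s) > 0):
            raise ValueError("delays must be strictly increasing")
        if not self.series:
            raise ValueError("need at least one series")
        clean = {}
        for name, vals in self.series.items():
            if name not in SERIES_NAMES:
                raise ValueError(f"unknown series name {name!r}")
            vals = np.asarray(vals, dtype=float)
            if vals.size != self.tau_e_s.size:
                raise ValueError(f"series {name!r} length mismatch")
            clean[name] = vals
        self.series = clean

    @classmethod
    def from_csv(cls, path, temperature_K: float = 288.0) -> "ExchangeDataset":
        """Read ``tau_e_s,series,integral`` CSV."""
        df = pd.read_csv(path)
        series = {}
        tau = None
        for name, grp in df.groupby("series"):
            grp = grp.sort_values("tau_e_s")
            if tau is None:
                tau = grp["tau_e_s"].to_numpy()
            elif not np.allclose(tau, grp["tau_e_s"].to_numpy()):
                raise ValueError("all series must share the delay grid")
            series[str(name)] = grp["integral"].to_numpy()
        return cls(tau, series, temperature_K)

    def to_csv(self, path) -> None:
        rows = []
        for name, vals in self.series.items():
            for t, v in zip(self.tau_e_s, vals):
                rows.append({"tau_e_s": t, "series": name, "integral": v})
        pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class ExchangeRates:
    """Exchange rates and the concentration bookkeeping that links them."""

    k: float                    # effective exchange rate, s^-1
    R: float                    # effective relaxation rate, s^-1
    k_d: float                  # dissociation rate constant, s^-1
    k_a_prime: float            # effective association rate, s^-1
    conc_ir_mM: float
    conc_py_total_mM: float
    conc_py_free_mM: float
    n_bound_per_complex: int = 3
    n_exchangeable: int = 2     # two equatorial sites -> the factor 0.5
    k_err: float | None = None
    k_d_err: float | None = None
    k_a_prime_err: float | None = None

    def __post_init__(self):
        free = self.conc_py_total_mM \
            - self.n_bound_per_complex * self.conc_ir_mM
        if abs(free - self.conc_py_free_mM) > 1e-9 * max(abs(free), 1.0):
            raise ValueError("free pyridine concentration inconsistent with "
                             "total, bound-per-complex and [Ir]")
        if self.conc_py_free_mM <= 0:
            raise ValueError("free pyridine concentration must be positive")
        x = self.conc_ir_mM / self.conc_py_free_mM
        kd_expect = self.k / (1.0 / self.n_exchangeable + x)
        if abs(self.k_d - kd_expect) > 1e-9 * max(abs(kd_expect), 1.0):
            raise ValueError("k_d inconsistent with k and concentrations")
        ka_expect = x * self.k_d
        if abs(self.k_a_prime - ka_expect) > 1e-9 * max(abs(ka_expect), 1.0):
            raise ValueError("k_a' inconsistent with k_d and concentrations")

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"k_s": self.k, "R_s": self.R, "k_d_s": self.k_d,
                       "k_a_prime_s": self.k_a_prime,
                       "conc_ir_mM": self.conc_ir_mM,
                       "conc_py_total_mM": self.conc_py_total_mM,
                       "conc_py_free_mM": self.conc_py_free_mM,
                       "n_bound_per_complex": self.n_bound_per_complex,
                       "k_err": self.k_err, "k_d_err": self.k_d_err,
                       "k_a_prime_err": self.k_a_prime_err}, fh, indent=1)


@dataclass
class PTFSweep:
    """Normalized signal vs polarization-transfer field (signed, uT)."""

    fields_uT: np.ndarray
    integrals: np.ndarray
    ppf_applied: bool = False

    def __post_init__(self):
        self.fields_uT = np.asarray(self.fields_uT, dtype=float)
        self.integrals = np.asarray(self.integrals, dtype=float)
        if self.fields_uT.size != self.integrals.size:
            raise ValueError("fields and integrals must match")
        if not np.all(np.diff(self.fields_uT) > 0):
            raise ValueError("fields must be strictly increasing")
        if not np.all(np.isfinite(self.integrals)):
            raise ValueError("integrals must be finite")

    @classmethod
    def from_csv(cls, path, ppf_applied: bool = False) -> "PTFSweep":
        """Read ``field_uT,integral`` CSV."""
        df = pd.read_csv(path).sort_values("field_uT")
        return cls(df["field_uT"].to_numpy(), df["integral"].to_numpy(),
                   ppf_applied)


# ---------------------------------------------------------------------------
# Global biexponential fit
# ---------------------------------------------------------------------------

@dataclass
class ExchangeFit:
    """Shared-rate biexponential fit over all kinetics series."""

    k: float
    R: float
    k_err: float | None
    R_err: float | None
    amplitudes: dict            # name -> (A1, A2)
    converged: bool
    rate_separation_ok: bool
    slow_component_constrained: bool
    result: lmfit.minimizer.MinimizerResult | None = None


def fit_exchange_global(data: ExchangeDataset) -> ExchangeFit:
    """Fit ``A1 exp(-k tau) + A2 exp(-R tau)`` jointly over all series.

    One shared fast rate ``k`` (exchange) and one shared slow rate ``R``
    (relaxation); per-series amplitudes are free and may be negative
    (inverted compartments start negative).  Warns when the rates are
    poorly separated (ratio < 3) and flags ``R`` as unconstrained when the
    slow amplitudes are all negligible.
    """
    if data.tau_e_s.size < 6:
        raise ValueError("need >= 6 delays per series")
    names = list(data.series)

    # initial guesses: fast rate from the half-decay time of the series
    # with the largest dynamic range, slow rate well below it
    spans = {n: np.ptp(v) for n, v in data.series.items()}
    ref = max(spans, key=spans.get)
    tau, sig = data.tau_e_s, data.series[ref]
    dev = np.abs(sig - sig[-1])
    above = np.nonzero(dev <= 0.5 * dev[0])[0]
    t_half = tau[above[0]] if above.size and tau[above[0]] > 0 \
        else max(tau[-1] / 4, 1e-6)
    k0 = math.log(2.0) / t_half

    params = lmfit.Parameters()
    params.add("k", value=k0, min=1e-6)
    params.add("R", value=k0 / 50.0, min=1e-9)
    for i, n in enumerate(names):
        v = data.series[n]
        params.add(f"a1_{i}", value=float(v[0] - v[-1]))
        params.add(f"a2_{i}", value=float(v[-1]))

    def residual(p):
        out = []
        for i, n in enumerate(names):
            model = p[f"a1_{i}"] * np.exp(-p["k"] * data.tau_e_s) \
                + p[f"a2_{i}"] * np.exp(-p["R"] * data.tau_e_s)
            out.append(data.series[n] - model)
        return np.concatenate(out)

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        warnings.warn("exchange fit did not converge; returning best-so-far",
                      stacklevel=2)
    p = result.params
    k, R = float(p["k"].value), float(p["R"].value)
    if k < R:  # enforce the fast/slow labelling
        k, R = R, k
        fast, slow = "a2", "a1"
    else:
        fast, slow = "a1", "a2"
    amplitudes = {n: (float(p[f"{fast}_{i}"].value),
                      float(p[f"{slow}_{i}"].value))
                  for i, n in enumerate(names)}
    sep_ok = (k / R) >= 3.0 if R > 0 else True
    if not sep_ok:
        warnings.warn("k and R differ by less than 3x; the two rates are "
                      "poorly identifiable", stacklevel=2)
    nonzero = data.tau_e_s[data.tau_e_s > 0]
    if nonzero.size and k > 10.0 / nonzero.min():
        sep_ok = False
        warnings.warn("fitted k decays faster than the delay-grid "
                      "resolution; the fast component is poorly "
                      "identifiable", stacklevel=2)
    a1_scale = max(abs(a[0]) for a in amplitudes.values())
    slow_small = all(abs(a[1]) < 1e-6 * max(a1_scale, 1e-300)
                     for a in amplitudes.values())
    if slow_small:
        warnings.warn("slow-component amplitudes are negligible; R is "
                      "unconstrained by the data", stacklevel=2)
    return ExchangeFit(
        k=k, R=R,
        k_err=p["k"].stderr, R_err=p["R"].stderr,
        amplitudes=amplitudes, converged=bool(result.success),
        rate_separation_ok=sep_ok,
        slow_component_constrained=not slow_small, result=result)


# ---------------------------------------------------------------------------
# Rate-constant algebra
# ---------------------------------------------------------------------------

def derive_rate_constants(k: float, conc_ir_mM: float, conc_py_total_mM: float,
                          n_bound: int = 3, k_err: float | None = None,
                          R: float = np.nan,
                          n_exchangeable: int = 2) -> ExchangeRates:
    """Dissociation and association rate constants from the effective rate.

    With x = [Ir]/[free Py] and two exchangeable equatorial sites:

        k_d  = k / (0.5 + x),        k_a' = x * k_d.

    For a complex with ``n_exchangeable != 2`` equivalent sites the 0.5 is
    generalized to ``1/n_exchangeable``.  Uncertainty on k, when given,
    propagates linearly (the concentration ratio is treated as exact).
    """
    free = conc_py_total_mM - n_bound * conc_ir_mM
    if free <= 0:
        raise ValueError("free pyridine concentration must be positive: "
                         f"total {conc_py_total_mM} mM - {n_bound} x "
                         f"{conc_ir_mM} mM <= 0")
    if n_exchangeable < 1:
        raise ValueError("n_exchangeable must be a positive integer")
    x = conc_ir_mM / free
    degeneracy = 1.0 / n_exchangeable
    k_d = k / (degeneracy + x)
    k_a = x * k_d
    kd_err = ka_err = None
    if k_err is not None:
        kd_err = k_err / (degeneracy + x)
        ka_err = x * kd_err
    return ExchangeRates(
        k=k, R=R, k_d=k_d, k_a_prime=k_a,
        conc_ir_mM=conc_ir_mM, conc_py_total_mM=conc_py_total_mM,
        conc_py_free_mM=free, n_bound_per_complex=n_bound,
        n_exchangeable=n_exchangeable, k_err=k_err, k_d_err=kd_err,
        k_a_prime_err=ka_err)


# ---------------------------------------------------------------------------
# PTF-sweep readout
# ---------------------------------------------------------------------------

def ptf_sweep_analysis(sweep: PTFSweep, window: int = 2,
                       flat_drop: float = 0.05) -> dict:
    """Optimum field and zero crossings of a PTF sweep.

    The optimum is the vertex of a local quadratic fitted around the
    discrete maximum (+/-``window`` points), clamped to the fitted window;
    ``optimum_halfwidth_uT`` is the half-width of the near-flat region in
    which the quadratic stays within ``flat_drop`` (5%) of its peak.  Zero
    crossings are located by sign changes with linear interpolation.
    """
    if sweep.fields_uT.size < 5:
        raise ValueError("need >= 5 sweep points")
    B, s = sweep.fields_uT, sweep.integrals
    imax = int(np.argmax(s))
    lo, hi = max(0, imax - window), min(B.size, imax + window + 1)
    Bw, sw = B[lo:hi], s[lo:hi]
    if Bw.size >= 3:
        a, b, c = np.polyfit(Bw, sw, 2)
        if a < 0:
            opt = float(np.clip(-b / (2 * a), Bw[0], Bw[-1]))
            peak = a * opt**2 + b * opt + c
            halfwidth = float(np.sqrt(flat_drop * abs(peak) / abs(a))) \
                if peak != 0 else 0.0
        else:  # window not locally concave; keep the discrete maximum
            opt, halfwidth = float(B[imax]), 0.0
    else:
        opt, halfwidth = float(B[imax]), 0.0

    crossings = []
    for i in range(B.size - 1):
        if s[i] == 0.0:
            crossings.append(float(B[i]))
        elif s[i] * s[i + 1] < 0:
            frac = s[i] / (s[i] - s[i + 1])
            crossings.append(float(B[i] + frac * (B[i + 1] - B[i])))
    if s[-1] == 0.0:
        crossings.append(float(B[-1]))
    return {"optimum_field_uT": opt,
            "optimum_halfwidth_uT": halfwidth,
            "zero_crossings_uT": crossings}


# ---------------------------------------------------------------------------
# Mechanistic two-site simulator (tests the fitting chain)
# ---------------------------------------------------------------------------

def simulate_two_site_kinetics(rates: ExchangeRates, R: float,
                               init: tuple[float, float],
                               tau_grid_s) -> ExchangeDataset:
    """Two-compartment magnetization exchange with uniform relaxation.

    Free and exchangeable-bound magnetization exchange at first-order rates
    ``k_fb = k_a'`` (free -> bound) and ``k_bf = k_d`` (bound -> free), both
    compartments relaxing at R:

        d/dt [Mf, Mb] = ([[-k_fb, k_bf], [k_fb, -k_bf]] - R I) [Mf, Mb]

    The non-zero kinetic eigenvalue is ``k_fb + k_bf`` (on top of R).
    ``init`` is the magnetization at tau = 0, e.g. ``(-1, +1)`` for
    selective inversion of the free site.  Returns the free and bound
    series under the appropriate names for the chosen inversion pattern.
    """
    tau = np.asarray(tau_grid_s, dtype=float)
    k_fb, k_bf = rates.k_a_prime, rates.k_d
    K = np.array([[-k_fb - R, k_bf], [k_fb, -k_bf - R]])
    m0 = np.asarray(init, dtype=float)
    out = np.empty((tau.size, 2))
    for i, t in enumerate(tau):
        out[i] = expm(K * t) @ m0
    prefix = "free_inv" if init[0] < init[1] else "bound_inv"
    return ExchangeDataset(tau, {f"{prefix}_free": out[:, 0],
                                 f"{prefix}_bound": out[:, 1]})
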