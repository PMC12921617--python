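"""Nuclear magnetic relaxation dispersion (NMRD) analysis of [1-13C]pyruvate.

The longitudinal relaxation rate R1 = 1/T1 of the carboxyl 13C depends on
the magnetic field.  Per field, T1 is extracted from a magnetization decay
trace; all traces are fitted globally with a biexponential

    s(t) = A1 exp(-t/tau1) + A2 exp(-t/tau2) + y0

whose slow time constant tau2 is shared across fields (it compensates a
small, field-independent secondary decay; y0 absorbs the thermal
polarization at the given field).  T1 at each field is tau1.

The dispersion of R1(B) is modelled as two inner-sphere Lorentzian terms
plus a chemical-shift-anisotropy (CSA) term:

    R_IS,i  = dW_i^2 tau_Ci / (1 + (w_C tau_Ci)^2),       i = 1, 2
    R_CSA   = (1/5) (w_C * dCSA)^2 tau_CSA / (1 + (w_C tau_CSA)^2)
    R1(B)   = R_IS,1 + R_IS,2 + R_CSA,      w_C = gamma_13C * B

where dW_i are fitted coupling constants (rad/s), tau_Ci their correlation
times, dCSA the chemical shift anisotropy (ppm) and tau_CSA its correlation
time.  The model is used exactly in this three-term form, with no
spin-number or dipolar prefactors.

Module also provides the T1(B) interpolator consumed by the transfer-loss
integral and the SNR-time bookkeeping for INEPT-enhanced detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

# ---------------------------------------------------------------------------
# Gyromagnetic ratios (rad s^-1 T^-1); magnitudes, sign ignored for |w_C|
# ---------------------------------------------------------------------------

GAMMA_13C = 2 * math.pi * 10.7084e6
GAMMA_1H = 2 * math.pi * 42.577478518e6
GAMMA_15N = 2 * math.pi * 4.3173e6


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class DecayTrace:
    """A magnetization decay at one application field."""

    field_T: float
    delays_s: np.ndarray
    signals: np.ndarray
    signal_errors: np.ndarray | None = None

    def __post_init__(self):
        self.delays_s = np.asarray(self.delays_s, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signal_errors is not None:
            self.signal_errors = np.asarray(self.signal_errors, dtype=float)
            if self.signal_errors.size != self.delays_s.size:
                raise ValueError("one error per point required")
        if self.signals.size != self.delays_s.size:
            raise ValueError("signals and delays must match")
        if np.any(self.delays_s < 0):
            raise ValueError("delays must be non-negative")
        if self.delays_s.size >= 2 and not np.all(np.diff(self.delays_s) > 0):
            raise ValueError("delays must be strictly increasing")
        if self.delays_s.size < 5:
            raise ValueError("need >= 5 points per trace for fitting")


@dataclass
class DecayFit:
    """Result of the global biexponential fit over all fields."""

    fields_T: np.ndarray
    a1: np.ndarray
    tau1_s: np.ndarray          # per-field T1
    tau1_err_s: np.ndarray
    y0: np.ndarray
    a2_fraction: float          # shared A2/A1
    tau2_s: float               # shared slow time constant
    tau2_err_s: float
    result: lmfit.minimizer.MinimizerResult | None = None
    converged: bool = True

    @property
    def t1_s(self) -> np.ndarray:
        return self.tau1_s

    def to_curve(self) -> "NMRDCurve":
        r1 = 1.0 / self.tau1_s
        r1_err = self.tau1_err_s / self.tau1_s**2
        order = np.argsort(self.fields_T)
        return NMRDCurve(self.fields_T[order], r1[order], r1_err[order])


@dataclass
class NMRDCurve:
    """Relaxation rate vs field: the dispersion profile."""

    fields_T: np.ndarray
    r1: np.ndarray
    r1_err: np.ndarray | None = None

    def __post_init__(self):
        self.fields_T = np.asarray(self.fields_T, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        if self.r1.size != self.fields_T.size:
            raise ValueError("r1 and fields must match")
        if np.any(self.fields_T <= 0):
            raise ValueError("fields must be strictly positive")
        if self.fields_T.size >= 2 and not np.all(np.diff(self.fields_T) > 0):
            raise ValueError("fields must be strictly increasing")
        if np.any(self.r1 <= 0):
            raise ValueError("relaxation rates must be positive")
        if self.r1_err is not None:
            self.r1_err = np.asarray(self.r1_err, dtype=float)

    @property
    def t1_s(self) -> np.ndarray:
        return 1.0 / self.r1

    @classmethod
    def from_csv(cls, path) -> "NMRDCurve":
        """Read ``field_T,T1_s[,T1_err_s]`` CSV."""
        df = pd.read_csv(path).sort_values("field_T")
        t1 = df["T1_s"].to_numpy()
        err = df["T1_err_s"].to_numpy() if "T1_err_s" in df.columns else None
        r1_err = err / t1**2 if err is not None else None
        return cls(df["field_T"].to_numpy(), 1.0 / t1, r1_err)

    def to_csv(self, path) -> None:
        out = {"field_T": self.fields_T, "T1_s": self.t1_s}
        if self.r1_err is not None:
            out["T1_err_s"] = self.r1_err / self.r1**2
        pd.DataFrame(out).to_csv(path, index=False)


@dataclass
class RelaxModelParams:
    """The six parameters of the three-term dispersion model."""

    dw1: float          # rad/s
    dw2: float          # rad/s
    tau_c1: float       # s
    tau_c2: float       # s
    dcsa_ppm: float     # ppm
    tau_csa: float      # s
    gamma: float = GAMMA_13C
    ci95: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("dw1", "dw2", "tau_c1", "tau_c2", "dcsa_ppm", "tau_csa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_json(self, path) -> None:
        import json
        with open(path, "w") as fh:
            json.dump({"dw1_rad_s": self.dw1, "dw2_rad_s": self.dw2,
                       "tau_c1_s": self.tau_c1, "tau_c2_s": self.tau_c2,
                       "dcsa_ppm": self.dcsa_ppm, "tau_csa_s": self.tau_csa,
                       "gamma_rad_s_T": self.gamma,
                       "ci95": self.ci95}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RelaxModelParams":
        import json
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["dw1_rad_s"], d["dw2_rad_s"], d["tau_c1_s"],
                   d["tau_c2_s"], d["dcsa_ppm"], d["tau_csa_s"],
                   gamma=d.get("gamma_rad_s_T", GAMMA_13C),
                   ci95=d.get("ci95", {}))


#: Fitted dispersion parameters for the standard dDNP [1-13C]pyruvate
#: composition (dw in rad/s, correlation times in seconds, dCSA in ppm).
PYRUVATE_DNP_PARAMS = RelaxModelParams(
    dw1=91.6, dw2=736.9, tau_c1=541.8e-9, tau_c2=6.6e-9,
    dcsa_ppm=46.1, tau_csa=3.5e-12,
    ci95={"dw1_rad_s": 8.7, "dw2_rad_s": 42.4, "tau_c1_s": 110.9e-9,
          "tau_c2_s": 0.7e-9, "dcsa_ppm": 3.0, "tau_csa_s": 0.4e-12})


# ---------------------------------------------------------------------------
# Dispersion model
# ---------------------------------------------------------------------------

def nmrd_model(B, params: RelaxModelParams):
    """Three-term dispersion model R1(B) in s^-1.

    ``R1 = R_IS,1 + R_IS,2 + R_CSA`` with Larmor angular frequency
    ``w_C = gamma B``.  Negative fields are rejected; take ``|B|`` upstream
    where a signed convention is in use.
    """
    B = np.asarray(B, dtype=float)
    if np.any(B < 0):
        raise ValueError("field must be non-negative; use |B| upstream")
    w = params.gamma * B
    r_is1 = params.dw1**2 * params.tau_c1 / (1.0 + (w * params.tau_c1) ** 2)
    r_is2 = params.dw2**2 * params.tau_c2 / (1.0 + (w * params.tau_c2) ** 2)
    delta = params.dcsa_ppm * 1e-6
    r_csa = 0.2 * (w * delta) ** 2 * params.tau_csa \
        / (1.0 + (w * params.tau_csa) ** 2)
    out = r_is1 + r_is2 + r_csa
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Global biexponential decay fitting
# ---------------------------------------------------------------------------

def _trace_model(t, a1, tau1, a2_frac, tau2, y0):
    return a1 * np.exp(-t / tau1) + a2_frac * a1 * np.exp(-t / tau2) + y0


def fit_decays_global(traces: list[DecayTrace]) -> DecayFit:
    """Global biexponential fit with a shared slow component.

    Each trace gets its own amplitude ``A1``, time constant ``tau1`` (the
    per-field T1) and baseline ``y0``; a single amplitude fraction
    ``A2 = a2_frac * A1`` and slow time constant ``tau2`` are shared across
    all traces.  Weighted (inverse-variance) least squares when errors are
    supplied, unweighted otherwise.

    To keep the slow component identifiable, ``tau2`` is bounded below by
    twice the largest initial ``tau1`` estimate and ``a2_frac`` starts at
    5% (its contribution is known to be small).
    """
    if not traces:
        raise ValueError("need at least one trace")
    n_par = 3 * len(traces) + 2
    n_pts = sum(t.delays_s.size for t in traces)
    if n_pts <= n_par:
        raise ValueError("fewer data points than fit parameters")

    # initial tau1 per trace from a log-linear fit of the baseline-subtracted
    # early decay
    tau1_init, a1_init, y0_init = [], [], []
    for tr in traces:
        y0g = float(tr.signals[-1]) * 0.5
        amp = tr.signals - y0g
        pos = amp > np.max(np.abs(amp)) * 1e-3
        if pos.sum() >= 2:
            slope = np.polyfit(tr.delays_s[pos], np.log(amp[pos]), 1)[0]
            tau = -1.0 / slope if slope < 0 else tr.delays_s[-1]
        else:
            tau = max(tr.delays_s[-1] / 3.0, 1e-9)
        tau1_init.append(max(tau, 1e-9))
        a1_init.append(float(tr.signals[0] - y0g))
        y0_init.append(y0g)

    tau2_floor = 2.0 * max(tau1_init)
    params = lmfit.Parameters()
    params.add("a2_frac", value=0.05, min=0.0, max=1.0)
    params.add("tau2", value=2.0 * tau2_floor, min=tau2_floor)
    for i, tr in enumerate(traces):
        params.add(f"a1_{i}", value=a1_init[i])
        params.add(f"tau1_{i}", value=tau1_init[i], min=1e-9)
        params.add(f"y0_{i}", value=y0_init[i])

    def residual(p):
        out = []
        for i, tr in enumerate(traces):
            model = _trace_model(tr.delays_s, p[f"a1_{i}"], p[f"tau1_{i}"],
                                 p["a2_frac"], p["tau2"], p[f"y0_{i}"])
            r = tr.signals - model
            if tr.signal_errors is not None:
                r = r / tr.signal_errors
            out.append(r)
        return np.concatenate(out)

    result = lmfit.minimize(residual, params, method="leastsq",
                            max_nfev=3000)
    if not result.success:
        warnings.warn("global decay fit did not converge; returning "
                      "best-so-far parameters", stacklevel=2)
    p = result.params
    tau1 = np.array([p[f"tau1_{i}"].value for i in range(len(traces))])
    tau1_err = np.array([p[f"tau1_{i}"].stderr or np.nan
                         for i in range(len(traces))])
    return DecayFit(
        fields_T=np.array([tr.field_T for tr in traces]),
        a1=np.array([p[f"a1_{i}"].value for i in range(len(traces))]),
        tau1_s=tau1, tau1_err_s=tau1_err,
        y0=np.array([p[f"y0_{i}"].value for i in range(len(traces))]),
        a2_fraction=float(p["a2_frac"].value),
        tau2_s=float(p["tau2"].value),
        tau2_err_s=float(p["tau2"].stderr or np.nan),
        result=result, converged=bool(result.success))


def read_decay_csv(path) -> list[DecayTrace]:
    """Read ``field_T,vd_s,signal[,signal_err]`` CSV into per-field traces."""
    df = pd.read_csv(path)
    traces = []
    for field_T, grp in df.groupby("field_T"):
        grp = grp.sort_values("vd_s")
        err = grp["signal_err"].to_numpy() if "signal_err" in grp.columns \
            else None
        traces.append(DecayTrace(float(field_T), grp["vd_s"].to_numpy(),
                                 grp["signal"].to_numpy(), err))
    return traces


# ---------------------------------------------------------------------------
# NMRD model fitting
# ---------------------------------------------------------------------------

#: Generic starting point for dispersion fits; the CSA correlation time
#: doubles as the fixed prior (see fit_nmrd) and defaults to the pyruvate
#: literature value.
DEFAULT_NMRD_INIT = RelaxModelParams(
    dw1=100.0, dw2=1000.0, tau_c1=1e-6, tau_c2=1e-8,
    dcsa_ppm=50.0, tau_csa=3.5e-12)


def fit_nmrd(curve: NMRDCurve,
             init: RelaxModelParams = DEFAULT_NMRD_INIT,
             bounds: dict | None = None,
             fix: tuple = ("tau_csa",)) -> RelaxModelParams:
    """Fit the three-term dispersion model to R1(B).

    Weighted least squares (inverse variance when ``r1_err`` is present).
    The two inner-sphere correlation times are ordered ``tau_c1 > tau_c2``
    by construction (``tau_c2 = ratio * tau_c1`` with ratio in (0, 1)), which
    removes the label-swap degeneracy.  95% CIs come from the covariance at
    the optimum; parameters pinned at a bound and ill-conditioned (nearly
    degenerate ``tau_c1 ~ tau_c2``) fits are flagged with a warning.

    ``fix`` lists parameters held at their ``init`` value.  By default the
    CSA correlation time is fixed: throughout the accessible field range
    ``w_C tau_CSA << 1`` (extreme narrowing), so only the product
    ``dCSA^2 tau_CSA`` is identifiable from the data and ``tau_CSA`` must
    come from prior knowledge for ``dCSA`` to be meaningful.
    """
    if curve.fields_T.size < 7:
        raise ValueError("need >= 7 points to fit 6 parameters")
    bounds = bounds or {}

    params = lmfit.Parameters()

    def add(name, value, lo=0.0, hi=np.inf):
        user = bounds.get(name)
        if user is not None:
            lo, hi = user
        params.add(name, value=value, min=lo, max=hi,
                   vary=name not in fix)

    add("dw1", init.dw1, 1e-3, 1e6)
    add("dw2", init.dw2, 1e-3, 1e6)
    add("tau_c1", init.tau_c1, 1e-12, 1.0)
    params.add("tau_ratio", value=min(init.tau_c2 / init.tau_c1, 0.9),
               min=1e-6, max=1.0, vary="tau_c2" not in fix)
    add("dcsa_ppm", init.dcsa_ppm, 1e-3, 1e4)
    add("tau_csa", init.tau_csa, 1e-15, 1e-6)

    weights = None
    if curve.r1_err is not None and np.all(curve.r1_err > 0):
        weights = 1.0 / curve.r1_err

    def residual(p):
        m = RelaxModelParams(p["dw1"].value, p["dw2"].value,
                             p["tau_c1"].value,
                             p["tau_c1"].value * p["tau_ratio"].value,
                             p["dcsa_ppm"].value, p["tau_csa"].value,
                             gamma=init.gamma)
        r = curve.r1 - nmrd_model(curve.fields_T, m)
        return r * weights if weights is not None else r

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        warnings.warn("NMRD fit did not converge", stacklevel=2)
    p = result.params
    tau_c1 = p["tau_c1"].value
    tau_c2 = tau_c1 * p["tau_ratio"].value
    if tau_c2 > 0.5 * tau_c1:
        warnings.warn("tau_c1 and tau_c2 nearly degenerate; the two "
                      "inner-sphere terms are poorly identifiable",
                      stacklevel=2)
    for name in ("dw1", "dw2", "tau_c1", "dcsa_ppm", "tau_csa"):
        par = p[name]
        span = par.max - par.min
        if np.isfinite(span) and span > 0:
            rel = min(par.value - par.min, par.max - par.value) / span
            if rel < 1e-6:
                warnings.warn(f"parameter {name} pinned at a bound",
                              stacklevel=2)

    def err(name, scale=1.0):
        e = p[name].stderr
        return 1.96 * e * scale if e is not None else np.nan

    ratio_err = p["tau_ratio"].stderr or np.nan
    tau_c2_ci = 1.96 * np.hypot(
        (p["tau_c1"].stderr or 0.0) * p["tau_ratio"].value,
        ratio_err * tau_c1) if np.isfinite(ratio_err) else np.nan
    return RelaxModelParams(
        p["dw1"].value, p["dw2"].value, tau_c1, tau_c2,
        p["dcsa_ppm"].value, p["tau_csa"].value, gamma=init.gamma,
        ci95={"dw1_rad_s": err("dw1"), "dw2_rad_s": err("dw2"),
              "tau_c1_s": err("tau_c1"), "tau_c2_s": tau_c2_ci,
              "dcsa_ppm": err("dcsa_ppm"), "tau_csa_s": err("tau_csa")})


# ---------------------------------------------------------------------------
# T1 interpolation and SNR bookkeeping
# ---------------------------------------------------------------------------

def t1_interpolator(curve: NMRDCurve):
    """Monotone-safe interpolator B -> T1 (seconds).

    Interpolates log(r1) against log(B) with a shape-preserving PCHIP
    (no overshoot between points), clamped to the endpoint values outside
    the measured field range.
    """
    logb = np.log(curve.fields_T)
    logr = np.log(curve.r1)
    pchip = PchipInterpolator(logb, logr, extrapolate=False)
    lo, hi = logb[0], logb[-1]

    def t1_of_B(B):
        B = np.asarray(B, dtype=float)
        if np.any(B <= 0):
            raise ValueError("field must be positive")
        x = np.clip(np.log(B), lo, hi)
        out = 1.0 / np.exp(pchip(x))
        return float(out) if out.ndim == 0 else out

    return t1_of_B


def snr_time_reduction(gain: float, t1_slow: float, t1_fast: float) -> float:
    """Measurement-time reduction from polarization-transfer detection.

    Signal averaging time to a target SNR scales as 1/SNR^2 and the
    repetition time as the T1 of the polarization source, so transferring
    from a fast-relaxing nucleus (1H) with signal gain g reduces the time by
    ``g^2 * (t1_slow / t1_fast)``.
    """
    if gain <= 0 or t1_slow <= 0 or t1_fast <= 0:
        raise ValueError("all inputs must be positive")
    return gain**2 * t1_slow / t1_fast
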