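"""Ultralow-field shimming of a mu-metal shield.

Nine shim coils (X, Y, Z offsets, five first-order gradients, one
second-order Z term) null the residual background field inside the shield.
Shimming runs in two stages:

1. *Simulative tuning* — each coil's field per unit current mu_coil(z) is
   calibrated from +/-I scans, and the nine currents are found by minimizing
   the regularized loss  L = sum_sample ||B_b + sum_i I_i mu_i||^2
   + alpha sum_i I_i^2  with its analytic gradient; 95% confidence
   intervals come from the Hessian at the optimum.
2. *Iterative tuning* — the X, Y, Z offset currents are refined by
   coordinate descent against a field probe at the sample center until the
   magnitude drops below a threshold (2 nT by default).

The same linear calibration supplies the Z-shim field schedule (nominally
108 nT per mA) used to step the polarization-transfer field.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fieldmap import FieldProfile, HomogeneityStats, homogeneity_stats

logger = logging.getLogger("fieldcycle")

#: Canonical coil order used everywhere a 9-vector of currents appears.
COIL_IDS = ("X", "Y", "Z", "dY/dx", "dZ/dx", "dZ/dy", "dY/dy", "dZ/dz",
            "d2Z/dz2")

#: Default regularization weight (nT^2/mA^2): small against the unshimmed
#: loss (~10^5 nT^2 per sample point) yet enough to suppress degenerate
#: large-current solutions.
DEFAULT_ALPHA = 1e-2

#: Iterative-tuning termination: field magnitude at the sample center (nT).
DEFAULT_STOP_NT = 2.0


@dataclass
class CoilResponse:
    """Per-position 3-component field per unit current of one shim coil."""

    coil_id: str
    grid_usteps: np.ndarray
    mu: np.ndarray  # shape (n, 3), nT/mA

    def __post_init__(self):
        self.grid_usteps = np.asarray(self.grid_usteps, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.shape != (self.grid_usteps.size, 3):
            raise ValueError("mu must have shape (n_positions, 3)")
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("coil response must be finite everywhere")

    def resample(self, grid: np.ndarray) -> "CoilResponse":
        from scipy.interpolate import CubicSpline
        grid = np.asarray(grid, dtype=float)
        mu = np.column_stack([
            CubicSpline(self.grid_usteps, self.mu[:, k])(grid) for k in range(3)])
        return CoilResponse(self.coil_id, grid, mu)


@dataclass
class ShimState:
    """A 9-current shim solution with confidence intervals and residuals."""

    currents_mA: np.ndarray
    ci95_mA: np.ndarray
    alpha: float
    residual_profile: FieldProfile | None = None
    residual_stats: HomogeneityStats | None = None
    converged: bool = True
    ci_reliable: bool = True
    info: dict = field(default_factory=dict)

    def __post_init__(self):
        self.currents_mA = np.asarray(self.currents_mA, dtype=float)
        self.ci95_mA = np.asarray(self.ci95_mA, dtype=float)
        if self.currents_mA.size != self.ci95_mA.size:
            raise ValueError("one CI per current required")
        if np.any(self.ci95_mA < 0):
            raise ValueError("confidence half-widths must be non-negative")

    def to_json(self, path) -> None:
        out = {"currents_mA": self.currents_mA.tolist(),
               "ci95_mA": self.ci95_mA.tolist(),
               "alpha": self.alpha,
               "converged": self.converged,
               "ci_reliable": self.ci_reliable}
        if self.residual_stats is not None:
            s = self.residual_stats
            out["residual_stats"] = {"mean_nT": s.mean, "median_nT": s.median,
                                     "sd_nT": s.sd, "rel_sd_percent": s.rel_sd}
        with open(path, "w") as fh:
            json.dump(out, fh, indent=1)


# ---------------------------------------------------------------------------
# Coil calibration and field simulation
# ---------------------------------------------------------------------------

def calibrate_coil_response(profile_plus: FieldProfile,
                            profile_minus: FieldProfile,
                            delta_current_mA: float,
                            coil_id: str = "") -> CoilResponse:
    """Field per unit current from a symmetric +/-I pair of scans.

    mu(z) = (B_plus(z) - B_minus(z)) / (2 |I|) per component.  The symmetric
    difference cancels the background and any response term odd in I.
    Grids must match exactly; no silent resampling at this stage.
    """
    if delta_current_mA == 0:
        raise ValueError("delta current must be non-zero")
    if profile_plus.position_usteps.size != profile_minus.position_usteps.size \
            or not np.allclose(profile_plus.position_usteps,
                               profile_minus.position_usteps):
        raise ValueError("plus and minus scans must share an identical grid")
    denom = 2.0 * abs(delta_current_mA)
    mu = np.column_stack([
        (profile_plus.bx_nT - profile_minus.bx_nT) / denom,
        (profile_plus.by_nT - profile_minus.by_nT) / denom,
        (profile_plus.bz_nT - profile_minus.bz_nT) / denom,
    ])
    return CoilResponse(coil_id or profile_plus.label,
                        profile_plus.position_usteps.copy(), mu)


def read_coil_scan_csv(path) -> tuple[FieldProfile, float]:
    """Read a per-coil scan CSV ``position_usteps,bx_nT,by_nT,bz_nT,current_mA``."""
    df = pd.read_csv(path)
    current = float(df["current_mA"].iloc[0])
    prof = FieldProfile(df["position_usteps"].to_numpy(), df["bx_nT"].to_numpy(),
                        df["by_nT"].to_numpy(), df["bz_nT"].to_numpy())
    return prof, current


def _common_grid(background: FieldProfile,
                 responses: list[CoilResponse]
                 ) -> tuple[FieldProfile, list[CoilResponse]]:
    """Spline-resample background and all coils to the densest grid."""
    grids = [background.position_usteps] + [r.grid_usteps for r in responses]
    dense = max(grids, key=lambda g: g.size)
    lo = max(g[0] for g in grids)
    hi = min(g[-1] for g in grids)
    grid = dense[(dense >= lo) & (dense <= hi)]
    bg = background.resample(grid)
    rs = [r.resample(grid) for r in responses]
    return bg, rs


def simulate_field(background: FieldProfile,
                   responses: list[CoilResponse],
                   currents_mA) -> FieldProfile:
    """Linear superposition B_sim(z) = B_b(z) + sum_i I_i mu_i(z).

    Profiles on different grids are cubic-spline resampled to the densest
    common grid first.
    """
    currents = np.asarray(currents_mA, dtype=float)
    if len(responses) != currents.size:
        raise ValueError("one current per coil response required")
    if len(responses) == 0:
        raise ValueError("at least one coil response required")
    bg, rs = _common_grid(background, responses)
    total = np.column_stack([bg.bx_nT, bg.by_nT, bg.bz_nT]).astype(float)
    for resp, cur in zip(rs, currents):
        total += cur * resp.mu
    return FieldProfile(bg.position_usteps, total[:, 0], total[:, 1],
                        total[:, 2], label="simulated")


# ---------------------------------------------------------------------------
# Loss, gradient, optimization
# ---------------------------------------------------------------------------

def _design_arrays(background: FieldProfile, responses: list[CoilResponse],
                   sample_positions) -> tuple[np.ndarray, np.ndarray]:
    """Stacked background vector b (3m,) and design matrix M (3m, ncoil)
    over the sample positions, in nT and nT/mA."""
    bg, rs = _common_grid(background, responses)
    pos = bg.position_usteps
    if sample_positions is None:
        mask = np.ones(pos.size, dtype=bool)
    else:
        sample_positions = np.asarray(sample_positions, dtype=float)
        mask = np.isin(pos, sample_positions)
        if mask.sum() != sample_positions.size:
            # tolerate float fuzz from resampling
            mask = np.zeros(pos.size, dtype=bool)
            for p in sample_positions:
                idx = np.argmin(np.abs(pos - p))
                if abs(pos[idx] - p) > 1e-6 * max(abs(p), 1.0):
                    raise ValueError("sample positions must lie on the grid")
                mask[idx] = True
    b = np.column_stack([bg.bx_nT, bg.by_nT, bg.bz_nT])[mask].ravel()
    M = np.column_stack([r.mu[mask].ravel() for r in rs])
    return b, M


def shim_loss(background: FieldProfile, responses: list[CoilResponse],
              currents_mA, alpha: float = DEFAULT_ALPHA,
              sample_positions=None) -> tuple[float, np.ndarray]:
    """Regularized shim loss and its analytic gradient.

    ``L = sum_sample ||B||^2 + alpha sum_i I_i^2`` with
    ``B = B_b + sum_i I_i mu_i``; the gradient is
    ``dL/dI_i = 2 sum_sample B . mu_i + 2 alpha I_i``.
    Units: nT^2 with currents in mA and alpha in nT^2/mA^2.
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    currents = np.asarray(currents_mA, dtype=float)
    b, M = _design_arrays(background, responses, sample_positions)
    resid = b + M @ currents
    loss = float(resid @ resid + alpha * currents @ currents)
    grad = 2.0 * (M.T @ resid) + 2.0 * alpha * currents
    return loss, grad


def optimize_shims(background: FieldProfile, responses: list[CoilResponse],
                   alpha: float = DEFAULT_ALPHA,
                   sample_positions=None) -> ShimState:
    """Simulative tuning: minimize the regularized loss over the 9 currents.

    Uses scipy's trust-constr minimizer with the analytic gradient.  For a
    linear coil model the problem is an (optionally ridge-) regularized
    linear least squares, so the optimum satisfies the normal equations
    ``(M^T M + alpha I) c = -M^T b``; the iterative solve is kept as the
    contract (it also covers bound-constrained variants) and the normal
    equations serve as an independent check in the tests.

    Confidence intervals (95%) come from the inverse Hessian of the loss:
    ``cov = sigma^2 (M^T M + alpha I)^{-1}`` with ``sigma^2`` the residual
    variance over ``3m - n_coils`` degrees of freedom, scaled by a
    t-quantile.  All-zero coil responses are dropped from the design with a
    warning (their currents and CIs are returned as 0).
    """
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    b, M = _design_arrays(background, responses, sample_positions)
    ncoil = M.shape[1]

    live = np.array([np.any(M[:, j] != 0) for j in range(ncoil)])
    if not np.all(live):
        warnings.warn("dropping all-zero coil response(s) from the design",
                      stacklevel=2)
    Ml = M[:, live]

    def fun(c):
        r = b + Ml @ c
        return float(r @ r + alpha * c @ c)

    def jac(c):
        return 2.0 * (Ml.T @ (b + Ml @ c)) + 2.0 * alpha * c

    def hess(c):
        return 2.0 * (Ml.T @ Ml + alpha * np.eye(Ml.shape[1]))

    x0 = np.zeros(Ml.shape[1])
    res = optimize.minimize(fun, x0, jac=jac, hess=hess, method="trust-constr",
                            options={"gtol": 1e-10, "xtol": 1e-12,
                                     "maxiter": 2000})
    c_live = res.x
    # the loss is exactly quadratic in the currents, so one Newton step from
    # the solver's solution removes any leftover trust-region truncation
    try:
        c_live = c_live - np.linalg.solve(hess(c_live), jac(c_live))
    except np.linalg.LinAlgError:
        pass

    # 95% CIs from the Hessian of the data-misfit at the optimum
    dof = max(b.size - Ml.shape[1], 1)
    resid = b + Ml @ c_live
    sigma2 = float(resid @ resid) / dof
    H = Ml.T @ Ml + alpha * np.eye(Ml.shape[1])
    ci_reliable = True
    try:
        cond = np.linalg.cond(H)
        if cond > 1e12:
            raise np.linalg.LinAlgError("ill-conditioned Hessian")
        cov = sigma2 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        ci_reliable = False
        ridge = 1e-8 * np.trace(H) / H.shape[0]
        logger.warning("near-singular Hessian; ridge fallback %.3g for CIs",
                       ridge)
        cov = sigma2 * np.linalg.inv(H + ridge * np.eye(H.shape[0]))
    tq = stats.t.ppf(0.975, dof)
    ci_live = tq * np.sqrt(np.clip(np.diag(cov), 0, None))

    currents = np.zeros(ncoil)
    ci = np.zeros(ncoil)
    currents[live] = c_live
    ci[live] = ci_live

    residual = simulate_field(background, responses, currents)
    if sample_positions is not None:
        sp = np.asarray(sample_positions, dtype=float)
        rng = (float(sp.min()), float(sp.max()))
    else:
        rng = None
    rstats = homogeneity_stats(residual, rng)
    return ShimState(currents, ci, alpha, residual_profile=residual,
                     residual_stats=rstats, converged=bool(res.success),
                     ci_reliable=ci_reliable,
                     info={"loss": float(res.fun),
                           "grad_norm": float(np.linalg.norm(jac(c_live)))})


# ---------------------------------------------------------------------------
# Iterative fine-tuning
# ---------------------------------------------------------------------------

def iterative_tune(probe, start: ShimState,
                   step_range_mA: tuple[float, float] = (0.1, 0.01),
                   stop_threshold_nT: float = DEFAULT_STOP_NT,
                   max_iter: int = 500) -> ShimState:
    """Coordinate descent on the X, Y, Z offset currents against a probe.

    ``probe(currents_mA) -> (bx, by, bz)`` returns the field vector (nT) at
    the sample center for a 9-current setting.  Per sweep the X, then Y,
    then Z current is stepped by +/-step while this decreases the probed
    ``||B||``; the step shrinks geometrically from ``step_range_mA[0]`` to
    ``step_range_mA[1]``.  Accepted moves never increase the probed
    magnitude.  Terminates when ``||B|| < stop_threshold_nT`` or after
    ``max_iter`` probe evaluations, returning the best state seen with a
    convergence flag.
    """
    step_hi, step_lo = step_range_mA
    if step_hi <= 0 or step_lo <= 0 or step_lo > step_hi:
        raise ValueError("step_range_mA must be (hi, lo) with hi >= lo > 0")
    currents = start.currents_mA.copy()

    def mag(c):
        return float(np.linalg.norm(probe(c)))

    best = mag(currents)
    n_eval = 1
    if best < stop_threshold_nT:
        return ShimState(currents, start.ci95_mA.copy(), start.alpha,
                         converged=True, info={"probe_nT": best, "n_eval": 0})

    step = step_hi
    while n_eval < max_iter and best >= stop_threshold_nT:
        improved = False
        for axis in (0, 1, 2):  # X, Y, Z in canonical coil order
            for sign in (+1.0, -1.0):
                while n_eval < max_iter:
                    trial = currents.copy()
                    trial[axis] += sign * step
                    m = mag(trial)
                    n_eval += 1
                    if m < best:
                        currents, best, improved = trial, m, True
                        if best < stop_threshold_nT:
                            break
                    else:
                        break
                if best < stop_threshold_nT:
                    break
            if best < stop_threshold_nT:
                break
        if best < stop_threshold_nT:
            break
        if not improved:
            if step <= step_lo:
                break
            step = max(step / 2.0, step_lo)
    converged = best < stop_threshold_nT
    return ShimState(currents, start.ci95_mA.copy(), start.alpha,
                     converged=converged,
                     info={"probe_nT": best, "n_eval": n_eval})


# ---------------------------------------------------------------------------
# Z-shim field schedule
# ---------------------------------------------------------------------------

def zshim_schedule(calibration_currents_mA, measured_fields_nT,
                   targets_nT) -> tuple[np.ndarray, float, float]:
    """Currents realizing target fields from a linear Z-shim calibration.

    An ordinary least-squares line (field = slope * current + intercept,
    nominal slope 108 nT/mA) is fitted to the calibration sweep; the
    returned current for a target T is ``(T - intercept)/slope``.

    Returns ``(currents_mA, slope_nT_per_mA, intercept_nT)``.
    """
    c = np.asarray(calibration_currents_mA, dtype=float)
    f = np.asarray(measured_fields_nT, dtype=float)
    if c.size != f.size or c.size < 2:
        raise ValueError("need >= 2 matched calibration points")
    slope, intercept = np.polyfit(c, f, 1)
    scale = max(np.ptp(f), abs(intercept), 1.0)
    if abs(slope) * np.ptp(c) < 1e-12 * scale:
        raise ValueError("zero calibration slope; cannot invert")
    targets = np.asarray(targets_nT, dtype=float)
    return (targets - intercept) / slope, float(slope), float(intercept)
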