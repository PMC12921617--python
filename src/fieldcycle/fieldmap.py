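"""Field profiles, calibration lookup tables and shuttle kinematics.

A magnetic-field-cycling (MFC) shuttle moves an NMR sample along the bore
axis between a mu-metal shield (with an internal solenoid electromagnet, SE)
and the isocenter of the spectrometer's B0 magnet.  Position is expressed in
stepper-motor microsteps: 0 is the outside/homing position, 33 000 usteps is
the B0 isocenter.  This module holds the sampled field profiles B(z), the
lookup tables that invert them (field -> position, field -> SE current), the
homogeneity statistics over a sample range, and the trapezoidal motion
profile that converts a shuttle move into a field-versus-time trace.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

logger = logging.getLogger("fieldcycle")

# ---------------------------------------------------------------------------
# Shuttle geometry constants
# ---------------------------------------------------------------------------

#: Shuttle travel between outside position and B0 isocenter, in microsteps.
USTEPS_FULL_TRAVEL = 33_000

#: Millimetres per microstep.  The drive is specified by 1747.2 mm/s at
#: 48 000 usteps/s, i.e. exactly 1747.2/48000 = 0.0364 mm per microstep.
MM_PER_USTEP = 1747.2 / 48000.0

#: Default shuttle kinematics: downward acceleration and maximum velocity.
DEFAULT_ACCEL_MM_S2 = 6552.0
DEFAULT_VMAX_MM_S = 1747.2

#: Axial position (percent of full travel) of the SE sweet spot where the
#: field-to-current calibration is taken.
SE_SWEET_SPOT_PERCENT = 3.34

#: Axial position (percent) of the shimmed sample center inside the shield.
Z_SAMPLE_PERCENT = 5.35

#: Regime boundaries for field setting (in tesla).
ZSHIM_MAX_T = 3.16e-6      # z-shim offsets reach about 3.16 uT
ZSHIM_FLOOR_T = 6.2e-9     # below ~6.2 nT the field counts as shimmed zero
SOLENOID_MAX_T = 12e-3     # above 12 mT the stray field of B0 is used


def microsteps_to_mm(n) -> float | np.ndarray:
    """Convert a microstep count to millimetres (0.0364 mm per microstep)."""
    arr = np.asarray(n, dtype=float)
    if np.any(arr < 0):
        raise ValueError("microstep count must be non-negative")
    out = arr * MM_PER_USTEP
    return float(out) if np.isscalar(n) or out.ndim == 0 else out


def mm_to_microsteps(mm) -> float | np.ndarray:
    """Inverse of :func:`microsteps_to_mm` (returns fractional microsteps)."""
    arr = np.asarray(mm, dtype=float)
    if np.any(arr < 0):
        raise ValueError("length must be non-negative")
    out = arr / MM_PER_USTEP
    return float(out) if np.isscalar(mm) or out.ndim == 0 else out


# ---------------------------------------------------------------------------
# FieldProfile
# ---------------------------------------------------------------------------

@dataclass
class FieldProfile:
    """Sampled 3-component magnetic field along the shuttle axis.

    Parameters
    ----------
    position_usteps : array
        Axial sample positions in microsteps, strictly increasing.
    bx_nT, by_nT, bz_nT : array
        Field components in nanotesla.  Components keep their sign
        (negative SE currents flip the field orientation); all magnitude
        statistics use ``|B|``.
    """

    position_usteps: np.ndarray
    bx_nT: np.ndarray
    by_nT: np.ndarray
    bz_nT: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.position_usteps = np.asarray(self.position_usteps, dtype=float)
        self.bx_nT = np.asarray(self.bx_nT, dtype=float)
        self.by_nT = np.asarray(self.by_nT, dtype=float)
        self.bz_nT = np.asarray(self.bz_nT, dtype=float)
        n = self.position_usteps.size
        if not (self.bx_nT.size == self.by_nT.size == self.bz_nT.size == n):
            raise ValueError("component arrays must share the position grid")
        if n >= 2 and not np.all(np.diff(self.position_usteps) > 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.all(np.isfinite(self.bx_nT)) and np.all(np.isfinite(self.by_nT))
                and np.all(np.isfinite(self.bz_nT))):
            raise ValueError("field components must be finite")

    @property
    def magnitude_nT(self) -> np.ndarray:
        return np.sqrt(self.bx_nT**2 + self.by_nT**2 + self.bz_nT**2)

    @property
    def percent(self) -> np.ndarray:
        return self.position_usteps / USTEPS_FULL_TRAVEL * 100.0

    @property
    def position_mm(self) -> np.ndarray:
        return self.position_usteps * MM_PER_USTEP

    def __len__(self) -> int:
        return self.position_usteps.size

    # -- interpolation ------------------------------------------------------

    def component_spline(self, component: str) -> CubicSpline:
        """Cubic spline of one component (``'bx' | 'by' | 'bz'``) vs usteps."""
        data = {"bx": self.bx_nT, "by": self.by_nT, "bz": self.bz_nT}[component]
        return CubicSpline(self.position_usteps, data)

    def interp_magnitude(self, usteps) -> np.ndarray:
        """Field magnitude at arbitrary positions inside the sampled grid.

        Components are splined individually and recombined; querying outside
        the grid is an error (extrapolating a stray field is unsafe).
        """
        q = np.asarray(usteps, dtype=float)
        lo, hi = self.position_usteps[0], self.position_usteps[-1]
        if np.any(q < lo - 1e-9) or np.any(q > hi + 1e-9):
            raise ValueError("query position outside the calibrated grid")
        q = np.clip(q, lo, hi)
        bx = self.component_spline("bx")(q)
        by = self.component_spline("by")(q)
        bz = self.component_spline("bz")(q)
        return np.sqrt(bx**2 + by**2 + bz**2)

    def resample(self, grid: np.ndarray) -> "FieldProfile":
        """Cubic-spline resample of all components onto ``grid`` (usteps)."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.position_usteps[0], self.position_usteps[-1]
        if grid[0] < lo - 1e-9 or grid[-1] > hi + 1e-9:
            raise ValueError("resampling grid exceeds the measured extent")
        return FieldProfile(
            grid,
            self.component_spline("bx")(grid),
            self.component_spline("by")(grid),
            self.component_spline("bz")(grid),
            label=self.label,
        )

    # -- CSV dialect --------------------------------------------------------

    @classmethod
    def from_csv(cls, path, label: str = "") -> "FieldProfile":
        """Read ``position_usteps,bx_nT,by_nT,bz_nT`` CSV (header required)."""
        df = pd.read_csv(path)
        required = ["position_usteps", "bx_nT", "by_nT", "bz_nT"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"field-profile CSV missing columns: {missing}")
        return cls(df["position_usteps"].to_numpy(), df["bx_nT"].to_numpy(),
                   df["by_nT"].to_numpy(), df["bz_nT"].to_numpy(), label=label)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "position_usteps": self.position_usteps,
            "bx_nT": self.bx_nT, "by_nT": self.by_nT, "bz_nT": self.bz_nT,
        }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Homogeneity statistics
# ---------------------------------------------------------------------------

@dataclass
class HomogeneityStats:
    """Magnitude statistics of a field profile over a sample range."""

    mean: float
    median: float
    sd: float
    rel_sd: float              # sd / median, in percent
    median_mean_dev: float     # |median - mean| / mean, in percent
    n: int

    def __str__(self) -> str:
        return (f"({self.mean:.1f} ± {self.sd:.1f}) nT over {self.n} points "
                f"(rel SD {self.rel_sd:.1f}%)")


def homogeneity_stats(profile: FieldProfile,
                      sample_range: tuple[float, float] | None = None
                      ) -> HomogeneityStats:
    """Mean/median/SD of ``|B|`` over a microstep interval.

    ``rel_sd`` is SD over median (percent), the figure of merit used for the
    sample-range homogeneity; ``median_mean_dev`` quantifies the mismatch
    between the set field (sample center) and the mean experienced field.
    """
    mag = profile.magnitude_nT
    if sample_range is not None:
        lo, hi = sample_range
        if hi < lo:
            raise ValueError("sample_range must be (lo, hi) with lo <= hi")
        mask = (profile.position_usteps >= lo) & (profile.position_usteps <= hi)
        mag = mag[mask]
    if mag.size < 3:
        raise ValueError("need at least 3 samples inside the range")
    mean = float(np.mean(mag))
    median = float(np.median(mag))
    sd = float(np.std(mag, ddof=0))
    rel_sd = sd / median * 100.0 if median != 0 else 0.0
    dev = abs(median - mean) / mean * 100.0 if mean != 0 else 0.0
    return HomogeneityStats(mean, median, sd, rel_sd, dev, int(mag.size))


# ---------------------------------------------------------------------------
# Lookup tables
# ---------------------------------------------------------------------------

def _longest_strictly_monotone_run(y: np.ndarray) -> tuple[int, int]:
    """Index range [i, j] (inclusive) of the longest strictly monotone run."""
    d = np.sign(np.diff(y))
    best = (0, 0)
    start = 0
    for i in range(1, d.size):
        if d[i] == 0 or d[i] != d[i - 1] or d[i - 1] == 0:
            if d[i - 1] != 0 and (i - start) > (best[1] - best[0]):
                best = (start, i)
            start = i
    if d.size and d[-1] != 0 and (d.size - start) > (best[1] - best[0]):
        best = (start, d.size)
    return best


@dataclass
class LookupTable:
    """Invertible piecewise-linear calibration map restricted to its
    monotone valid range; queries outside the range are rejected."""

    kind: str  # field_to_position | field_to_current | zshim_field_to_current
    abscissa: np.ndarray  # field values
    ordinate: np.ndarray  # position (usteps) or current (A or mA)
    valid_range: tuple[float, float] = (np.nan, np.nan)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.ordinate = np.asarray(self.ordinate, dtype=float)
        if self.abscissa.size != self.ordinate.size:
            raise ValueError("abscissa and ordinate must have equal length")
        if self.abscissa.size < 2:
            raise ValueError("a lookup table needs at least 2 points")
        if not np.all(np.diff(self.abscissa) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(np.isnan(self.valid_range)):
            self.valid_range = (float(self.abscissa[0]), float(self.abscissa[-1]))

    def query(self, value) -> float | np.ndarray:
        """Interpolate ordinate at a field value inside the valid range."""
        q = np.asarray(value, dtype=float)
        lo, hi = self.valid_range
        if np.any(q < lo - 1e-12 * max(abs(lo), 1.0)) or \
           np.any(q > hi + 1e-12 * max(abs(hi), 1.0)):
            raise ValueError(
                f"query {value!r} outside calibrated range [{lo:g}, {hi:g}]; "
                "extrapolation is not permitted")
        out = np.interp(q, self.abscissa, self.ordinate)
        return float(out) if out.ndim == 0 else out

    # -- JSON dialect -------------------------------------------------------

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "kind": self.kind,
                "abscissa": self.abscissa.tolist(),
                "ordinate": self.ordinate.tolist(),
                "valid_range": list(self.valid_range),
                "metadata": self.metadata,
            }, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "LookupTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["kind"], np.asarray(d["abscissa"]), np.asarray(d["ordinate"]),
                   tuple(d["valid_range"]), d.get("metadata", {}))


def build_field_to_position_table(profiles, currents=None) -> LookupTable:
    """Invert a stray-field profile into a field -> position table.

    The field along the shuttle path is only invertible on its strictly
    monotone sub-range (the stray-field rise between shield and isocenter);
    a plateau near the isocenter or wiggles near the shield are excluded.
    With several profiles (one per SE current) the zero-current — or first —
    profile defines the table and the rest are kept as metadata.

    Parameters
    ----------
    profiles : FieldProfile or list of FieldProfile
    currents : list of float, optional
        SE current (A) per profile, used to pick the reference profile
        (closest to 0 A).
    """
    if isinstance(profiles, FieldProfile):
        profiles = [profiles]
    if not profiles:
        raise ValueError("need at least one field profile")
    if currents is not None:
        if len(currents) != len(profiles):
            raise ValueError("one current per profile required")
        ref = int(np.argmin(np.abs(np.asarray(currents, dtype=float))))
    else:
        ref = 0
    prof = profiles[ref]
    mag = prof.magnitude_nT
    pos = prof.position_usteps
    i, j = _longest_strictly_monotone_run(mag)
    if (i, j) != (0, mag.size - 1):
        warnings.warn(
            "field profile not monotone over its full range; lookup table "
            f"restricted to usteps [{pos[i]:.0f}, {pos[j]:.0f}]",
            stacklevel=2)
    mag, pos = mag[i:j + 1], pos[i:j + 1]
    if mag[0] > mag[-1]:  # store with increasing field
        mag, pos = mag[::-1], pos[::-1]
    meta = {"units": {"abscissa": "nT", "ordinate": "usteps"},
            "n_profiles": len(profiles)}
    if currents is not None:
        meta["reference_current_A"] = float(currents[ref])
    return LookupTable("field_to_position", mag, pos, metadata=meta)


def build_field_to_current_table(fields_mT, currents_A) -> LookupTable:
    """Field -> SE-current table from a fixed-position current sweep.

    Stores the piecewise-linear inverse and reports the fitted linear slope
    (mT/A) as metadata (the SE measures ~7.1 mT/A).
    """
    f = np.asarray(fields_mT, dtype=float)
    c = np.asarray(currents_A, dtype=float)
    if f.size != c.size or f.size < 2:
        raise ValueError("need >= 2 matched calibration points")
    if np.any(np.diff(c) <= 0):
        raise ValueError("currents must be strictly increasing (no duplicates)")
    slope, intercept = np.polyfit(c, f, 1)
    order = np.argsort(f)
    f, c = f[order], c[order]
    if np.any(np.diff(f) <= 0):
        raise ValueError("field must be strictly monotone in current")
    return LookupTable(
        "field_to_current", f, c,
        metadata={"slope_mT_per_A": float(slope),
                  "intercept_mT": float(intercept),
                  "units": {"abscissa": "mT", "ordinate": "A"}})


# ---------------------------------------------------------------------------
# Field-setting plan
# ---------------------------------------------------------------------------

@dataclass
class FieldPlan:
    """Actuator settings that realize a target field.

    Exactly one actuator is non-default per regime: the z-shim offset in the
    zshim regime, the SE current in the solenoid regime, the shuttle
    position in the stray regime.
    """

    regime: str               # zshim | solenoid | stray
    position_usteps: float
    se_current_A: float = 0.0
    zshim_offset_mA: float = 0.0


def plan_field_setting(target_T: float,
                       current_table: LookupTable | None = None,
                       position_table: LookupTable | None = None,
                       zshim_slope_nT_per_mA: float = 108.0) -> FieldPlan:
    """Choose the actuator regime for a target field magnitude.

    * ``|target| <= 3.16 uT`` — z-shim coil offset at the shimmed sample
      position (fields below the 6.2 nT floor count as shimmed zero);
    * ``3.16 uT < target <= 12 mT`` — SE current with the shuttle parked at
      the 3.34% sweet spot;
    * ``target > 12 mT`` — shuttle into the B0 stray field.
    """
    if target_T < 0:
        raise ValueError("target field must be non-negative (magnitude)")
    if target_T <= ZSHIM_MAX_T:
        offset = 0.0 if target_T < ZSHIM_FLOOR_T else \
            target_T * 1e9 / zshim_slope_nT_per_mA
        return FieldPlan("zshim",
                         position_usteps=Z_SAMPLE_PERCENT / 100 * USTEPS_FULL_TRAVEL,
                         zshim_offset_mA=offset)
    if target_T <= SOLENOID_MAX_T:
        if current_table is None:
            raise ValueError("solenoid regime requires a field-to-current table")
        current = current_table.query(target_T * 1e3)  # table in mT
        return FieldPlan("solenoid",
                         position_usteps=SE_SWEET_SPOT_PERCENT / 100 * USTEPS_FULL_TRAVEL,
                         se_current_A=float(current))
    if position_table is None:
        raise ValueError("stray regime requires a field-to-position table")
    pos = position_table.query(target_T * 1e9)  # table in nT
    return FieldPlan("stray", position_usteps=float(pos))


# ---------------------------------------------------------------------------
# Shuttle kinematics
# ---------------------------------------------------------------------------

@dataclass
class MotionProfile:
    """Trapezoidal (or triangular) velocity profile of a shuttle move."""

    distance_mm: float
    accel_mm_s2: float
    vmax_mm_s: float
    t_ramp: float     # ramp-up duration (== ramp-down)
    t_cruise: float
    total_time: float
    v_peak: float

    @property
    def is_triangular(self) -> bool:
        return self.t_cruise == 0.0

    def position(self, t) -> np.ndarray:
        """Distance travelled at time t (piecewise quadratic), clamped."""
        t = np.asarray(t, dtype=float)
        a, vp = self.accel_mm_s2, self.v_peak
        t1, t2 = self.t_ramp, self.t_ramp + self.t_cruise
        d_ramp = 0.5 * a * self.t_ramp**2
        out = np.where(
            t <= t1, 0.5 * a * np.clip(t, 0, None)**2,
            np.where(
                t <= t2, d_ramp + vp * (t - t1),
                d_ramp + vp * self.t_cruise
                + vp * np.clip(t - t2, 0, self.t_ramp)
                - 0.5 * a * np.clip(t - t2, 0, self.t_ramp)**2))
        return np.minimum(out, self.distance_mm)

    def velocity(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        a, vp = self.accel_mm_s2, self.v_peak
        t1, t2 = self.t_ramp, self.t_ramp + self.t_cruise
        up = a * np.clip(t, 0, t1)
        down = vp - a * np.clip(t - t2, 0, self.t_ramp)
        return np.where(t <= t1, up, np.where(t <= t2, vp, np.clip(down, 0, None)))


def motion_profile(distance_mm: float,
                   accel_mm_s2: float = DEFAULT_ACCEL_MM_S2,
                   vmax_mm_s: float = DEFAULT_VMAX_MM_S) -> MotionProfile:
    """Closed-form trapezoidal motion plan.

    The profile is triangular (never reaches ``vmax``) when
    ``distance < vmax^2/accel``; otherwise it ramps to ``vmax``, cruises and
    ramps down, with total time ``2 vmax/a + (d - vmax^2/a)/vmax``.  This is
    the idealized kinematic profile; measured shuttle times additionally
    include drive overhead and friction.
    """
    if distance_mm < 0:
        raise ValueError("distance must be non-negative")
    if accel_mm_s2 <= 0 or vmax_mm_s <= 0:
        raise ValueError("accel and vmax must be positive")
    if distance_mm == 0:
        return MotionProfile(0.0, accel_mm_s2, vmax_mm_s, 0.0, 0.0, 0.0, 0.0)
    d_crit = vmax_mm_s**2 / accel_mm_s2
    if distance_mm < d_crit:
        v_peak = math.sqrt(distance_mm * accel_mm_s2)
        t_ramp = v_peak / accel_mm_s2
        t_cruise = 0.0
    else:
        v_peak = vmax_mm_s
        t_ramp = vmax_mm_s / accel_mm_s2
        t_cruise = (distance_mm - d_crit) / vmax_mm_s
    return MotionProfile(distance_mm, accel_mm_s2, vmax_mm_s,
                         t_ramp, t_cruise, 2 * t_ramp + t_cruise, v_peak)


def field_during_motion(motion: MotionProfile,
                        field_vs_position: FieldProfile,
                        dt: float,
                        start_usteps: float = 0.0,
                        direction: int = +1):
    """Compose position(t) with the interpolated field profile.

    Returns a :class:`fieldcycle.transfer.TransferProfile` sampled at step
    ``dt`` (endpoint included), with the field in tesla.  ``direction`` is
    +1 for motion toward larger microstep positions.
    """
    from .transfer import TransferProfile  # local import avoids a cycle

    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, motion.total_time, dt)
    if t.size == 0 or t[-1] < motion.total_time:
        t = np.append(t, motion.total_time)
    pos_mm = motion.position(t)
    pos_usteps = start_usteps + direction * pos_mm / MM_PER_USTEP
    mag_nT = field_vs_position.interp_magnitude(pos_usteps)
    # endpoints match the profile exactly at the start/end positions
    mag_nT[0] = field_vs_position.interp_magnitude(start_usteps)
    mag_nT[-1] = field_vs_position.interp_magnitude(pos_usteps[-1])
    return TransferProfile(times_s=t, fields_T=mag_nT * 1e-9,
                           label="shuttle")
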