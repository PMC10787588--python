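"""Domain types shared by every pipeline stage.

Units are SI throughout (metres, seconds, m/s); display layers convert to
mm/s.  All records validate their invariants on construction and raise
``ValueError`` naming the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = [
    "AcquisitionParams",
    "DopplerConfig",
    "GroundTruth",
    "ScanSet",
    "SurfaceProfile",
    "VelocityMap",
]

_SCAN_MODES = ("stationary", "rotational")
_CONVENTIONS = ("round_trip", "one_way")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass
class AcquisitionParams:
    """Acquisition geometry and timing of the rotational PA/US probe.

    Parameters
    ----------
    c : float
        Speed of sound in the coupling medium, m/s.
    fprf : float
        Laser / A-line pulse repetition frequency, Hz.
    fs : float
        RF digitisation rate, Hz.
    lines_per_rev : int
        A-lines acquired per full probe rotation.
    dphi : float
        Angular step between adjacent A-lines, degrees.
    probe_offset : float
        Distance from the transducer surface to the rotation axis, m.
    pa_us_delay : float
        Delay between the PA excitation and the US pulse of a pair, s.
    scan_mode : {"stationary", "rotational"}
    propagation_convention : {"round_trip", "one_way"}
        How an arrival sample maps to depth.  ``round_trip`` uses c/2
        (pulse-echo); ``one_way`` uses c.
    """

    c: float = 1540.0
    fprf: float = 1000.0
    fs: float = 180e6
    lines_per_rev: int = 1000
    dphi: float = 0.36
    probe_offset: float = 5.57e-3
    pa_us_delay: float = 16.3e-6
    scan_mode: str = "stationary"
    propagation_convention: str = "round_trip"

    def __post_init__(self) -> None:
        for name in ("c", "fprf", "fs", "dphi", "probe_offset", "pa_us_delay"):
            _require(float(getattr(self, name)) > 0.0, f"{name} must be > 0")
        _require(int(self.lines_per_rev) >= 1, "lines_per_rev must be >= 1")
        _require(
            abs(self.dphi * self.lines_per_rev - 360.0) <= 1e-9,
            "dphi * lines_per_rev must equal 360 degrees "
            f"(got {self.dphi * self.lines_per_rev!r})",
        )
        _require(self.scan_mode in _SCAN_MODES, f"scan_mode must be one of {_SCAN_MODES}")
        _require(
            self.propagation_convention in _CONVENTIONS,
            f"propagation_convention must be one of {_CONVENTIONS}",
        )

    # -- depth/radius mapping -------------------------------------------------
    @property
    def depth_per_sample(self) -> float:
        """Depth increment of one original sample, m."""
        factor = 0.5 if self.propagation_convention == "round_trip" else 1.0
        return factor * self.c / self.fs

    def depth_of_sample(self, k) -> np.ndarray | float:
        """Depth below the transducer surface of sample index ``k`` (m)."""
        return np.asarray(k, dtype=float) * self.depth_per_sample

    def sample_of_depth(self, z) -> np.ndarray | float:
        """Fractional sample index at depth ``z`` metres."""
        return np.asarray(z, dtype=float) / self.depth_per_sample

    def radius_of_sample(self, k) -> np.ndarray | float:
        """Distance from the rotation axis for sample ``k`` (m)."""
        return self.probe_offset + self.depth_of_sample(k)


@dataclass
class DopplerConfig:
    """Every tunable constant of the correlational Doppler processing chain.

    Defaults are the processing constants of the flowmetry method: 3–30 MHz
    FIR passband, x3 axial interpolation, 25-point correlation window,
    10 dB rising-edge threshold, 70 deg compensation cap, 100-line ROI
    averaging and 20 report sectors.
    """

    passband: tuple[float, float] = (3e6, 30e6)
    nres: int = 3
    window_len: int = 25
    max_lag: int = 15
    rho_min: float = 0.7
    noise_factor: float = 3.0
    angle_cap: float = 70.0
    subsample_refine: bool = False
    toa_threshold_db: float = 10.0
    roi_lines: int = 100
    n_regions: int = 20
    window_hop: int = 12

    def __post_init__(self) -> None:
        lo, hi = self.passband
        _require(0.0 < lo < hi, "passband must satisfy 0 < low < high")
        _require(int(self.nres) >= 1, "nres must be >= 1")
        _require(int(self.window_len) > 0 and self.window_len % 2 == 1,
                 "window_len must be a positive odd integer")
        _require(0 < int(self.max_lag) < self.window_len,
                 "max_lag must satisfy 0 < max_lag < window_len")
        _require(0.0 <= self.rho_min <= 1.0, "rho_min must lie in [0, 1]")
        _require(self.noise_factor >= 0.0, "noise_factor must be >= 0")
        _require(0.0 < self.angle_cap < 90.0, "angle_cap must lie in (0, 90)")
        _require(self.toa_threshold_db > 0.0, "toa_threshold_db must be > 0")
        _require(int(self.roi_lines) >= 1, "roi_lines must be >= 1")
        _require(int(self.n_regions) >= 1, "n_regions must be >= 1")
        _require(int(self.window_hop) >= 1, "window_hop must be >= 1")

    def validate_against(self, params: AcquisitionParams) -> None:
        """Check constraints that couple config and acquisition."""
        _require(self.passband[1] < params.fs / 2,
                 "passband high edge must be below fs/2")


@dataclass
class GroundTruth:
    """Simulator truth attached to a synthetic scan.

    ``true_axial_velocity`` and ``true_speed`` are per (sample, line) and
    zero outside flow regions; positive axial velocity means motion toward
    the transducer.  ``flow_angle`` (deg) and ``surface_arrival`` (fractional
    samples) are per line.
    """

    true_axial_velocity: np.ndarray
    true_speed: np.ndarray
    flow_angle: np.ndarray
    surface_arrival: np.ndarray

    def __post_init__(self) -> None:
        _require(self.true_axial_velocity.shape == self.true_speed.shape,
                 "true_axial_velocity and true_speed shapes must match")
        n_lines = self.true_axial_velocity.shape[1]
        _require(self.flow_angle.shape == (n_lines,),
                 "flow_angle must be one value per line")
        _require(self.surface_arrival.shape == (n_lines,),
                 "surface_arrival must be one value per line")


@dataclass
class ScanSet:
    """Paired PA/US RF frames plus acquisition metadata.

    ``pa`` and ``us`` are (n_samples, n_lines) float arrays of identical
    shape; ``meta`` carries free-form provenance (seed, generator version).
    """

    pa: np.ndarray
    us: np.ndarray
    params: AcquisitionParams
    meta: dict = field(default_factory=dict)
    ground_truth: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        self.pa = np.asarray(self.pa, dtype=float)
        self.us = np.asarray(self.us, dtype=float)
        _require(self.pa.ndim == 2, "pa must be 2-D (samples x lines)")
        _require(self.pa.shape == self.us.shape, "pa and us shapes must be identical")
        _require(self.pa.shape[1] >= 2, "a scan needs at least 2 A-lines")
        _require(bool(np.isfinite(self.pa).all()), "pa contains non-finite values")
        _require(bool(np.isfinite(self.us).all()), "us contains non-finite values")
        if self.ground_truth is not None:
            _require(self.ground_truth.true_axial_velocity.shape == self.pa.shape,
                     "ground_truth shape inconsistent with scan")

    @property
    def n_samples(self) -> int:
        return self.pa.shape[0]

    @property
    def n_lines(self) -> int:
        return self.pa.shape[1]


@dataclass
class VelocityMap:
    """Per-window correlation output and derived velocities.

    Arrays are (n_window_rows, n_line_pairs).  ``pshift`` is the lag in
    interpolated samples (integer dtype unless sub-sample refinement was
    on), ``rho`` the normalized correlation at that lag, ``vc`` the axial
    velocity (m/s), ``v`` the angle-compensated velocity (present after
    compensation).  ``window_centers`` holds window centre coordinates in
    interpolated samples; it becomes 2-D after back-shifting.
    """

    pshift: np.ndarray
    rho: np.ndarray
    valid: np.ndarray
    window_centers: np.ndarray
    nres: int = 1
    vc: Optional[np.ndarray] = None
    v: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        _require(self.pshift.shape == self.rho.shape == self.valid.shape,
                 "pshift, rho and valid must share a shape")

    @property
    def n_pairs(self) -> int:
        return self.pshift.shape[1]

    def copy(self) -> "VelocityMap":
        return VelocityMap(
            pshift=self.pshift.copy(),
            rho=self.rho.copy(),
            valid=self.valid.copy(),
            window_centers=self.window_centers.copy(),
            nres=self.nres,
            vc=None if self.vc is None else self.vc.copy(),
            v=None if self.v is None else self.v.copy(),
        )


@dataclass
class SurfaceProfile:
    """Per-line water–tissue interface arrival and derived geometry.

    ``arrival`` is the time-of-arrival sample index Li per line (fractional
    samples allowed), ``valid`` flags lines with a detected crossing,
    ``interpolated`` flags lines filled by outlier rejection, ``shifts``
    records integer alignment shifts, ``theta`` the capped per-line
    beam-to-flow angle (deg) and ``theta_raw`` the uncapped chord angle.
    """

    arrival: np.ndarray
    valid: np.ndarray
    shifts: Optional[np.ndarray] = None
    theta: Optional[np.ndarray] = None
    theta_raw: Optional[np.ndarray] = None
    interpolated: Optional[np.ndarray] = None
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        _require(self.arrival.shape == self.valid.shape,
                 "arrival and valid must share a shape")

    @property
    def n_lines(self) -> int:
        return self.arrival.shape[0]

    def copy(self) -> "SurfaceProfile":
        return SurfaceProfile(
            arrival=self.arrival.copy(),
            valid=self.valid.copy(),
            shifts=None if self.shifts is None else self.shifts.copy(),
            theta=None if self.theta is None else self.theta.copy(),
            theta_raw=None if self.theta_raw is None else self.theta_raw.copy(),
            interpolated=None if self.interpolated is None else self.interpolated.copy(),
            warning=self.warning,
        )


def with_updates(obj, **changes):
    """dataclasses.replace that re-runs validation."""
    return replace(obj, **changes)
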