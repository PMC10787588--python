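"""Synthetic PA/US flow-phantom scans with ground truth.

Stand-in for the physical phantoms: a linear tube imaged with a stationary
beam, a spiral tube imaged by a rotating probe, and a lumen-like surface
with a superficial flow layer.  Absorbers are ideal points convolved with
a Gaussian-enveloped transducer pulse; the beam is a line.  The model is
kinematic, not acoustic: pulses are placed at the exact (sub-sample)
arrival times implied by the active propagation convention, which makes
every downstream shift estimate checkable against the recorded truth.

Scatterers inside a tube live on a 1-D pattern along the beam chord
through the bore and are advected by the flow's axial component each PRF
interval, wrapping periodically so adjacent lines are (locally) shifted
copies of one another.  For rotational scans the pattern is shared across
lines: migration of the beam's footprint along the tube between adjacent
lines is neglected, standing in for the finite lateral beam width of a
real focused transducer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .types import AcquisitionParams, GroundTruth, ScanSet, _require

__all__ = [
    "PhantomSpec",
    "make_pulse",
    "pulse_half_duration",
    "simulate_stationary_sequence",
    "simulate_rotational_scan",
    "spiral_flow_angle",
]

_KINDS = ("linear_tube", "spiral", "lumen")

# envelope truncation: keep the pulse out to -60 dB of peak amplitude
_TPR_DB = -60.0


def _gauss_coeff(fc: float, frac_bw: float, bwr_db: float = -6.0) -> float:
    """Gaussian envelope coefficient a in exp(-a t^2) for the given
    fractional bandwidth measured ``bwr_db`` down the amplitude spectrum."""
    ref = 10.0 ** (bwr_db / 20.0)
    return -((np.pi * fc * frac_bw) ** 2) / (4.0 * np.log(ref))


def pulse_waveform(t: np.ndarray, fc: float, frac_bw: float) -> np.ndarray:
    """Gaussian-enveloped cosine evaluated at times ``t`` (s); unit peak."""
    a = _gauss_coeff(fc, frac_bw)
    t = np.asarray(t, dtype=float)
    return np.exp(-a * t * t) * np.cos(2.0 * np.pi * fc * t)


def pulse_half_duration(fc: float, frac_bw: float) -> float:
    """Half-duration (s) at which the envelope falls to the -60 dB floor."""
    a = _gauss_coeff(fc, frac_bw)
    ref = 10.0 ** (_TPR_DB / 20.0)
    return math.sqrt(-math.log(ref) / a)


def make_pulse(fc: float, frac_bw: float, fs: float) -> np.ndarray:
    """Sampled transducer pulse: Gaussian-enveloped cosine, odd length,
    centred, unit peak amplitude.

    ``frac_bw`` is the -6 dB spectral full width divided by ``fc`` (1.15
    for the 15 MHz probe emulated here).
    """
    if not 0 < fc < fs / 2:
        raise ValueError(f"fc={fc:g} must lie in (0, fs/2) to avoid aliasing")
    half = pulse_half_duration(fc, frac_bw)
    k = max(1, int(math.ceil(half * fs)))
    t = np.arange(-k, k + 1) / fs
    return pulse_waveform(t, fc, frac_bw)


@dataclass
class PhantomSpec:
    """Geometry, flow, noise and pulse parameters for a synthetic phantom.

    Key fields
    ----------
    kind : {"linear_tube", "spiral", "lumen"}
    tube_inner_diameter : float
        Bore of the flow tubing, m (580 um PTFE emulated by default).
    flow_speed : float
        Flow speed along the tube, m/s.
    beam_to_flow_angle : float
        Linear tube: angle between the A-line and the tube bore, deg.
    spiral_pitch, probe_tilt : float
        Spiral: helix advance per turn (m; default 2*pi*R, i.e. 45 deg
        pitch angle) and probe tilt (deg).  Together they set the constant
        effective beam-to-flow angle (see :func:`spiral_flow_angle`).
    lumen_radius_fn : callable
        Lumen: maps azimuth (deg) -> surface radius from the rotation
        axis (m); may return an array for an array input.
    snr_db : float
        Additive white Gaussian noise level relative to the RMS RF signal
        inside the flow region; ``None`` or ``inf`` disables noise.
    seed : int
        Mandatory for any stochastic generation.
    """

    kind: str
    seed: int
    tube_inner_diameter: float = 580e-6
    flow_speed: float = 1e-3
    flow_profile: str = "plug"
    beam_to_flow_angle: float = 60.0
    spiral_pitch: Optional[float] = None
    probe_tilt: float = 45.0
    lumen_radius_fn: Optional[Callable] = None
    scatterer_density: float = 80.0          # per mm of tube chord
    pulse_center_freq: float = 15e6
    pulse_frac_bandwidth: float = 1.15
    snr_db: Optional[float] = 20.0
    n_lines: Optional[int] = None
    n_samples: int = 3000
    tube_center_depth: float = 6e-3          # linear tube, below transducer face
    surface_depth: float = 2e-3              # rotational: phantom surface depth
    tube_depth: float = 3.2e-3               # rotational: tube centre depth
    flow_layer_thickness: float = 5e-4       # lumen: flow-layer extent along beam
    wobble_amp: float = 1.7e-5               # rotational surface wobble, m
    wobble_cycles: float = 1.0
    us_echo_rel_amp: float = 10.0            # wall/surface echo vs tube RF RMS

    def __post_init__(self) -> None:
        _require(self.kind in _KINDS, f"kind must be one of {_KINDS}")
        _require(self.seed is not None, "seed is mandatory")
        _require(self.flow_speed >= 0.0, "flow_speed must be >= 0")
        _require(0.0 < self.beam_to_flow_angle < 90.0,
                 "beam_to_flow_angle must lie in (0, 90) degrees")
        _require(self.flow_profile in ("plug", "parabolic"),
                 "flow_profile must be 'plug' or 'parabolic'")
        if self.snr_db is not None:
            _require(math.isfinite(self.snr_db) or self.snr_db == math.inf,
                     "snr_db must be finite or +inf")
        _require(self.n_samples >= 64, "n_samples unreasonably small")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _render_lines(n_samples: int, n_lines: int, centers: np.ndarray,
                  amps: np.ndarray, line_idx: np.ndarray,
                  fc: float, frac_bw: float, fs: float) -> np.ndarray:
    """Accumulate pulses at fractional sample positions.

    ``centers`` (fractional samples), ``amps`` and ``line_idx`` are flat,
    one entry per (scatterer, line) placement.
    """
    frame = np.zeros((n_samples, n_lines))
    k = max(1, int(math.ceil(pulse_half_duration(fc, frac_bw) * fs)))
    base = np.floor(centers).astype(np.int64)
    frac = centers - base
    a = _gauss_coeff(fc, frac_bw)
    two_pi_fc = 2.0 * np.pi * fc
    for d in range(-k, k + 1):
        idx = base + d
        ok = (idx >= 0) & (idx < n_samples)
        if not ok.any():
            continue
        t = (d - frac[ok]) / fs
        w = amps[ok] * np.exp(-a * t * t) * np.cos(two_pi_fc * t)
        np.add.at(frame, (idx[ok], line_idx[ok]), w)
    return frame


def _tube_pattern(rng: np.random.Generator, chord: float, density_per_mm: float):
    n_sc = max(4, int(round(density_per_mm * chord * 1e3)))
    u0 = rng.uniform(0.0, chord, n_sc)
    amps = rng.normal(0.0, 1.0, n_sc)
    return u0, amps


def _signal_rows(params: AcquisitionParams, z_lo: float, z_hi: float,
                 n_samples: int) -> slice:
    k_lo = int(np.clip(np.floor(params.sample_of_depth(z_lo)), 0, n_samples))
    k_hi = int(np.clip(np.ceil(params.sample_of_depth(z_hi)), 0, n_samples))
    return slice(k_lo, k_hi)


def _add_noise(rng: np.random.Generator, pa: np.ndarray, us: np.ndarray,
               signal_rms: float, snr_db: Optional[float], meta: dict) -> None:
    meta["signal_rms"] = float(signal_rms)
    if snr_db is None or snr_db == math.inf or signal_rms == 0.0:
        meta["noise_rms"] = 0.0
        return
    sigma = signal_rms * 10.0 ** (-snr_db / 20.0)
    noise_pa = rng.normal(0.0, sigma, pa.shape)
    noise_us = rng.normal(0.0, sigma, us.shape)
    pa += noise_pa
    us += noise_us
    meta["noise_rms"] = float(np.sqrt(np.mean(noise_pa ** 2)))
    meta["noise_sigma"] = float(sigma)


def _speed_factors(spec: PhantomSpec, u0: np.ndarray, chord: float) -> np.ndarray:
    """Per-scatterer speed multiplier for the chosen flow profile."""
    if spec.flow_profile == "plug":
        return np.ones_like(u0)
    # parabolic: factor from initial transverse position across the bore
    xi = 2.0 * (u0 / chord) - 1.0
    return 1.0 - xi ** 2


# ---------------------------------------------------------------------------
# stationary linear tube
# ---------------------------------------------------------------------------

def simulate_stationary_sequence(spec: PhantomSpec,
                                 params: AcquisitionParams) -> ScanSet:
    """Linear-tube phantom imaged with a stationary beam.

    The beam crosses the 580 um bore at ``beam_to_flow_angle``; point
    absorbers advect along the tube by ``flow_speed / fprf`` per interval,
    so their depth changes by ``flow_speed * cos(angle) / fprf``.  Motion
    toward the transducer is the positive flow direction.  The US channel
    carries strong static tube-wall echoes for surface detection.
    """
    _require(spec.kind == "linear_tube", "spec.kind must be 'linear_tube'")
    _require(params.scan_mode == "stationary", "params.scan_mode must be 'stationary'")
    n_lines = spec.n_lines or 201
    n_samples = spec.n_samples
    theta = math.radians(spec.beam_to_flow_angle)
    chord = spec.tube_inner_diameter / math.sin(theta)
    z_front = spec.tube_center_depth - chord / 2.0
    z_back = spec.tube_center_depth + chord / 2.0

    margin = pulse_half_duration(spec.pulse_center_freq, spec.pulse_frac_bandwidth) \
        * params.fs * params.depth_per_sample
    max_depth = params.depth_of_sample(n_samples - 1)
    if z_front - margin <= 0 or z_back + margin >= max_depth:
        raise ValueError(
            f"tube span [{z_front*1e3:.2f}, {z_back*1e3:.2f}] mm falls outside "
            f"the sampled depth window (0, {max_depth*1e3:.2f}) mm")

    rng = np.random.default_rng(spec.seed)
    u0, amps = _tube_pattern(rng, chord, spec.scatterer_density)
    factors = _speed_factors(spec, u0, chord)

    v_ax = spec.flow_speed * math.cos(theta)      # m/s toward the transducer
    dz = v_ax / params.fprf                       # depth decrease per interval
    lines = np.arange(n_lines)
    # (n_sc, n_lines) chord coordinate, periodic wrap
    u = (u0[:, None] - factors[:, None] * dz * lines[None, :]) % chord
    z = z_front + u
    centers = (np.asarray(params.sample_of_depth(z))).ravel()
    amps_flat = np.broadcast_to(amps[:, None], u.shape).ravel()
    line_flat = np.broadcast_to(lines[None, :], u.shape).ravel()

    pa = _render_lines(n_samples, n_lines, centers, amps_flat, line_flat,
                       spec.pulse_center_freq, spec.pulse_frac_bandwidth, params.fs)

    rows = _signal_rows(params, z_front, z_back, n_samples)
    signal_rms = float(np.sqrt(np.mean(pa[rows, :] ** 2)))

    # US: static wall echoes at the front and back of the bore
    echo_amp = spec.us_echo_rel_amp * (signal_rms if signal_rms > 0 else 1.0)
    wall_centers = np.asarray(params.sample_of_depth(np.array([z_front, z_back])))
    wc = np.repeat(wall_centers, n_lines)
    wl = np.tile(lines, 2)
    wa = np.full(wc.shape, echo_amp)
    us = _render_lines(n_samples, n_lines, wc, wa, wl,
                       spec.pulse_center_freq, spec.pulse_frac_bandwidth, params.fs)

    meta = {
        "generator": "corrdop.simulate.simulate_stationary_sequence",
        "seed": int(spec.seed),
        "kind": spec.kind,
        "flow_speed": float(spec.flow_speed),
        "beam_to_flow_angle_deg": float(spec.beam_to_flow_angle),
        "true_axial_velocity": float(v_ax),
    }
    _add_noise(rng, pa, us, signal_rms, spec.snr_db, meta)

    tav = np.zeros((n_samples, n_lines))
    tsp = np.zeros((n_samples, n_lines))
    if spec.flow_profile == "plug":
        tav[rows, :] = v_ax
        tsp[rows, :] = spec.flow_speed
    else:
        ks = np.arange(rows.start, rows.stop)
        xi = 2.0 * ((np.asarray(params.depth_of_sample(ks)) - z_front) / chord) - 1.0
        prof = np.clip(1.0 - xi ** 2, 0.0, None)
        tav[rows, :] = (v_ax * prof)[:, None]
        tsp[rows, :] = (spec.flow_speed * prof)[:, None]
    truth = GroundTruth(
        true_axial_velocity=tav,
        true_speed=tsp,
        flow_angle=np.full(n_lines, spec.beam_to_flow_angle),
        surface_arrival=np.full(n_lines, float(params.sample_of_depth(z_front))),
    )
    return ScanSet(pa=pa, us=us, params=params, meta=meta, ground_truth=truth)


# ---------------------------------------------------------------------------
# rotational scans: spiral tube / lumen surface
# ---------------------------------------------------------------------------

def spiral_flow_angle(spec: PhantomSpec, params: AcquisitionParams) -> float:
    """Effective constant beam-to-flow angle of the spiral geometry, deg.

    The helix tangent has no radial component, so the tilted beam
    b = cos(tilt) e_r + sin(tilt) e_z meets the tangent
    T = cos(alpha) e_phi + sin(alpha) e_z at
    cos(theta) = sin(tilt) * sin(alpha), with pitch angle
    alpha = atan(pitch / (2 pi R)); the result is independent of azimuth,
    which is why a single constant-angle correction applies.
    """
    r_cyl = params.probe_offset + spec.tube_depth
    pitch = spec.spiral_pitch if spec.spiral_pitch is not None else 2 * math.pi * r_cyl
    alpha = math.atan2(pitch, 2 * math.pi * r_cyl)
    tilt = math.radians(spec.probe_tilt)
    c = math.sin(tilt) * math.sin(alpha)
    return math.degrees(math.acos(np.clip(c, -1.0, 1.0)))


def simulate_rotational_scan(spec: PhantomSpec,
                             params: AcquisitionParams) -> ScanSet:
    """Rotational B-scan of a spiral tube or a lumen-like surface.

    The beam direction advances by ``dphi`` per line.  A slow sinusoidal
    surface wobble (``wobble_amp`` metres over ``wobble_cycles`` per
    revolution) emulates tissue displacement and exercises the
    time-of-arrival alignment; the flow structures ride on the same
    wobble.  The US channel carries a dominant surface echo well above the
    noise floor, and ``ground_truth.surface_arrival`` records the exact
    interface arrival per line.
    """
    _require(spec.kind in ("spiral", "lumen"), "spec.kind must be 'spiral' or 'lumen'")
    _require(params.scan_mode == "rotational", "params.scan_mode must be 'rotational'")
    n_lines = spec.n_lines or params.lines_per_rev
    n_samples = spec.n_samples
    rng = np.random.default_rng(spec.seed)
    lines = np.arange(n_lines)
    phi_deg = lines * params.dphi

    wobble = spec.wobble_amp * np.sin(
        2.0 * np.pi * spec.wobble_cycles * lines / max(n_lines, 1))

    if spec.kind == "spiral":
        surf_depth = spec.surface_depth + wobble
        theta_eff = spiral_flow_angle(spec, params)
        theta_per_line = np.full(n_lines, theta_eff)
        tube_depth = spec.tube_depth + wobble
        chord = spec.tube_inner_diameter / math.sin(math.radians(theta_eff)) \
            if theta_eff < 89.9 else spec.tube_inner_diameter * 500.0
        v_ax = spec.flow_speed * math.cos(math.radians(theta_eff))
        axial_per_line = np.full(n_lines, v_ax)
    else:
        if spec.lumen_radius_fn is None:
            base = params.probe_offset + spec.surface_depth
            radius = np.full(n_lines, base)
        else:
            radius = np.asarray(spec.lumen_radius_fn(phi_deg), dtype=float)
            if radius.shape != (n_lines,):
                radius = np.broadcast_to(radius, (n_lines,)).astype(float)
        surf_depth = radius - params.probe_offset + wobble
        if np.any(surf_depth <= 0):
            raise ValueError("lumen surface lies inside the probe radius")
        # beam-to-flow angle from the analytic surface tangent:
        # cos(theta) = |dr/dphi| / hypot(dr/dphi, r)
        dphi_rad = math.radians(params.dphi)
        full_circle = n_lines == params.lines_per_rev
        if full_circle:
            drdphi = (np.roll(radius, -1) - np.roll(radius, 1)) / (2 * dphi_rad)
        else:
            drdphi = np.gradient(radius, dphi_rad)
        cos_t = np.abs(drdphi) / np.hypot(drdphi, radius)
        theta_per_line = np.degrees(np.arccos(np.clip(cos_t, -1.0, 1.0)))
        chord = spec.flow_layer_thickness
        axial_per_line = spec.flow_speed * cos_t
        tube_depth = surf_depth + 0.5e-3 + chord / 2.0

    max_depth = params.depth_of_sample(n_samples - 1)
    margin = pulse_half_duration(spec.pulse_center_freq, spec.pulse_frac_bandwidth) \
        * params.fs * params.depth_per_sample
    z_front = tube_depth - chord / 2.0
    z_back = tube_depth + chord / 2.0
    if np.any(z_front - margin <= 0) or np.any(z_back + margin >= max_depth):
        raise ValueError("flow region falls outside the sampled depth window")
    if np.any(surf_depth - margin <= 0):
        raise ValueError("surface falls outside the sampled depth window")

    u0, amps = _tube_pattern(rng, float(chord), spec.scatterer_density)
    factors = _speed_factors(spec, u0, float(chord))
    # cumulative axial advection (allows per-line angle variation)
    offsets = np.concatenate([[0.0], np.cumsum(axial_per_line[:-1] / params.fprf)])
    u = (u0[:, None] - factors[:, None] * offsets[None, :]) % float(chord)
    z = z_front[None, :] + u if np.ndim(z_front) else z_front + u
    centers = np.asarray(params.sample_of_depth(z)).ravel()
    amps_flat = np.broadcast_to(amps[:, None], u.shape).ravel()
    line_flat = np.broadcast_to(lines[None, :], u.shape).ravel()
    pa = _render_lines(n_samples, n_lines, centers, amps_flat, line_flat,
                       spec.pulse_center_freq, spec.pulse_frac_bandwidth, params.fs)

    lo = float(np.min(z_front))
    hi = float(np.max(z_back))
    rows = _signal_rows(params, lo, hi, n_samples)
    signal_rms = float(np.sqrt(np.mean(pa[rows, :] ** 2)))

    echo_amp = spec.us_echo_rel_amp * (signal_rms if signal_rms > 0 else 1.0)
    surf_centers = np.asarray(params.sample_of_depth(surf_depth))
    us = _render_lines(n_samples, n_lines, surf_centers, np.full(n_lines, echo_amp),
                       lines, spec.pulse_center_freq, spec.pulse_frac_bandwidth,
                       params.fs)

    meta = {
        "generator": "corrdop.simulate.simulate_rotational_scan",
        "seed": int(spec.seed),
        "kind": spec.kind,
        "flow_speed": float(spec.flow_speed),
        "flow_angle_deg": float(np.median(theta_per_line)),
    }
    _add_noise(rng, pa, us, signal_rms, spec.snr_db, meta)

    cap_hit = np.mean(theta_per_line >= 70.0)
    if spec.flow_speed > 0 and cap_hit > 0.5:
        warnings.warn(
            f"flow angle >= 70 deg on {cap_hit:.0%} of lines: geometry is "
            "largely uncorrectable", stacklevel=2)

    tav = np.zeros((n_samples, n_lines))
    tsp = np.zeros((n_samples, n_lines))
    k_front = np.asarray(params.sample_of_depth(np.broadcast_to(z_front, (n_lines,))))
    k_back = np.asarray(params.sample_of_depth(np.broadcast_to(z_back, (n_lines,))))
    ks = np.arange(n_samples)[:, None]
    in_flow = (ks >= k_front[None, :]) & (ks <= k_back[None, :])
    tav[in_flow] = np.broadcast_to(axial_per_line[None, :], tav.shape)[in_flow]
    tsp[in_flow] = spec.flow_speed
    truth = GroundTruth(
        true_axial_velocity=tav,
        true_speed=tsp,
        flow_angle=theta_per_line.astype(float),
        surface_arrival=surf_centers.astype(float),
    )
    return ScanSet(pa=pa, us=us, params=params, meta=meta, ground_truth=truth)
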