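"""Surface-referenced geometry: time-of-arrival detection, A-line
alignment, per-line flow-angle estimation and cos-theta compensation.

For a rotating endoscopic probe the water–tissue interface seen by the US
channel defines both a registration reference (tissue moves between
lines) and the local surface tangent.  Flow is assumed parallel to the
surface, so the beam-to-flow angle of line i is the angle between the
A-line direction and the chord joining the surface points of lines i-1
and i placed at polar coordinates (r_{i-1}, 0) and (r_i, dphi).  The
compensation factor 1/cos(theta) diverges toward 90 deg and is capped at
``angle_cap`` (70 deg) to prevent over-compensation.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .preprocess import envelope, noise_floor
from .types import AcquisitionParams, DopplerConfig, SurfaceProfile, VelocityMap

__all__ = [
    "detect_surface",
    "reject_outliers",
    "align_to_surface",
    "backshift",
    "estimate_angles",
    "compensate",
    "to_polar",
]


def detect_surface(us_frame: np.ndarray, params: AcquisitionParams,
                   cfg: DopplerConfig, *, floor: float | None = None,
                   smooth: int = 31) -> SurfaceProfile:
    """Rising-edge time-of-arrival detection on the US channel.

    Per line, the arrival Li is the first sample where the smoothed
    envelope reaches ``toa_threshold_db`` above the noise floor.  The
    envelope is averaged over a trailing window of ``smooth`` samples
    (about one pulse length) so isolated noise peaks cannot trigger a
    crossing and detection never precedes the echo onset.  Lines with no
    crossing are flagged invalid; if more than half the lines are invalid
    a warning is attached to the profile.  For noiseless input (zero
    floor) the threshold falls back to 1e-3 of the frame's peak envelope.
    """
    us_frame = np.asarray(us_frame, dtype=float)
    env = envelope(us_frame)
    if smooth > 1:
        cs = np.cumsum(env, axis=0)
        pad = np.zeros((1,) + cs.shape[1:])
        cs = np.vstack([pad, cs])
        idx = np.arange(env.shape[0])
        lo = np.maximum(idx - smooth + 1, 0)
        env = (cs[idx + 1] - cs[lo]) / (idx - lo + 1)[:, None]
        # no crossing before one full window: a truncated mean is just the
        # raw noisy envelope and false-triggers at the line start
        env[: smooth - 1] = 0.0
    if floor is None:
        floor = noise_floor(us_frame, (0, min(200, us_frame.shape[0])))
    thr = floor * 10.0 ** (cfg.toa_threshold_db / 20.0)
    if thr <= 0.0:
        thr = 1e-3 * float(env.max()) if env.max() > 0 else np.inf
    above = env >= thr
    has = above.any(axis=0)
    arrival = np.where(has, above.argmax(axis=0), np.nan).astype(float)
    valid = has.copy()
    prof = SurfaceProfile(arrival=arrival, valid=valid)
    if valid.size and np.mean(~valid) > 0.5:
        prof.warning = "surface not detected on more than 50% of lines"
        warnings.warn(prof.warning, stacklevel=2)
    return prof


def reject_outliers(profile: SurfaceProfile, params: AcquisitionParams,
                    *, window: int = 15, n_mad: float = 5.0,
                    min_jitter: float = 3.0) -> SurfaceProfile:
    """Sliding-median outlier rejection of the arrival profile.

    A circular median window (wrap for rotational scans, edge-replicated
    otherwise) provides the reference; points deviating by more than
    ``n_mad`` times the median absolute deviation are replaced by the
    local median and flagged ``interpolated``, as are invalid lines.  The
    rejection threshold never drops below ``min_jitter`` samples so that
    detection quantisation on a smooth surface is not treated as outlying
    (the MAD of a noise-free profile is zero).
    """
    if not profile.valid.any():
        raise ValueError("no surface: every line is invalid")
    arr = profile.arrival.copy()
    # fill invalid lines with the global median before filtering
    global_med = float(np.median(arr[profile.valid]))
    arr[~profile.valid] = global_med
    full_rev = (params.scan_mode == "rotational"
                and profile.n_lines == params.lines_per_rev)
    mode = "wrap" if full_rev else "nearest"
    med = ndimage.median_filter(arr, size=window, mode=mode)
    resid = arr - med
    mad = float(np.median(np.abs(resid[profile.valid])))
    tol = max(n_mad * mad, min_jitter)
    bad = (np.abs(resid) > tol) | ~profile.valid
    out = profile.copy()
    out.arrival = np.where(bad, med, arr)
    out.interpolated = bad
    out.valid = np.ones_like(profile.valid)
    return out


def align_to_surface(pa_frame: np.ndarray, profile: SurfaceProfile,
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Shift each A-line by an integer number of samples so every arrival
    sits at the reference (median) arrival; vacated samples are zero
    filled.  Returns ``(aligned_frame, shifts)`` with
    ``shift_i = ref - Li``.
    """
    pa_frame = np.asarray(pa_frame, dtype=float)
    n, m = pa_frame.shape
    if profile.n_lines != m:
        raise ValueError("profile does not match frame line count")
    ref = int(round(float(np.median(profile.arrival[profile.valid]))))
    shifts = (ref - np.round(profile.arrival)).astype(np.int64)
    if np.any(np.abs(shifts) > n // 2):
        raise ValueError("alignment shift exceeds half the line length")
    aligned = np.zeros_like(pa_frame)
    for i in range(m):
        s = int(shifts[i])
        if s == 0:
            aligned[:, i] = pa_frame[:, i]
        elif s > 0:
            aligned[s:, i] = pa_frame[: n - s, i]
        else:
            aligned[: n + s, i] = pa_frame[-s:, i]
    return aligned, shifts


def backshift(vmap: VelocityMap, shifts: np.ndarray) -> VelocityMap:
    """Undo the alignment on window-centre coordinates.

    Centres are in interpolated samples, so the per-line integer shift
    scales by ``nres``.  The result has 2-D ``window_centers`` of shape
    (n_rows, n_pairs); the shift of the first line of each pair is used.
    """
    shifts = np.asarray(shifts, dtype=np.int64)
    out = vmap.copy()
    pair_shift = shifts[: vmap.n_pairs]
    centers = np.atleast_1d(vmap.window_centers)
    if centers.ndim == 1:
        centers = np.broadcast_to(centers[:, None],
                                  (centers.shape[0], vmap.n_pairs)).copy()
    out.window_centers = centers - pair_shift[None, :] * vmap.nres
    return out


def _chord_angles(radii: np.ndarray, dphi_deg: float, circular: bool,
                  ) -> np.ndarray:
    """Unsigned angle (deg) between the A-line direction and the surface
    chord at each line, from adjacent surface points (r_{i-1}, 0) and
    (r_i, dphi)."""
    r = np.asarray(radii, dtype=float)
    m = r.shape[0]
    dphi = np.radians(dphi_deg)
    prev = np.roll(r, 1) if circular else np.concatenate([[r[0]], r[:-1]])
    ax, ay = prev, np.zeros_like(prev)
    bx, by = r * np.cos(dphi), r * np.sin(dphi)
    cx, cy = bx - ax, by - ay
    clen = np.hypot(cx, cy)
    bhat_x, bhat_y = np.cos(dphi), np.sin(dphi)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_t = np.abs(cx * bhat_x + cy * bhat_y) / clen
    theta = np.degrees(np.arccos(np.clip(cos_t, 0.0, 1.0)))
    theta[clen == 0] = np.nan
    if not circular:
        theta[0] = theta[1] if m > 1 else np.nan
    return theta


def estimate_angles(profile: SurfaceProfile, params: AcquisitionParams,
                    cfg: DopplerConfig, *, mode: str = "exact",
                    ) -> SurfaceProfile:
    """Per-line beam-to-flow angle from the surface profile.

    ``mode="exact"`` (default) solves the chord triangle in closed form —
    the law-of-sines identity between adjacent radii without any
    small-angle approximation.  ``mode="recursive"`` runs the approximate
    law-of-sines recursion
    ``sin(theta_i) = r_{i-1} sin(dphi + theta_{i-1}) / r_i``
    seeded with the exact angle of the first line.  Angles are then
    capped at ``cfg.angle_cap``; the uncapped values are kept in
    ``theta_raw``.
    """
    if params.scan_mode != "rotational":
        raise ValueError("angle estimation requires a rotational scan")
    arr = profile.arrival
    if np.any(~np.isfinite(arr)):
        raise ValueError("profile has undetected arrivals; run reject_outliers first")
    radii = np.asarray(params.radius_of_sample(arr))
    circular = profile.n_lines == params.lines_per_rev
    exact = _chord_angles(radii, params.dphi, circular)
    if mode == "exact":
        theta_raw = exact
    elif mode == "recursive":
        theta_raw = np.empty_like(exact)
        theta_raw[0] = exact[0]
        dphi = params.dphi
        for i in range(1, radii.size):
            s = radii[i - 1] * np.sin(np.radians(dphi + theta_raw[i - 1])) / radii[i]
            theta_raw[i] = np.degrees(np.arcsin(np.clip(s, -1.0, 1.0)))
    else:
        raise ValueError("mode must be 'exact' or 'recursive'")
    out = profile.copy()
    out.theta_raw = theta_raw
    out.theta = np.minimum(theta_raw, cfg.angle_cap)
    return out


def compensate(vmap: VelocityMap, angle, cfg: DopplerConfig) -> VelocityMap:
    """Angle-compensate axial velocity: ``v = vc / cos(min(theta, cap))``.

    ``angle`` is either a fixed angle in degrees (linear-phantom mode) or
    a :class:`SurfaceProfile` with ``theta`` filled, in which case the
    angle of the second line of each pair — the vertex the chord angle
    belongs to — is used.
    """
    if vmap.vc is None:
        raise ValueError("run to_velocity before compensate")
    if isinstance(angle, SurfaceProfile):
        if angle.theta is None:
            raise ValueError("profile has no theta; run estimate_angles first")
        m = angle.n_lines
        if vmap.n_pairs == m:          # circular pairing
            theta_pair = angle.theta[(np.arange(m) + 1) % m]
        elif vmap.n_pairs == m - 1:
            theta_pair = angle.theta[1:]
        else:
            raise ValueError("profile line count does not match velocity map pairs")
        theta = np.asarray(theta_pair, dtype=float)[None, :]
    else:
        theta = float(angle)
        if not 0.0 <= theta < 90.0:
            raise ValueError("angle must lie in [0, 90) degrees")
    capped = np.minimum(theta, cfg.angle_cap)
    factor = 1.0 / np.cos(np.radians(capped))
    out = vmap.copy()
    out.v = vmap.vc * factor
    return out


def to_polar(image: np.ndarray, profile, params: AcquisitionParams,
             out_px: int = 512, *, nres: int = 1) -> np.ndarray:
    """Warp a (sample, line) image into a square polar raster.

    Radius of sample k is ``probe_offset + depth(k / nres)`` per the
    active propagation convention; azimuth is ``line * dphi``.  Bilinear
    sampling; pixels outside the sampled annulus are NaN.  ``profile`` is
    accepted for interface symmetry but the warp itself is purely
    geometric.
    """
    image = np.asarray(image, dtype=float)
    n, m = image.shape
    r_in = params.probe_offset
    r_out = float(params.radius_of_sample((n - 1) / nres))
    half = r_out
    px = (np.arange(out_px) + 0.5) / out_px * (2 * half) - half
    X, Y = np.meshgrid(px, -px)  # row 0 at top
    rho = np.hypot(X, Y)
    phi = np.degrees(np.arctan2(Y, X)) % 360.0
    k = np.asarray(params.sample_of_depth(rho - r_in)) * nres
    line = phi / params.dphi
    inside = (rho >= r_in) & (k <= n - 1)
    # wrap azimuth by appending the first line
    img_w = np.concatenate([image, image[:, :1]], axis=1)
    coords = np.vstack([k.ravel(), line.ravel()])
    sampled = ndimage.map_coordinates(np.nan_to_num(img_w), coords, order=1,
                                      mode="nearest")
    nan_w = np.isnan(img_w).astype(float)
    nan_frac = ndimage.map_coordinates(nan_w, coords, order=1, mode="nearest")
    out = sampled.reshape(out_px, out_px)
    out[nan_frac.reshape(out_px, out_px) > 0] = np.nan
    out[~inside] = np.nan
    return out
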