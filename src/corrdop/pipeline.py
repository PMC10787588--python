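"""End-to-end processing: ScanSet in, velocity map and surface out.

Order of operations for a rotational scan mirrors the acquisition
workflow: band-pass the PA RF, detect the US interface arrival, align the
PA lines to it, mask by amplitude, interpolate axially, correlate
adjacent lines, gate by correlation amplitude, convert to velocity and
angle-compensate.  Stationary scans skip alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from . import doppler, geometry, preprocess
from .types import AcquisitionParams, DopplerConfig, ScanSet, SurfaceProfile, VelocityMap

__all__ = ["PipelineResult", "process_scanset", "mean_speed"]


@dataclass
class PipelineResult:
    """Everything a caller may want after processing one scan."""

    vmap: VelocityMap                  # gated, velocity-converted, compensated
    vmap_display: VelocityMap          # back-shifted copy for coregistration
    profile: Optional[SurfaceProfile]  # None for stationary scans
    mask: np.ndarray                   # amplitude mask, original grid
    noise_floor: float
    vres: float
    params: AcquisitionParams
    cfg: DopplerConfig


def process_scanset(scan: ScanSet, cfg: DopplerConfig, *,
                    angle: Union[float, str, None] = None,
                    subsample_refine: Optional[bool] = None,
                    angle_mode: str = "exact") -> PipelineResult:
    """Run the full correlational Doppler chain on one scan.

    Parameters
    ----------
    angle
        ``None``: no compensation beyond axial velocity (v = vc);
        a number: fixed-angle compensation in degrees;
        ``"surface"``: per-line angles estimated from the US surface
        (rotational scans only).
    subsample_refine
        Override ``cfg.subsample_refine`` without mutating the config.
    """
    params = scan.params
    cfg.validate_against(params)
    if subsample_refine is not None and subsample_refine != cfg.subsample_refine:
        cfg = replace(cfg, subsample_refine=subsample_refine)
    rotational = params.scan_mode == "rotational"

    pa_f = preprocess.bandpass(scan.pa, params, cfg)
    # noise floor from the pre-surface region BEFORE alignment: the zero
    # fill introduced by large alignment shifts would bias it low and let
    # band-limited noise through the amplitude mask
    floor = preprocess.noise_floor(pa_f, (0, min(200, pa_f.shape[0])))

    profile = None
    shifts = None
    if rotational:
        profile = geometry.detect_surface(scan.us, params, cfg)
        profile = geometry.reject_outliers(profile, params)
        pa_f, shifts = geometry.align_to_surface(pa_f, profile)
        profile.shifts = shifts

    # relative lower bound so noiseless input (where the "floor" is only
    # filter ringing, ~1e-6 of peak) still gets meaningful thresholding;
    # at realistic SNR the measured floor is orders of magnitude larger
    floor = max(floor, 1e-3 * float(np.abs(pa_f).max()))
    mask = preprocess.amplitude_mask(pa_f, floor, cfg.noise_factor)

    up = preprocess.upsample_axial(pa_f, cfg.nres)
    mask_up = preprocess.upsample_mask(mask, cfg.nres)

    circular = rotational and scan.n_lines == params.lines_per_rev
    vmap = doppler.correlate_adjacent(up, mask_up, cfg, circular=circular)
    vmap = doppler.gate(vmap, cfg.rho_min)
    vres = doppler.velocity_resolution(params, cfg.nres)
    vmap = doppler.to_velocity(vmap, vres)

    if angle is None:
        vmap.v = vmap.vc.copy()
    elif isinstance(angle, str):
        if angle != "surface":
            raise ValueError("angle must be a number, None, or 'surface'")
        if profile is None:
            raise ValueError("surface-based angles require a rotational scan")
        profile = geometry.estimate_angles(profile, params, cfg, mode=angle_mode)
        vmap = geometry.compensate(vmap, profile, cfg)
    else:
        vmap = geometry.compensate(vmap, float(angle), cfg)

    display = geometry.backshift(vmap, shifts) if shifts is not None else vmap.copy()

    return PipelineResult(vmap=vmap, vmap_display=display, profile=profile,
                          mask=mask, noise_floor=floor, vres=vres,
                          params=params, cfg=cfg)


def mean_speed(vmap: VelocityMap) -> float:
    """Magnitude of the mean compensated velocity over valid windows (m/s).

    Averaging signed velocities first keeps the estimate unbiased when
    sub-sample refinement scatters low-speed windows around zero; the
    magnitude is taken last because reported flow speeds are unsigned.
    """
    src = vmap.v if vmap.v is not None else vmap.vc
    if src is None:
        raise ValueError("velocity map has no velocities; run to_velocity")
    vals = src[vmap.valid]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        return float("nan")
    return float(abs(vals.mean()))
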