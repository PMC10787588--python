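"""RF conditioning ahead of correlation.

Band-pass filtering, noise-floor estimation, envelope amplitude masking
and band-limited axial interpolation.  Frames are (n_samples, n_lines)
real arrays; every operation works per A-line along axis 0.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import signal

from .types import AcquisitionParams, DopplerConfig

__all__ = [
    "bandpass",
    "bandpass_taps",
    "noise_floor",
    "amplitude_mask",
    "envelope",
    "upsample_axial",
]

# Kaiser design sized for >=40 dB rejection one octave below the low band
# edge (1.5 MHz transition at fs=180 MHz); 301 taps, linear phase.
_N_TAPS = 301
_KAISER_BETA = 4.55


@lru_cache(maxsize=8)
def bandpass_taps(low: float, high: float, fs: float) -> np.ndarray:
    """Linear-phase FIR band-pass taps for the given edges (Hz)."""
    if high >= fs / 2:
        raise ValueError("passband high edge must be below fs/2")
    return signal.firwin(_N_TAPS, [low, high], pass_zero=False,
                         window=("kaiser", _KAISER_BETA), fs=fs)


def bandpass(frame: np.ndarray, params: AcquisitionParams,
             cfg: DopplerConfig) -> np.ndarray:
    """Apply the passband FIR filter per A-line, group delay compensated.

    The filter is odd-length linear phase and applied with ``mode='same'``
    convolution, so the output stays aligned with the input.
    """
    frame = np.asarray(frame, dtype=float)
    taps = bandpass_taps(cfg.passband[0], cfg.passband[1], params.fs)
    if frame.shape[0] < taps.shape[0]:
        raise ValueError(
            f"frame length {frame.shape[0]} shorter than filter length {taps.shape[0]}")
    if frame.ndim == 1:
        return signal.fftconvolve(frame, taps, mode="same")
    return signal.fftconvolve(frame, taps[:, None], mode="same", axes=0)


def noise_floor(frame: np.ndarray, noise_region="auto", *,
                surface_arrival: np.ndarray | None = None,
                pulse_len: int = 0) -> float:
    """Mean absolute amplitude over a signal-free region, pooled across lines.

    ``noise_region`` may be a ``(start, stop)`` sample range, a slice, or
    ``"auto"``.  Auto selects all samples earlier than the shallowest valid
    surface arrival minus one pulse length when ``surface_arrival`` is
    given, otherwise (or if that region is empty) the first 200 samples,
    with a warning on the fallback.
    """
    frame = np.atleast_2d(np.asarray(frame, dtype=float))
    n = frame.shape[-2] if frame.ndim > 1 else frame.shape[0]
    if isinstance(noise_region, str):
        if noise_region != "auto":
            raise ValueError(f"unknown noise_region '{noise_region}'")
        stop = 0
        if surface_arrival is not None:
            arr = np.asarray(surface_arrival, dtype=float)
            arr = arr[np.isfinite(arr)]
            if arr.size:
                stop = int(np.floor(arr.min())) - int(pulse_len)
        if stop <= 0:
            if surface_arrival is not None:
                warnings.warn("auto noise region empty; falling back to first 200 samples")
            stop = min(200, n)
        region = slice(0, stop)
    elif isinstance(noise_region, slice):
        region = noise_region
    else:
        start, stop = noise_region
        region = slice(int(start), int(stop))
    block = frame[region] if frame.ndim == 1 else frame[region, :]
    if block.size == 0:
        raise ValueError("noise region is empty")
    return float(np.mean(np.abs(block)))


def envelope(frame: np.ndarray) -> np.ndarray:
    """Amplitude envelope: magnitude of the analytic signal per A-line."""
    frame = np.asarray(frame, dtype=float)
    return np.abs(signal.hilbert(frame, axis=0 if frame.ndim > 1 else -1))


def amplitude_mask(frame: np.ndarray, floor: float,
                   noise_factor: float) -> np.ndarray:
    """Boolean mask of samples whose envelope clears ``noise_factor * floor``.

    Used to keep the correlator away from noise-only regions; a zero floor
    (noiseless input) or zero factor degenerates to an all-true mask.
    """
    if floor < 0:
        raise ValueError("floor must be >= 0")
    return envelope(frame) >= noise_factor * floor


def upsample_axial(frame: np.ndarray, nres: int) -> np.ndarray:
    """Band-limited (Fourier) resampling to ``nres`` x the axial rate.

    Original samples are preserved at stride ``nres``; ``nres=1`` is the
    identity (a copy).
    """
    nres = int(nres)
    if nres < 1:
        raise ValueError("nres must be >= 1")
    frame = np.asarray(frame, dtype=float)
    if nres == 1:
        return frame.copy()
    axis = 0 if frame.ndim > 1 else -1
    n = frame.shape[axis]
    return signal.resample(frame, nres * n, axis=axis)


def upsample_mask(mask: np.ndarray, nres: int) -> np.ndarray:
    """Repeat each axial mask sample ``nres`` times (no interpolation)."""
    nres = int(nres)
    if nres < 1:
        raise ValueError("nres must be >= 1")
    return np.repeat(np.asarray(mask, dtype=bool), nres, axis=0)
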