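"""Correlational velocity estimation between adjacent A-lines.

The estimator slides a short window down each adjacent A-line pair and
finds the integer lag (in interpolated samples) maximising the normalized
zero-mean cross-correlation; the lag times the velocity resolution

    Vres = (c/2) * fprf / (fs * nres)

is the axial velocity of the scatterers in that window.  A positive shift
means the echo arrives earlier in the later line, i.e. motion toward the
transducer, displayed as positive velocity.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .types import AcquisitionParams, DopplerConfig, VelocityMap

__all__ = [
    "velocity_resolution",
    "correlate_adjacent",
    "gate",
    "to_velocity",
    "roi_average",
]

_NORM_EPS = 1e-12


def velocity_resolution(params: AcquisitionParams, nres: int) -> float:
    """Axial speed corresponding to a one-interpolated-sample shift per
    PRF interval: ``(c/2) * fprf / (fs * nres)`` m/s.

    With c=1540 m/s, fprf=1 kHz, fs=180 MHz, nres=3 this is 1.4259 mm/s.
    """
    nres = int(nres)
    if nres < 1:
        raise ValueError("nres must be >= 1")
    return 0.5 * params.c * params.fprf / (params.fs * nres)


def _window_validity(mask: np.ndarray, centers: np.ndarray, half: int,
                     circular: bool) -> np.ndarray:
    """valid[ci, pair] = window fully inside mask on both pair lines."""
    m = mask.shape[1]
    csum = np.cumsum(mask.astype(np.int64), axis=0)
    pad = np.zeros((1, m), dtype=np.int64)
    csum = np.vstack([pad, csum])
    counts = csum[centers + half + 1, :] - csum[centers - half, :]
    full = counts == (2 * half + 1)
    if circular:
        nxt = np.roll(full, -1, axis=1)
        return full & nxt
    return full[:, :-1] & full[:, 1:]


def correlate_adjacent(frame_interp: np.ndarray, mask: np.ndarray,
                       cfg: DopplerConfig, *, circular: bool = False,
                       ) -> VelocityMap:
    """Windowed lag search between each adjacent A-line pair.

    Parameters
    ----------
    frame_interp : ndarray, (n_interp_samples, n_lines)
        Band-passed frame already upsampled by ``cfg.nres``.
    mask : boolean ndarray, same shape
        Amplitude mask at interpolated resolution; a window is searched
        only if it lies fully inside the mask on both lines of the pair.
    circular : bool
        Pair the last line with the first (full-revolution scans).

    Returns a :class:`VelocityMap` with ``pshift``, ``rho``, ``valid`` and
    ``window_centers`` filled.  Ties in the lag search resolve to the
    smaller ``|lag|``, then to the non-negative lag.  With
    ``cfg.subsample_refine`` a parabola through the peak and its two
    neighbours refines the lag to a real value clamped to the search
    range.
    """
    frame = np.asarray(frame_interp, dtype=float)
    if frame.ndim != 2 or frame.shape[1] < 2:
        raise ValueError("frame must be 2-D with at least 2 lines")
    if mask.shape != frame.shape:
        raise ValueError("mask shape must match frame shape")
    n, m = frame.shape
    wl, L, hop = cfg.window_len, cfg.max_lag, cfg.window_hop
    half = wl // 2
    if wl > n:
        raise ValueError(f"window_len {wl} exceeds line length {n}")
    first = half + L
    last = n - half - L - 1
    if last < first:
        raise ValueError("line too short for window_len + max_lag")
    centers = np.arange(first, last + 1, hop)
    n_pairs = m if circular else m - 1

    valid = _window_validity(np.asarray(mask, dtype=bool), centers, half, circular)

    lags = np.arange(-L, L + 1)
    refine = bool(cfg.subsample_refine)
    pshift = np.zeros((centers.size, n_pairs), dtype=float if refine else np.int64)
    rho = np.zeros((centers.size, n_pairs), dtype=float)

    ci, pi = np.nonzero(valid)
    if ci.size:
        starts = centers[ci] - half
        cols = np.arange(wl)
        ref = frame[starts[:, None] + cols[None, :], pi[:, None]]
        ref = ref - ref.mean(axis=1, keepdims=True)
        ref_norm = np.linalg.norm(ref, axis=1)
        ok_ref = ref_norm > _NORM_EPS
        ref = ref / np.where(ok_ref, ref_norm, 1.0)[:, None]

        nxt_line = (pi + 1) % m if circular else pi + 1
        rho_all = np.empty((ci.size, lags.size))
        ok_all = np.ones(ci.size, dtype=bool) & ok_ref
        for j, s in enumerate(lags):
            cand = frame[starts[:, None] + s + cols[None, :], nxt_line[:, None]]
            cand = cand - cand.mean(axis=1, keepdims=True)
            cnorm = np.linalg.norm(cand, axis=1)
            okc = cnorm > _NORM_EPS
            cand = cand / np.where(okc, cnorm, 1.0)[:, None]
            rho_all[:, j] = np.einsum("ij,ij->i", ref, cand)
            rho_all[~okc, j] = 0.0

        # lag of the maximum; ties -> smaller |pshift|, then non-negative.
        # pshift = -lag (a match at negative lag means the content arrives
        # earlier in the later line).
        pvals = -lags
        maxv = rho_all.max(axis=1)
        tie = rho_all == maxv[:, None]
        penalty = np.abs(pvals)[None, :] + 0.25 * (pvals < 0)[None, :]
        penalty = np.where(tie, penalty, np.inf)
        best_j = np.argmin(penalty, axis=1)
        best_p = pvals[best_j].astype(float)
        best_rho = rho_all[np.arange(ci.size), best_j]

        if refine:
            interior = (np.abs(best_p) < L)
            jj = best_j[interior]
            r0 = rho_all[interior, jj]
            # neighbours in pshift: p-1 is lag index jj+1, p+1 is jj-1
            rm = rho_all[interior, jj + 1]   # pshift - 1
            rp = rho_all[interior, jj - 1]   # pshift + 1
            denom = rm - 2.0 * r0 + rp
            delta = np.where(denom < 0, 0.5 * (rm - rp) / np.where(denom == 0, 1, denom), 0.0)
            delta = np.clip(delta, -0.5, 0.5)
            refined = best_p[interior] + delta
            best_p[interior] = np.clip(refined, -L, L)

        out_p = best_p if refine else np.rint(best_p).astype(np.int64)
        pshift[ci, pi] = out_p
        rho[ci, pi] = best_rho
        valid[ci[~ok_all], pi[~ok_all]] = False

    return VelocityMap(pshift=pshift, rho=rho, valid=valid,
                       window_centers=centers.copy(), nres=cfg.nres)


def gate(vmap: VelocityMap, rho_min: float) -> VelocityMap:
    """Drop windows whose correlation amplitude falls below ``rho_min``."""
    out = vmap.copy()
    out.valid = vmap.valid & (vmap.rho >= rho_min)
    return out


def to_velocity(vmap: VelocityMap, vres: float) -> VelocityMap:
    """Convert lags to axial velocity: ``vc = pshift * vres`` (NaN where
    invalid)."""
    if vres <= 0:
        raise ValueError("vres must be > 0")
    out = vmap.copy()
    vc = vmap.pshift.astype(float) * vres
    vc[~vmap.valid] = np.nan
    out.vc = vc
    return out


def _block_slices(n_pairs: int, roi: int) -> list[slice]:
    if roi >= n_pairs:
        return [slice(0, n_pairs)]
    n_full = n_pairs // roi
    rem = n_pairs - n_full * roi
    slices = [slice(i * roi, (i + 1) * roi) for i in range(n_full)]
    if rem >= roi / 2:
        slices.append(slice(n_full * roi, n_pairs))
    return slices


def roi_average(vmap: VelocityMap, roi_lines: int) -> VelocityMap:
    """Average velocities over blocks of consecutive line pairs.

    Suppresses estimate noise the way limited A-line averaging does on a
    hand-held probe: per window row, disjoint blocks of ``roi_lines``
    pairs (a trailing partial block is kept if at least half-sized) are
    reduced to the mean of their valid members.  A block is valid when at
    least 10% of its members were valid.
    """
    roi = int(roi_lines)
    if roi < 1:
        raise ValueError("roi_lines must be >= 1")
    slices = _block_slices(vmap.n_pairs, roi)
    n_rows = vmap.pshift.shape[0]
    n_blocks = len(slices)

    pshift = np.zeros((n_rows, n_blocks))
    rho = np.zeros((n_rows, n_blocks))
    valid = np.zeros((n_rows, n_blocks), dtype=bool)
    vc = None if vmap.vc is None else np.full((n_rows, n_blocks), np.nan)
    v = None if vmap.v is None else np.full((n_rows, n_blocks), np.nan)

    for b, sl in enumerate(slices):
        vb = vmap.valid[:, sl]
        cnt = vb.sum(axis=1)
        members = vb.shape[1]
        ok = cnt >= max(1, int(np.ceil(0.1 * members)))
        with np.errstate(invalid="ignore"):
            for src, dst in ((vmap.pshift.astype(float), pshift), (vmap.rho, rho)):
                s = np.where(vb, src[:, sl], 0.0).sum(axis=1)
                dst[:, b] = np.where(cnt > 0, s / np.maximum(cnt, 1), 0.0)
            if vc is not None:
                s = np.where(vb, np.nan_to_num(vmap.vc[:, sl]), 0.0).sum(axis=1)
                vc[ok, b] = (s / np.maximum(cnt, 1))[ok]
            if v is not None:
                s = np.where(vb, np.nan_to_num(vmap.v[:, sl]), 0.0).sum(axis=1)
                v[ok, b] = (s / np.maximum(cnt, 1))[ok]
        valid[:, b] = ok

    return VelocityMap(pshift=pshift, rho=rho, valid=valid,
                       window_centers=vmap.window_centers.copy(),
                       nres=vmap.nres, vc=vc, v=v)
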