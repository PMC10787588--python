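"""HDF5 scan container and TOML configuration loading.

Container layout (version 1)::

    /pa      float64, (n_samples, n_lines)   photoacoustic RF
    /us      float64, (n_samples, n_lines)   ultrasound RF
    /params  group; one attribute per AcquisitionParams field (SI units)
    /meta    group; free-form scalar/string attributes
    /truth   optional group with the simulator ground-truth datasets
"""

from __future__ import annotations

import dataclasses
import os
import tomllib
from typing import Optional

import h5py
import numpy as np

from .types import AcquisitionParams, DopplerConfig, GroundTruth, ScanSet

__all__ = ["read_scanset", "write_scanset", "load_config", "LAYOUT_VERSION"]

LAYOUT_VERSION = 1

_TRUTH_FIELDS = ("true_axial_velocity", "true_speed", "flow_angle", "surface_arrival")


class ScanFormatError(ValueError):
    """Raised when a container is missing required datasets or attributes."""


def write_scanset(scan: ScanSet, path: str | os.PathLike) -> str:
    """Write a validated :class:`ScanSet` to an HDF5 container.

    Returns the path written.  The scan is re-validated before writing, so
    NaNs or mismatched shapes fail early.
    """
    # re-validate (the arrays may have been mutated since construction)
    ScanSet(pa=scan.pa, us=scan.us, params=scan.params,
            meta=scan.meta, ground_truth=scan.ground_truth)
    path = os.fspath(path)
    with h5py.File(path, "w") as f:
        f.attrs["layout_version"] = LAYOUT_VERSION
        dpa = f.create_dataset("pa", data=np.asarray(scan.pa, dtype=np.float64))
        dpa.attrs["units"] = "arbitrary (RF amplitude)"
        dus = f.create_dataset("us", data=np.asarray(scan.us, dtype=np.float64))
        dus.attrs["units"] = "arbitrary (RF amplitude)"
        g = f.create_group("params")
        for fld in dataclasses.fields(scan.params):
            g.attrs[fld.name] = getattr(scan.params, fld.name)
        g.attrs["units"] = "SI: c m/s, fprf Hz, fs Hz, dphi deg, probe_offset m, pa_us_delay s"
        m = f.create_group("meta")
        for k, v in scan.meta.items():
            m.attrs[str(k)] = v
        if scan.ground_truth is not None:
            t = f.create_group("truth")
            for name in _TRUTH_FIELDS:
                t.create_dataset(name, data=np.asarray(getattr(scan.ground_truth, name)))
    return path


def read_scanset(path: str | os.PathLike) -> ScanSet:
    """Read a :class:`ScanSet` from an HDF5 container written by
    :func:`write_scanset`.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ScanFormatError
        If a required dataset or the params group is missing.
    ValueError
        If the stored arrays violate ScanSet invariants.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with h5py.File(path, "r") as f:
        for name in ("pa", "us"):
            if name not in f:
                raise ScanFormatError(f"container is missing required dataset '{name}'")
        if "params" not in f:
            raise ScanFormatError("container is missing required group 'params'")
        pa = f["pa"][...]
        us = f["us"][...]
        pattrs = dict(f["params"].attrs)
        pattrs.pop("units", None)
        kwargs = {}
        for fld in dataclasses.fields(AcquisitionParams):
            if fld.name in pattrs:
                val = pattrs[fld.name]
                if isinstance(val, bytes):
                    val = val.decode()
                kwargs[fld.name] = val
        # normalise numpy scalar / string types
        for k, v in list(kwargs.items()):
            if isinstance(v, np.generic):
                kwargs[k] = v.item()
        if "lines_per_rev" in kwargs:
            kwargs["lines_per_rev"] = int(kwargs["lines_per_rev"])
        params = AcquisitionParams(**kwargs)
        meta = {}
        if "meta" in f:
            for k, v in f["meta"].attrs.items():
                if isinstance(v, bytes):
                    v = v.decode()
                elif isinstance(v, np.generic):
                    v = v.item()
                meta[k] = v
        truth = None
        if "truth" in f:
            t = f["truth"]
            missing = [n for n in _TRUTH_FIELDS if n not in t]
            if missing:
                raise ScanFormatError(f"truth group is missing dataset(s) {missing}")
            truth = GroundTruth(**{n: t[n][...] for n in _TRUTH_FIELDS})
    return ScanSet(pa=pa, us=us, params=params, meta=meta, ground_truth=truth)


def load_config(path: Optional[str | os.PathLike] = None,
                ) -> tuple[AcquisitionParams, DopplerConfig]:
    """Load acquisition and Doppler configuration from a TOML file.

    The file may contain ``[acquisition]`` and ``[doppler]`` tables; any
    absent key keeps its default.  ``path=None`` (or a missing file path of
    ``None``) returns pure defaults.  Unknown keys and out-of-range values
    raise ``ValueError`` naming the field.
    """
    acq_kwargs: dict = {}
    dop_kwargs: dict = {}
    if path is not None:
        with open(os.fspath(path), "rb") as fh:
            data = tomllib.load(fh)
        known = {"acquisition", "doppler"}
        extra = set(data) - known
        if extra:
            raise ValueError(f"unknown config table(s) {sorted(extra)}; expected {sorted(known)}")
        acq_fields = {f.name for f in dataclasses.fields(AcquisitionParams)}
        dop_fields = {f.name for f in dataclasses.fields(DopplerConfig)}
        for k, v in data.get("acquisition", {}).items():
            if k not in acq_fields:
                raise ValueError(f"unknown acquisition key '{k}'")
            acq_kwargs[k] = v
        for k, v in data.get("doppler", {}).items():
            if k not in dop_fields:
                raise ValueError(f"unknown doppler key '{k}'")
            if k == "passband":
                v = tuple(float(x) for x in v)
            dop_kwargs[k] = v
    params = AcquisitionParams(**acq_kwargs)
    cfg = DopplerConfig(**dop_kwargs)
    cfg.validate_against(params)
    return params, cfg
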