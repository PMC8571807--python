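"""Readers/writers for frame-stack containers and filter configuration.

Two on-disk forms are supported:

* an HDF5 container with one group per stack (e.g. ``/us``, ``/pa``), each
  holding a dataset ``data`` of shape (depth, lateral, frame) and attributes
  ``modality``, ``scale``, ``frame_rate_hz``, ``pixel_pitch_mm``;
* multi-frame TIFF, one page per frame, with the same metadata embedded as
  JSON in the image description.

Configuration files are flat YAML key-value mappings; every key has a
default and the resolved values always land in the run provenance.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from . import __version__
from .masking import MaskParams
from .preprocess import FrameStack, Modality, Scale
from .svd_core import ComponentSet, FilterConfig
from .synthetic import PhantomConfig

__all__ = [
    "read_stack",
    "write_stack",
    "write_components",
    "load_config",
    "filter_config_from_dict",
    "mask_params_from_dict",
    "phantom_config_from_dict",
    "make_provenance",
]

_REQUIRED_ATTRS = ("modality", "scale", "frame_rate_hz", "pixel_pitch_mm")


def _check_finite(data: np.ndarray, where: str) -> None:
    bad = ~np.isfinite(data)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(
            f"{where}: {int(bad.sum())} non-finite value(s); first at index {idx}"
        )


def _is_tiff(path: str | Path) -> bool:
    return str(path).lower().endswith((".tif", ".tiff"))


def read_stack(path: str | Path, group: str = "/us") -> FrameStack:
    """Load a FrameStack from an HDF5 container group or a multi-frame TIFF."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _is_tiff(path):
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        if pages.ndim == 2:
            pages = pages[None, ...]
        data = np.moveaxis(pages, 0, -1)  # pages are frames
    else:
        with h5py.File(path, "r") as f:
            if group not in f:
                raise KeyError(f"group {group!r} not found in {path}")
            g = f[group]
            if "data" not in g:
                raise KeyError(f"dataset 'data' missing under {group}")
            data = g["data"][()]
            meta = {}
            for key in _REQUIRED_ATTRS:
                if key not in g.attrs:
                    raise KeyError(f"required attribute {key!r} missing from {group}")
                meta[key] = g.attrs[key]
    _check_finite(np.asarray(data, dtype=float), f"{path}:{group}")
    for key in _REQUIRED_ATTRS:
        meta.setdefault(key, _DEFAULT_META[key])
    return FrameStack(
        np.asarray(data, dtype=float),
        modality=Modality(str(meta["modality"])),
        scale=Scale(str(meta["scale"])),
        frame_rate_hz=float(meta["frame_rate_hz"]),
        pixel_pitch_mm=tuple(np.asarray(meta["pixel_pitch_mm"], dtype=float)),
    )


_DEFAULT_META = {
    "modality": "US",
    "scale": "log_dB",
    "frame_rate_hz": 20.0,
    "pixel_pitch_mm": (0.1, 0.1),
}


def write_stack(path: str | Path, stack: FrameStack, group: str = "/us") -> None:
    """Write a FrameStack to an HDF5 container group or a multi-frame TIFF."""
    path = Path(path)
    meta = {
        "modality": stack.modality.value,
        "scale": stack.scale.value,
        "frame_rate_hz": stack.frame_rate_hz,
        "pixel_pitch_mm": list(stack.pixel_pitch_mm),
    }
    if _is_tiff(path):
        pages = np.moveaxis(stack.data, -1, 0)
        tifffile.imwrite(path, pages.astype(np.float32), description=json.dumps(meta))
        return
    with h5py.File(path, "a") as f:
        if group in f:
            del f[group]
        g = f.create_group(group)
        g.create_dataset("data", data=stack.data)
        for k, v in meta.items():
            g.attrs[k] = v
        if stack.provenance:
            g.attrs["provenance"] = json.dumps(stack.provenance, default=str)


def write_components(path: str | Path, components: ComponentSet, prefix: str = "/components") -> None:
    """Write the three component stacks plus the per-block threshold fields."""
    for name in ("stationary", "flow", "noise"):
        write_stack(path, getattr(components, name), f"{prefix}/{name}")
    with h5py.File(path, "a") as f:
        grp = f.require_group("/provenance")
        key = prefix.strip("/").replace("/", "_")
        if f"{key}_thresholds" in grp.attrs:
            del grp.attrs[f"{key}_thresholds"]
        grp.attrs[f"{key}_thresholds"] = json.dumps(components.provenance, default=str)


# ---------------------------------------------------------------------------
# configuration


def load_config(path: str | Path | None) -> dict:
    """Load a flat YAML key-value config file (empty dict when path is None)."""
    if path is None:
        return {}
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config file {path} must contain a flat key-value mapping")
    return cfg


def _pick(cfg: dict, cls, keys: dict) -> dict:
    kwargs = {}
    for key, conv in keys.items():
        if key in cfg:
            kwargs[key] = conv(cfg[key])
    return kwargs


def filter_config_from_dict(cfg: dict) -> FilterConfig:
    keys = {
        "block_rows_px": int,
        "block_cols_px": int,
        "preset_ratio": float,
        "diff_ma_frac": float,
        "grid_window": lambda v: tuple(int(x) for x in v),
        "median_window": lambda v: tuple(int(x) for x in v),
        "fallback_policy": str,
        "ratio_domain": str,
    }
    return FilterConfig(**_pick(cfg, FilterConfig, keys))


def mask_params_from_dict(cfg: dict) -> MaskParams:
    keys = {
        "blur_sigma_px": float,
        "canny_sigma_px": float,
        "closing_radius_px": int,
        "pa_threshold_pct": float,
        "std_floor": float,
    }
    return MaskParams(**_pick(cfg, MaskParams, keys))


def phantom_config_from_dict(cfg: dict) -> PhantomConfig:
    keys = {
        "image_shape_px": lambda v: tuple(int(x) for x in v),
        "pixel_pitch_mm": lambda v: tuple(float(x) for x in v),
        "frame_rate_hz": float,
        "n_frames": int,
        "lumen_center_mm": lambda v: tuple(float(x) for x in v),
        "lumen_diameter_mm": float,
        "wall_thickness_mm": float,
        "pulsation_hz": float,
        "wall_strain": float,
        "cavity_radius_mm": float,
        "arteriole_diameter_mm": float,
        "arteriole_angle_deg": float,
        "iph_diameter_mm": float,
        "speckle_grain_px": float,
        "flow_corr": float,
        "background_amp": float,
        "wall_amp": float,
        "flow_amp": float,
        "noise_sigma": float,
        "pa_iph_amp": float,
        "pa_flow_amp": float,
        "pa_background": float,
        "pa_noise_sigma": float,
        "fluence_decay_mm": float,
        "shadow_atten_per_mm": float,
        "log_floor_db": float,
        "seed": int,
    }
    return PhantomConfig(**_pick(cfg, PhantomConfig, keys))


def make_provenance(config: dict, seed: int | None = None, **extra) -> dict:
    """Assemble the reproducibility record embedded in every output container."""
    return {
        "software_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "config": config,
        "seed": seed,
        **extra,
    }
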