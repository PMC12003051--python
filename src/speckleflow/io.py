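"""Stack and report I/O.

Stacks travel as multi-page TIFF (the modality's de facto container;
12-bit data is stored in 16-bit pages) with a JSON sidecar carrying the
acquisition metadata (exposure times, bit depth, provenance).  Reports are
deterministic CSV / JSON files.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import asdict, dataclass, field
from typing import Any, Dict, List, Optional, Sequence

import numpy as np
import tifffile
import yaml

from . import __version__
from .contrast import KernelSpec
from .flowmodels import MESIFit
from .pipeline import ComparisonTable, REPORT_COLUMNS
from .specklesim import DecorrelationSpec, SimulationConfig, SpeckleStack

__all__ = [
    "sidecar_path",
    "read_stack",
    "write_stack",
    "write_report",
    "RunConfig",
    "load_run_config",
    "load_rois",
]


def sidecar_path(path: str) -> str:
    base, _ = os.path.splitext(path)
    return base + ".json"


def write_stack(stack: SpeckleStack, path: str) -> str:
    """Write a stack as multi-page TIFF plus a JSON metadata sidecar."""
    frames = stack.frames
    if stack.quantized:
        frames = frames.astype(np.uint16)
    else:
        frames = frames.astype(np.float32)
    tifffile.imwrite(path, frames)
    meta = {
        "exposure_times_ms": list(map(float, stack.exposure_time_per_frame)),
        "quantized": stack.quantized,
        "bit_depth": stack.bit_depth,
        "provenance": stack.provenance,
        "saturation_fractions": list(stack.saturation_fractions) if stack.saturation_fractions else None,
        "speckleflow_version": __version__,
    }
    sp = sidecar_path(path)
    with open(sp, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return sp


def read_stack(
    path: str,
    exposure_times: Optional[Sequence[float]] = None,
    exposure_cycle: Optional[Sequence[float]] = None,
) -> SpeckleStack:
    """Read a multi-page TIFF stack; exposure times from sidecar or override.

    ``exposure_cycle`` assigns exposures by cycling a repeating ladder over
    the pages (multi-exposure acquisitions interleave their exposure times).
    Raises on ragged pages, unsupported dtypes, or missing exposure
    metadata (no silent defaults).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    frames = tifffile.imread(path)
    if frames.dtype == object or frames.ndim not in (2, 3):
        raise ValueError(f"{path}: pages are ragged or not a 2D/3D stack")
    if frames.ndim == 2:
        frames = frames[None]
    if frames.dtype.kind not in "uif" or frames.dtype.itemsize > 8:
        raise ValueError(f"{path}: unsupported dtype {frames.dtype}")
    meta: Dict[str, Any] = {}
    sp = sidecar_path(path)
    if os.path.exists(sp):
        with open(sp) as fh:
            meta = json.load(fh)
    if exposure_times is None and exposure_cycle is not None:
        cycle = np.asarray(exposure_cycle, dtype=float)
        if len(frames) % cycle.size:
            raise ValueError(
                f"{path}: {len(frames)} pages are not divisible by the "
                f"{cycle.size}-exposure cycle (remainder {len(frames) % cycle.size})"
            )
        exposure_times = np.resize(cycle, len(frames))
    if exposure_times is None:
        exposure_times = meta.get("exposure_times_ms")
    if exposure_times is None:
        raise ValueError(
            f"{path}: no exposure times; provide a sidecar ({sp}) or an explicit override"
        )
    exposure_times = np.asarray(exposure_times, dtype=float)
    if exposure_times.size == 1 and len(frames) > 1:
        exposure_times = np.full(len(frames), float(exposure_times))
    if exposure_times.shape != (len(frames),):
        raise ValueError(
            f"{path}: {len(frames)} pages but {exposure_times.size} exposure times"
        )
    quantized = bool(meta.get("quantized", frames.dtype.kind == "u"))
    bit_depth = meta.get("bit_depth")
    if quantized and bit_depth is None:
        bit_depth = 8 * frames.dtype.itemsize
    return SpeckleStack(
        frames=frames,
        exposure_time_per_frame=exposure_times,
        quantized=quantized,
        bit_depth=bit_depth,
        provenance=meta.get("provenance", f"loaded from {os.path.basename(path)}"),
    )


def _config_hash(payload: Any) -> str:
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_report(report, path: str) -> None:
    """Serialize a ComparisonTable (CSV) or MESIFit (JSON) deterministically.

    Columns have a fixed order, floats are printed at 6 significant digits,
    and JSON reports carry the package version and a config hash, so equal
    inputs produce byte-identical files.
    """
    if isinstance(report, ComparisonTable):
        df = report.table
        if df.empty:
            raise ValueError("refusing to write an empty comparison table")
        df = df[REPORT_COLUMNS]
        df.to_csv(path, index=False, float_format="%.6g")
        return
    if isinstance(report, MESIFit):
        payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(report).items()}
        doc = {
            "fit": payload,
            "speckleflow_version": __version__,
            "config_hash": _config_hash(payload),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    if isinstance(report, dict) and all(isinstance(v, MESIFit) for v in report.values()):
        doc = {
            "fits": {k: asdict(v) for k, v in sorted(report.items())},
            "speckleflow_version": __version__,
        }
        doc["config_hash"] = _config_hash(doc["fits"])
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return
    raise TypeError(f"cannot serialize report of type {type(report)!r}")


@dataclass
class RunConfig:
    """Top-level YAML-backed run description."""

    simulation: SimulationConfig
    variants: List[KernelSpec]
    fit: Dict[str, Any] = field(default_factory=dict)
    out: Optional[str] = None
    log_level: str = "INFO"


def _require(mapping: Dict[str, Any], key: str, context: str):
    if key not in mapping:
        raise ValueError(f"config: missing required key {key!r} in {context}")
    return mapping[key]


def load_run_config(path: str) -> RunConfig:
    """Load and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config: top level must be a mapping")
    sim_raw = dict(_require(raw, "simulation", "top level"))
    dec_raw = dict(_require(sim_raw, "decorrelation", "simulation"))
    dec = DecorrelationSpec(
        tau_c=float(_require(dec_raw, "tau_c", "decorrelation")),
        form=dec_raw.get("form", "neg_exponential"),
        static=bool(dec_raw.get("static", False)),
    )
    sim_raw.pop("decorrelation")
    if "seed" not in sim_raw:
        raise ValueError("config: simulation requires an explicit seed")
    if "image_shape" in sim_raw:
        sim_raw["image_shape"] = tuple(int(v) for v in sim_raw["image_shape"])
    if "exposure_times" in sim_raw:
        sim_raw["exposure_times"] = tuple(float(v) for v in sim_raw["exposure_times"])
    try:
        sim = SimulationConfig(decorrelation=dec, **sim_raw)
    except TypeError as exc:
        raise ValueError(f"config: bad simulation block: {exc}") from None
    variants_raw = raw.get("variants") or []
    if not variants_raw:
        raise ValueError("config: at least one contrast variant is required")
    variants = []
    for i, v in enumerate(variants_raw):
        try:
            variants.append(KernelSpec(**v))
        except TypeError as exc:
            raise ValueError(f"config: bad variant #{i}: {exc}") from None
    fit = raw.get("fit") or {}
    if not isinstance(fit, dict):
        raise ValueError("config: fit block must be a mapping")
    return RunConfig(
        simulation=sim,
        variants=variants,
        fit=fit,
        out=raw.get("out"),
        log_level=str(raw.get("log_level", "INFO")),
    )


def load_rois(path: str, image_shape) -> Dict[str, np.ndarray]:
    """Load ROI masks from a JSON sidecar of rectangles/polygons.

    Coordinates are 0-based, row-major; rectangles are half-open
    ``[r0, c0, r1, c1]``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    rois = doc["rois"] if isinstance(doc, dict) else doc
    masks: Dict[str, np.ndarray] = {}
    for roi in rois:
        name = _require(roi, "name", "roi")
        kind = roi.get("type", "rect")
        mask = np.zeros(image_shape, dtype=bool)
        if kind == "rect":
            r0, c0, r1, c1 = (int(v) for v in _require(roi, "bounds", name))
            mask[r0:r1, c0:c1] = True
        elif kind == "polygon":
            from matplotlib.path import Path

            verts = np.asarray(_require(roi, "vertices", name), dtype=float)
            rr, cc = np.mgrid[0 : image_shape[0], 0 : image_shape[1]]
            pts = np.column_stack([rr.ravel(), cc.ravel()])
            mask = Path(verts).contains_points(pts).reshape(image_shape)
        else:
            raise ValueError(f"roi {name!r}: unknown type {kind!r}")
        if not mask.any():
            raise ValueError(f"roi {name!r} is empty on image {image_shape}")
        masks[name] = mask
    return masks
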