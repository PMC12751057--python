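"""CSV serialisation for traces, rate datasets, contours and landscapes.

Numbers are written with 17 significant digits so that write-then-read is an
exact round trip for double precision.  Trace metadata travels in '#'
key: value header lines above the column header.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Mapping

import numpy as np

from .globalfit import ConfidenceRegion
from .landscape import EnergyLandscape
from .observables import Trace
from .schemes import ReactionConditions
from .synthetic import RateDataset

__all__ = [
    "TraceFormatError",
    "write_trace_csv",
    "read_trace_csv",
    "write_rate_dataset_csv",
    "read_rate_dataset_csv",
    "write_contour_csv",
    "write_landscape_csv",
    "config_hash",
]

_FMT = "%.17g"

_CONDITION_FIELDS = (
    "enzyme_total",
    "substrate_total",
    "active_fraction",
    "temperature",
    "path_length",
    "dead_time",
)


class TraceFormatError(ValueError):
    """Raised for malformed trace files, with the offending line number."""


def write_trace_csv(trace: Trace, path) -> Path:
    path = Path(path)
    lines = [f"# wavelength_nm: {_FMT % trace.wavelength}",
             f"# noise_sigma_AU: {_FMT % trace.noise_sigma}"]
    for name in _CONDITION_FIELDS:
        lines.append(f"# {name}: {_FMT % getattr(trace.conditions, name)}")
    if trace.conditions.label:
        lines.append(f"# label: {trace.conditions.label}")
    lines.append("time_s,absorbance_AU")
    for t, s in zip(trace.time, trace.signal):
        lines.append(f"{_FMT % t},{_FMT % s}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace_csv(path) -> Trace:
    path = Path(path)
    meta: dict[str, str] = {}
    times: list[float] = []
    signals: list[float] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if ":" not in line:
                    raise TraceFormatError(
                        f"{path}:{lineno}: unparseable metadata line {line!r}"
                    )
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                cols = [c.strip() for c in line.split(",")]
                if cols != ["time_s", "absorbance_AU"]:
                    raise TraceFormatError(
                        f"{path}:{lineno}: expected columns time_s,absorbance_AU, got {line!r}"
                    )
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise TraceFormatError(f"{path}:{lineno}: expected 2 fields, got {len(parts)}")
            try:
                t, s = float(parts[0]), float(parts[1])
            except ValueError:
                raise TraceFormatError(f"{path}:{lineno}: non-numeric value") from None
            if times and t <= times[-1]:
                raise TraceFormatError(
                    f"{path}:{lineno}: time {t:g} not strictly increasing"
                )
            times.append(t)
            signals.append(s)
    if not header_seen:
        raise TraceFormatError(f"{path}: missing column header")
    try:
        wavelength = float(meta["wavelength_nm"])
        noise_sigma = float(meta.get("noise_sigma_AU", "0"))
        conditions = ReactionConditions(
            **{name: float(meta[name]) for name in _CONDITION_FIELDS},
            label=meta.get("label", ""),
        )
    except KeyError as exc:
        raise TraceFormatError(f"{path}: missing metadata key {exc}") from None
    return Trace(
        time=np.asarray(times),
        signal=np.asarray(signals),
        wavelength=wavelength,
        conditions=conditions,
        noise_sigma=noise_sigma,
    )


def write_rate_dataset_csv(dataset: RateDataset, path) -> Path:
    path = Path(path)
    lines = [f"# model_id: {dataset.model_id}"]
    for key, value in (dataset.fixed_inputs or {}).items():
        lines.append(f"# fixed.{key}: {_FMT % value}")
    lines.append("predictor,response,replicate_id")
    for x, y, r in zip(dataset.predictor, dataset.response, dataset.replicate_id):
        lines.append(f"{_FMT % x},{_FMT % y},{int(r)}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_rate_dataset_csv(path) -> RateDataset:
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[tuple[float, float, int]] = []
    header_seen = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split(",")
            if len(parts) != 3:
                raise TraceFormatError(f"{path}:{lineno}: expected 3 fields")
            rows.append((float(parts[0]), float(parts[1]), int(parts[2])))
    if "model_id" not in meta:
        raise TraceFormatError(f"{path}: missing model_id metadata")
    fixed = {
        key[len("fixed."):]: float(value)
        for key, value in meta.items()
        if key.startswith("fixed.")
    }
    arr = np.asarray(rows, dtype=float)
    return RateDataset(
        model_id=meta["model_id"],
        predictor=arr[:, 0],
        response=arr[:, 1],
        replicate_id=arr[:, 2].astype(int),
        fixed_inputs=fixed or None,
    )


def write_contour_csv(region: ConfidenceRegion, path) -> Path:
    """SSR-ratio matrix with axis values; threshold and pair in the header."""
    path = Path(path)
    name_x, name_y = region.parameter_pair
    lines = [
        f"# parameter_pair: {name_x},{name_y}",
        f"# confidence: {_FMT % region.confidence}",
        f"# threshold: {_FMT % region.threshold}",
        "# first column: " + name_y + "; first row: " + name_x,
    ]
    header = [""] + [_FMT % v for v in region.grid_x]
    lines.append(",".join(header))
    for i, gy in enumerate(region.grid_y):
        row = [_FMT % gy] + [
            (_FMT % region.ssr_ratio[i, j]) if region.valid[i, j] else "invalid"
            for j in range(region.grid_x.size)
        ]
        lines.append(",".join(row))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_landscape_csv(landscape: EnergyLandscape, path) -> Path:
    path = Path(path)
    lines = [
        f"# reference_concentration_uM: {_FMT % landscape.reference_concentration}",
        f"# truncated: {landscape.truncated}",
        "state,relative_G_kcal_per_mol",
    ]
    for state, g in zip(landscape.states, landscape.relative_G):
        lines.append(f"{state},{_FMT % g}")
    path.write_text("\n".join(lines) + "\n")
    return path


def config_hash(config: Mapping) -> str:
    """Stable short hash of a configuration mapping, for run logs."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
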