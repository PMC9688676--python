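"""Tidy TSV / JSON input-output and result manifests.

All tabular data use one tidy, UTF-8, tab-delimited dialect:

elongation time courses
    columns ``time_s, band_length, fraction, condition, replicate``
stability lanes
    columns ``time_s, band_length, signal, condition, replicate``
    (band_length 7 or 10)

Long format was chosen over wide because the two assays carry different band
sets.  All invariants are enforced at load with row-numbered error messages.
Measurement tables are written losslessly (17 significant digits, exact
float64 round trip); derived result objects serialize to JSON/TSV with 12
significant digits.  Re-running a pipeline with identical inputs reproduces
byte-identical payloads (only the manifest carries a timestamp).
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .kinetics import ObservedTimeCourse
from .stability import StabilityLane
from .synthetic import ReplicateSet

__all__ = [
    "SchemaError",
    "read_timecourse_table",
    "write_timecourse_table",
    "read_stability_table",
    "write_stability_table",
    "write_results",
]

_TIMECOURSE_COLUMNS = ("time_s", "band_length", "fraction", "condition", "replicate")
_STABILITY_COLUMNS = ("time_s", "band_length", "signal", "condition", "replicate")


class SchemaError(ValueError):
    """Missing column or malformed row in a tidy data table."""


def _require_columns(frame: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def _round12(obj):
    """Recursively round floats to 12 significant digits for stable JSON."""
    if isinstance(obj, float):
        if np.isnan(obj):
            return None
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _round12(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return _round12(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


# -- elongation time courses ----------------------------------------------


def read_timecourse_table(path) -> ReplicateSet | dict[str, ReplicateSet]:
    """Load a tidy band-fraction table.

    Returns a single :class:`ReplicateSet` when the file holds one condition,
    otherwise a dict keyed by condition label.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, _TIMECOURSE_COLUMNS, path)

    for row, frac in zip(frame.index, frame["fraction"]):
        if not 0.0 <= float(frac) <= 1.0:
            raise SchemaError(f"{path}: row {row + 2}: fraction {frac} outside [0, 1]")
    for row, (t, b) in enumerate(zip(frame["time_s"], frame["band_length"])):
        if float(t) < 0:
            raise SchemaError(f"{path}: row {row + 2}: negative time {t}")
        if not 7 <= int(b) <= 19:
            raise SchemaError(f"{path}: row {row + 2}: band length {b} outside 7..19")
    dup = frame.duplicated(subset=["time_s", "band_length", "condition", "replicate"])
    if dup.any():
        row = int(frame.index[dup][0])
        raise SchemaError(
            f"{path}: row {row + 2}: duplicate (time_s, band_length, condition, replicate)"
        )

    out: dict[str, ReplicateSet] = {}
    for condition, cframe in frame.groupby("condition", sort=True):
        replicates = [
            ObservedTimeCourse.from_frame(rframe)
            for _, rframe in cframe.groupby("replicate", sort=True)
        ]
        out[str(condition)] = ReplicateSet(
            replicates=replicates,
            condition_label=str(condition),
            provenance={"path": str(path)},
        )
    if len(out) == 1:
        return next(iter(out.values()))
    return out


def write_timecourse_table(data: ReplicateSet | Sequence[ObservedTimeCourse], path) -> None:
    """Write replicates to the tidy TSV dialect (round-trips with the reader)."""
    replicates = list(data) if not isinstance(data, ReplicateSet) else data.replicates
    frame = pd.concat([r.to_frame() for r in replicates], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- stability lanes -------------------------------------------------------


def read_stability_table(path) -> list[StabilityLane]:
    """Load stability lanes (7-mer/10-mer signals) from a tidy TSV table."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    _require_columns(frame, _STABILITY_COLUMNS, path)

    lanes: list[StabilityLane] = []
    keys = {}
    for row in frame.itertuples():
        band = int(row.band_length)
        if band not in (7, 10):
            raise SchemaError(
                f"{path}: row {row.Index + 2}: stability band must be 7 or 10, got {band}"
            )
        if float(row.signal) < 0:
            raise SchemaError(f"{path}: row {row.Index + 2}: negative signal {row.signal}")
        key = (float(row.time_s), str(row.condition), int(row.replicate))
        keys.setdefault(key, {})[band] = float(row.signal)
    for (t, condition, replicate), signals in keys.items():
        if set(signals) != {7, 10}:
            raise SchemaError(
                f"{path}: lane (t={t}, {condition!r}, rep {replicate}) must have "
                "exactly one 7-mer and one 10-mer row"
            )
        lanes.append(
            StabilityLane(
                time=t,
                signal_7mer=signals[7],
                signal_10mer=signals[10],
                condition_label=condition,
                replicate_id=replicate,
            )
        )
    return lanes


def write_stability_table(lanes: Sequence[StabilityLane], path) -> None:
    rows = []
    for lane in lanes:
        for band, signal in ((7, lane.signal_7mer), (10, lane.signal_10mer)):
            rows.append(
                {
                    "time_s": lane.time,
                    "band_length": band,
                    "signal": signal,
                    "condition": lane.condition_label,
                    "replicate": lane.replicate_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


# -- result manifests ------------------------------------------------------


def _write_payload(name: str, obj, out_dir: Path) -> str:
    from .compare import ModelComparison
    from .fitting import AggregatedFit, FitResult
    from .stability import StabilityTimeCourse

    if isinstance(obj, (FitResult, AggregatedFit, ModelComparison)):
        filename = f"{name}.json"
        payload = json.dumps(_round12(obj.to_dict()), indent=2, sort_keys=True)
        (out_dir / filename).write_text(payload + "\n", encoding="utf-8")
    elif isinstance(obj, StabilityTimeCourse):
        filename = f"{name}.tsv"
        pd.DataFrame(
            {"time_s": obj.times, "collapse_fraction": obj.collapse, "sd": obj.sd}
        ).to_csv(out_dir / filename, sep="\t", index=False, float_format="%.12g")
    elif isinstance(obj, (ReplicateSet, ObservedTimeCourse)):
        filename = f"{name}.tsv"
        data = obj if isinstance(obj, ReplicateSet) else [obj]
        write_timecourse_table(data, out_dir / filename)
    elif isinstance(obj, Mapping) or isinstance(obj, (list, tuple)):
        filename = f"{name}.json"
        payload = json.dumps(_round12(obj), indent=2, sort_keys=True)
        (out_dir / filename).write_text(payload + "\n", encoding="utf-8")
    else:
        raise TypeError(f"cannot serialize object of type {type(obj).__name__}")
    return filename


def write_results(
    objects: Mapping[str, object],
    out_dir,
    seed: int | None = None,
    config: Mapping | None = None,
) -> dict:
    """Write named result objects plus a run manifest; returns the manifest.

    Payload files are byte-identical across reruns with identical inputs;
    only the manifest records the wall-clock timestamp.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    files = {}
    for name, obj in objects.items():
        files[name] = _write_payload(name, obj, out_dir)

    from . import __version__

    config_json = json.dumps(_round12(dict(config)) if config else {}, sort_keys=True)
    manifest = {
        "files": files,
        "seed": seed,
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "package_version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
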