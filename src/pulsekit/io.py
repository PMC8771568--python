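"""File formats: multi-page TIFF movies with JSON sidecars, ROI JSON,
gate JSON, and CSV/JSON outputs carrying a provenance metadata block."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .ev_quant import Gate
from .trace_extraction import Roi

META_PREFIX = "# pulsekit-meta: "


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def make_meta(config: dict, seed=None) -> dict:
    from . import __version__
    meta = {"tool": "pulsekit", "version": __version__,
            "config_hash": config_hash(config)}
    if seed is not None:
        meta["seed"] = int(seed)
    return meta


def sidecar_path(path) -> Path:
    return Path(path).with_suffix(".json")


def save_movie(path, stack: np.ndarray, frame_interval_s: float,
               extra: dict | None = None, meta: dict | None = None):
    """16-bit multi-page TIFF plus a JSON sidecar with the time base."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack, dtype=np.uint16))
    payload = {"frame_interval_s": float(frame_interval_s),
               "n_frames": int(stack.shape[0])}
    if extra:
        payload.update(extra)
    if meta:
        payload["_meta"] = meta
    sidecar_path(path).write_text(json.dumps(payload, indent=2, default=_json_default))


def load_movie(path):
    """Returns (stack, sidecar dict). Sidecar may be absent ({})."""
    path = Path(path)
    try:
        stack = tifffile.imread(path)
    except Exception as exc:  # noqa: BLE001 - report the offending file
        raise ValueError(f"malformed TIFF {path}: {exc}") from exc
    side = sidecar_path(path)
    info = json.loads(side.read_text()) if side.exists() else {}
    return stack, info


def save_rois(path, rois: list):
    payload = [{"name": r.name, "role": r.role,
                "vertices": [list(v) for v in r.vertices]} for r in rois]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_rois(path) -> list:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed ROI JSON {path}: {exc}") from exc
    rois = []
    for entry in payload:
        for key in ("name", "role", "vertices"):
            if key not in entry:
                raise ValueError(f"ROI JSON {path}: missing field {key!r}")
        rois.append(Roi(name=entry["name"], role=entry["role"],
                        vertices=tuple(tuple(v) for v in entry["vertices"])))
    return rois


def load_gate(path) -> Gate:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed gate JSON {path}: {exc}") from exc
    for key in ("name", "channels"):
        if key not in payload:
            raise ValueError(f"gate JSON {path}: missing field {key!r}")
    return Gate(name=payload["name"],
                channels={ch: tuple(iv) for ch, iv in payload["channels"].items()})


def save_gate(path, gate: Gate):
    Path(path).write_text(json.dumps(
        {"name": gate.name,
         "channels": {ch: list(iv) for ch, iv in gate.channels.items()}},
        indent=2))


def read_events(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:  # noqa: BLE001
        raise ValueError(f"malformed event CSV {path}: {exc}") from exc


def write_table(table: pd.DataFrame, path, meta: dict | None = None,
                index: bool = False):
    """CSV with a leading provenance comment line."""
    path = Path(path)
    with path.open("w") as fh:
        if meta:
            fh.write(META_PREFIX + json.dumps(meta, sort_keys=True) + "\n")
        table.to_csv(fh, index=index)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(path, payload: dict, meta: dict | None = None):
    if meta:
        payload = {**payload, "_meta": meta}
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default))
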