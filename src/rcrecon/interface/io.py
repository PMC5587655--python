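"""Artifact serialization: float32 TIFF volumes with JSON sidecars."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "save_image",
    "load_image",
    "save_json",
    "load_json",
    "config_hash",
]


def save_image(path, values: np.ndarray, pitch=None, origin=None,
               extra: dict | None = None) -> None:
    """Write a float32 TIFF (multi-page for 3-D) plus a JSON sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(values, dtype=np.float32))
    side = {"pitch": list(pitch) if pitch is not None else None,
            "origin": list(origin) if origin is not None else None}
    if extra:
        side.update(extra)
    save_json(path.with_suffix(path.suffix + ".json"), side)


def load_image(path):
    """Read a TIFF written by :func:`save_image`; returns (values, sidecar)."""
    path = Path(path)
    values = tifffile.imread(path).astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    sidecar = load_json(sidecar_path) if sidecar_path.exists() else {}
    return values, sidecar


def save_json(path, obj: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return str(obj)
    return obj


def config_hash(config_dict: dict) -> str:
    """Stable short hash identifying a scenario configuration."""
    blob = json.dumps(_jsonable(config_dict), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
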