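"""Lossless JSON round-tripping of result records.

Every result type in the package (CCA fits, permutation tests, association
rows, meta-analysis rows, preprocessing logs, study reports) is a dataclass
with ``to_dict``/``from_dict``.  This module wraps them in an envelope with a
schema version and RNG-seed provenance, serializes numpy arrays with shape
metadata, and maps the missing sentinel to JSON ``null``.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import numpy as np

SCHEMA_VERSION = 1

# populated lazily to avoid circular imports
_REGISTRY: dict[str, type] = {}


def register_result(cls: type) -> type:
    """Class decorator registering a result dataclass for round-tripping."""
    _REGISTRY[cls.__name__] = cls
    return cls


def _encode(obj: Any) -> Any:
    if obj is None:
        return None
    if isinstance(obj, np.ndarray):
        return {
            "__array__": True,
            "shape": list(obj.shape),
            "data": [_encode(v) for v in np.asarray(obj, dtype=float).ravel().tolist()],
        }
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if math.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _encode(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_encode(v) for v in obj]
    return obj


def _decode(obj: Any) -> Any:
    if isinstance(obj, dict):
        if obj.get("__array__"):
            flat = [math.nan if v is None else float(v) for v in obj["data"]]
            return np.asarray(flat, dtype=float).reshape(obj["shape"])
        return {k: _decode(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode(v) for v in obj]
    return obj


def write_results(record: Any, out_path: str | Path) -> Path:
    """Serialize a registered result record to JSON.

    The envelope carries the schema version, record type, and -- when the
    record exposes one -- the RNG seed that produced it.
    """
    out_path = Path(out_path)
    cls_name = type(record).__name__
    if cls_name not in _REGISTRY:
        raise TypeError(f"{cls_name} is not a registered result type")
    envelope = {
        "schema_version": SCHEMA_VERSION,
        "record_type": cls_name,
        "seed": _encode(getattr(record, "seed", None)),
        "payload": _encode(record.to_dict()),
    }
    try:
        out_path.write_text(json.dumps(envelope, indent=1, allow_nan=False))
    except OSError as exc:
        raise OSError(f"cannot write results to {out_path}: {exc}") from exc
    return out_path


def read_results(path: str | Path) -> Any:
    """Read a record written by :func:`write_results` back into its dataclass."""
    envelope = json.loads(Path(path).read_text())
    cls = _REGISTRY.get(envelope["record_type"])
    if cls is None:
        raise TypeError(f"unknown record type {envelope['record_type']!r}")
    return cls.from_dict(_decode(envelope["payload"]))
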