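"""Reading and writing censored samples and result documents.

Samples travel as CSV: either two columns (time, removed) carrying the full
scheme, or a single time column accompanied by a separate scheme.  Result
documents are JSON and embed the seed, the options used and a SHA-256 hash
of the input data, so every run is self-describing and re-runnable.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .censoring import CensoredSample, ProgressiveScheme

__all__ = ["read_sample", "write_sample", "data_hash", "write_result"]


def read_sample(path, scheme: ProgressiveScheme | None = None) -> CensoredSample:
    """Parse a censored sample from CSV.

    Two-column input (``time, removed``) defines the scheme implicitly with
    ``n = m + sum(removed)``; one-column input requires ``scheme``.  All
    sample invariants (positivity, strict ordering, removal accounting) are
    validated with descriptive errors.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if "time" in cols:
        times = df["time"].to_numpy(dtype=float)
    else:
        times = df.iloc[:, 0].to_numpy(dtype=float)
    if np.any(~np.isfinite(times)):
        raise ValueError(f"{path}: times contain NaN or infinite values")
    if np.any(times <= 0):
        raise ValueError(f"{path}: times must be strictly positive")
    if np.any(np.diff(times) <= 0):
        raise ValueError(f"{path}: times must be sorted strictly ascending")

    removal_col = next((c for c in cols if c in ("removed", "removals", "r")), None)
    if removal_col is not None:
        removals = tuple(int(v) for v in df[removal_col])
        m = len(removals)
        scheme = ProgressiveScheme(m + sum(removals), m, removals)
    elif scheme is None:
        raise ValueError(
            f"{path}: single-column input needs an explicit removal scheme"
        )
    if scheme.m != times.size:
        raise ValueError(
            f"{path}: {times.size} times but scheme expects m={scheme.m}"
        )
    return CensoredSample(tuple(times), scheme)


def write_sample(sample: CensoredSample, path) -> None:
    pd.DataFrame(
        {"time": sample.y, "removed": sample.scheme.removals}
    ).to_csv(path, index=False)


def data_hash(values) -> str:
    arr = np.ascontiguousarray(np.asarray(values, dtype=float))
    return hashlib.sha256(arr.tobytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_result(document: dict, path) -> None:
    """Write a result document as deterministic, sorted-key JSON."""
    with open(path, "w") as fh:
        json.dump(_jsonable(document), fh, indent=2, sort_keys=True)
        fh.write("\n")
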