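"""Orientation-signal container and CSV round-tripping.

A recording channel is a uniformly sampled sequence of angular values
(degrees) with a sampling rate and provenance tags (subject, activity,
body part, axis). Missing samples are encoded as NaN.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class OrientationSignal:
    """One channel of sampled angular data.

    Parameters
    ----------
    values : ndarray of float
        Angular samples in degrees. NaN marks a missing sample.
    fs : float
        Sampling rate in Hz (100 for the target recordings).
    meta : dict
        Provenance tags: subject, activity, body_part, axis, seed, ...
    """

    values: np.ndarray
    fs: float = 100.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if self.values.size < 2:
            raise ValueError("signal must have at least 2 samples")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration_s(self) -> float:
        return self.values.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) / self.fs

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())

    def with_values(self, values: np.ndarray) -> "OrientationSignal":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_csv(self, path: str | Path, manifest: bool = True) -> None:
        """Write `t,value` CSV plus a JSON sidecar with fs and meta tags."""
        path = Path(path)
        pd.DataFrame({"t": self.times, "value": self.values}).to_csv(
            path, index=False
        )
        if manifest:
            sidecar = path.with_suffix(".json")
            sidecar.write_text(
                json.dumps({"fs": self.fs, "meta": self.meta}, indent=2, sort_keys=True)
            )

    @classmethod
    def from_csv(cls, path: str | Path, fs: float | None = None) -> "OrientationSignal":
        path = Path(path)
        df = pd.read_csv(path)
        if "value" not in df.columns:
            raise ValueError(f"{path}: required column 'value' not found "
                             f"(columns: {list(df.columns)})")
        meta: dict = {}
        sidecar = path.with_suffix(".json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            meta = payload.get("meta", {})
            if fs is None:
                fs = payload.get("fs")
        if fs is None:
            if "t" in df.columns and len(df) >= 2:
                dt = np.median(np.diff(df["t"].to_numpy()))
                fs = 1.0 / dt
            else:
                fs = 100.0
        return cls(values=df["value"].to_numpy(dtype=float), fs=float(fs), meta=meta)
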