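"""Single-channel EEG-like time series container and plain-text I/O.

An :class:`EEGBlock` is one fixed-rate scalar recording block (by default
40 s at 125 Hz, i.e. 5000 samples) together with its sampling rate and
optional condition (eyes-closed / eyes-open) and group (control /
Alzheimer's disease) labels.  Blocks round-trip through a two-column CSV
(``time_s,value``) with a JSON sidecar carrying provenance (sampling rate,
generator parameters, seeds).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["EEGBlock", "read_block", "write_block"]


@dataclass
class EEGBlock:
    """One scalar EEG-like recording block.

    Parameters
    ----------
    data : ndarray
        Samples, shape ``(n,)``.
    fs : float
        Sampling rate in Hz.
    condition : str, optional
        Recording condition label, e.g. ``"EC"`` or ``"EO"``.
    group : str, optional
        Subject group label, e.g. ``"CTL"`` or ``"AD"``.
    meta : dict
        Free-form provenance (generator parameters, seed, ...).
    """

    data: np.ndarray
    fs: float = 125.0
    condition: str | None = None
    group: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("EEGBlock data must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Block length in seconds."""
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def normalized(self) -> "EEGBlock":
        """Return a copy scaled to zero mean and unit standard deviation."""
        sd = float(np.std(self.data))
        if sd == 0:
            raise ValueError("cannot normalize a constant block")
        data = (self.data - np.mean(self.data)) / sd
        return EEGBlock(data, self.fs, self.condition, self.group, dict(self.meta))

    def copy(self) -> "EEGBlock":
        return EEGBlock(
            self.data.copy(), self.fs, self.condition, self.group, dict(self.meta)
        )


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_block(block: EEGBlock, path: str | Path) -> Path:
    """Write a block as ``time_s,value`` CSV plus a JSON provenance sidecar.

    Returns the sidecar path.
    """
    path = Path(path)
    df = pd.DataFrame({"time_s": block.times, "value": block.data})
    df.to_csv(path, index=False, float_format="%.10g")
    sidecar = {
        "fs": block.fs,
        "n_samples": block.n_samples,
        "condition": block.condition,
        "group": block.group,
        "meta": _jsonable(block.meta),
    }
    sc_path = _sidecar_path(path)
    sc_path.write_text(json.dumps(sidecar, indent=2))
    return sc_path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def read_block(path: str | Path) -> EEGBlock:
    """Read a block written by :func:`write_block`.

    If the JSON sidecar is absent the sampling rate is inferred from the
    ``time_s`` column.
    """
    path = Path(path)
    df = pd.read_csv(path)
    data = df["value"].to_numpy(dtype=float)
    sc_path = _sidecar_path(path)
    if sc_path.exists():
        sc = json.loads(sc_path.read_text())
        return EEGBlock(
            data,
            fs=float(sc["fs"]),
            condition=sc.get("condition"),
            group=sc.get("group"),
            meta=sc.get("meta") or {},
        )
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.median(np.diff(t))
    return EEGBlock(data, fs=1.0 / dt)
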