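"""Time-delay phase-space reconstruction and delay selection.

A scalar series ``x(n)`` is embedded as delay vectors
``[x(n), x(n+T), ..., x(n+(d-1)T)]``.  The delay ``T`` is chosen as the
first local minimum of the average mutual information (AMI)

.. math::

    I(T) = \\sum P(x(n), x(n+T))\\,
           \\log_2 \\frac{P(x(n), x(n+T))}{P(x(n))\\,P(x(n+T))}

estimated from a 20x20 uniform-bin joint histogram spanning the series
range.  AMI is reported in bits (log base 2), matching the usual
convention for this statistic; if no interior minimum exists up to the
maximum lag, ``T = 2`` is used as the standard fallback.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .block import EEGBlock

__all__ = [
    "AMIProfile",
    "EmbeddingConfig",
    "average_mutual_information",
    "select_delay",
    "delay_embed",
]

logger = logging.getLogger(__name__)


@dataclass
class AMIProfile:
    """AMI values (bits) at lags ``0..T_max``."""

    lags: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have the same shape")


@dataclass(frozen=True)
class EmbeddingConfig:
    """Delay ``T`` (samples), dimension ``d`` and AMI histogram bins."""

    T: int
    d: int = 2
    n_bins: int = 20

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ValueError("delay T must be >= 1")
        if self.d < 2:
            raise ValueError("embedding dimension d must be >= 2")


def _as_series(series) -> np.ndarray:
    if isinstance(series, EEGBlock):
        return series.data
    return np.asarray(series, dtype=float)


def average_mutual_information(series, t_max: int = 50,
                               n_bins: int = 20) -> AMIProfile:
    """AMI (bits) of the series against its lagged copy, lags ``0..t_max``.

    The joint histogram uses ``n_bins`` uniform bins spanning the full
    series range on both axes; zero-count cells contribute nothing.
    At lag 0 the joint distribution is diagonal and the AMI equals the
    binned marginal entropy.
    """
    x = _as_series(series)
    if x.size < 10 * t_max:
        raise ValueError(
            f"series of {x.size} samples too short for t_max={t_max} "
            f"(need >= {10 * t_max})"
        )
    lo, hi = float(np.min(x)), float(np.max(x))
    lags = np.arange(t_max + 1)
    if lo == hi:
        warnings.warn("constant series: AMI profile is identically zero")
        return AMIProfile(lags, np.zeros(t_max + 1))
    edges = np.linspace(lo, hi, n_bins + 1)
    values = np.empty(t_max + 1)
    for t in lags:
        a = x[: x.size - t]
        b = x[t:]
        joint, _, _ = np.histogram2d(a, b, bins=(edges, edges))
        p = joint / joint.sum()
        pr = p.sum(axis=1, keepdims=True)
        pc = p.sum(axis=0, keepdims=True)
        nz = p > 0
        values[t] = float(np.sum(p[nz] * np.log2(p[nz] / (pr @ pc)[nz])))
    return AMIProfile(lags, values)


def select_delay(profile: AMIProfile) -> int:
    """First interior minimum of the AMI profile, or the fallback delay 2.

    Returns the smallest ``T >= 1`` with ``I(T-1) > I(T) < I(T+1)``.
    When the profile has no interior minimum up to its maximum lag the
    conventional fallback ``T = 2`` is returned (logged).
    """
    v = profile.values
    if v.size < 3:
        raise ValueError("profile needs at least 3 lags")
    for t in range(1, v.size - 1):
        if v[t - 1] > v[t] < v[t + 1]:
            return int(profile.lags[t])
    logger.info("AMI profile has no interior minimum; falling back to T=2")
    return 2


def delay_embed(series, cfg: EmbeddingConfig) -> np.ndarray:
    """Trajectory matrix of delay vectors; row ``n`` is
    ``[x(n), x(n+T), ..., x(n+(d-1)T)]``.

    The matrix has ``len(series) - (d-1)*T`` rows and ``d`` columns.
    """
    x = _as_series(series)
    span = (cfg.d - 1) * cfg.T
    n_rows = x.size - span
    if n_rows < 1:
        raise ValueError(
            f"series of {x.size} samples too short: need > {span} "
            f"for d={cfg.d}, T={cfg.T}"
        )
    return np.column_stack([x[j * cfg.T: j * cfg.T + n_rows] for j in range(cfg.d)])
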