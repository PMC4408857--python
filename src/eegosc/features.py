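"""Spectral and entropic features of one EEG block.

Three feature families drive the model-matching objective:

* fractional power in the seven canonical EEG frequency bands, from an
  averaged short-time periodogram (Welch, Hann window),
* Shannon entropy of the amplitude histogram (10 uniform bins spanning
  the data range, natural log),
* sample entropy SampEn(m=2, r=0.25*sigma) with *Euclidean* template
  distance.

All three are invariant to the amplitude scale of the block: histogram
bins and AMI bins span the observed range, and the SampEn tolerance is a
multiple of the block standard deviation.  Blocks are nevertheless
normalized to unit SD in :func:`feature_vector` so that stored features
are comparable across sources.

SampEn is conventionally defined with a Chebyshev (max-coordinate)
distance; the Euclidean variant used here counts fewer matches at the
same ``r`` and therefore reads slightly higher.  A ``metric`` switch
allows cross-checks against standard implementations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy import signal

from .block import EEGBlock

__all__ = [
    "BandDefinition",
    "BANDS",
    "SampEnConfig",
    "FeatureVector",
    "band_powers",
    "shannon_entropy",
    "sample_entropy",
    "feature_vector",
]


@dataclass(frozen=True)
class BandDefinition:
    """One named EEG frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float


#: The seven canonical bands.  Intervals are [lo, hi) except gamma which
#: is closed at 60 Hz (the hardware band limit).
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("lower_delta", 1.0, 2.0),
    BandDefinition("upper_delta", 2.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("lower_beta", 13.0, 20.0),
    BandDefinition("upper_beta", 20.0, 30.0),
    BandDefinition("gamma", 30.0, 60.0),
)

BAND_NAMES = tuple(b.name for b in BANDS)


@dataclass(frozen=True)
class SampEnConfig:
    """Sample-entropy settings: run length ``m`` and tolerance ``r_factor*sigma``."""

    m: int = 2
    r_factor: float = 0.25
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be positive")
        if self.metric not in ("euclidean", "chebyshev"):
            raise ValueError("metric must be 'euclidean' or 'chebyshev'")


@dataclass(frozen=True)
class FeatureVector:
    """Band-power fractions plus the two entropies for one block."""

    band_powers: np.ndarray  # 7 fractions of total 1-60 Hz power
    shannon: float           # nats
    sampen: float            # unitless; may be +inf when no (m+1)-matches exist

    def __post_init__(self) -> None:
        bp = np.asarray(self.band_powers, dtype=float)
        object.__setattr__(self, "band_powers", bp)
        if bp.shape != (len(BANDS),):
            raise ValueError(f"expected {len(BANDS)} band powers, got {bp.shape}")
        if np.any(bp < -1e-12):
            raise ValueError("band powers must be non-negative")
        if abs(bp.sum() - 1.0) > 1e-6:
            raise ValueError("fractional band powers must sum to 1")
        if self.shannon < 0 or self.shannon > math.log(10) + 1e-9:
            raise ValueError("shannon entropy outside [0, ln 10]")
        if self.sampen < 0:
            raise ValueError("sample entropy must be non-negative")

    def as_dict(self) -> dict:
        return {
            "band_powers": {n: float(v) for n, v in zip(BAND_NAMES, self.band_powers)},
            "shannon": float(self.shannon),
            "sampen": float(self.sampen),
        }


def band_powers(block: EEGBlock, bands: tuple[BandDefinition, ...] = BANDS,
                window_s: float = 2.0, overlap: float = 0.5) -> np.ndarray:
    """Fractional band powers from an averaged windowed periodogram.

    A Hann-windowed Welch estimate with ``window_s``-second segments and
    fractional ``overlap`` is integrated over each band; powers are
    returned as fractions of the total power over all bands (1-60 Hz).
    The 2-s default window gives 0.5 Hz resolution, enough to resolve the
    1 Hz wide lower-delta band.
    """
    x = block.data
    nperseg = int(round(window_s * block.fs))
    if x.size < nperseg:
        raise ValueError(
            f"block of {x.size} samples shorter than one {nperseg}-sample window"
        )
    f, psd = signal.welch(
        x, fs=block.fs, window="hann", nperseg=nperseg,
        noverlap=int(round(nperseg * overlap)), detrend="constant",
    )
    powers = np.empty(len(bands))
    for i, b in enumerate(bands):
        if b is bands[-1]:
            sel = (f >= b.lo) & (f <= b.hi)
        else:
            sel = (f >= b.lo) & (f < b.hi)
        powers[i] = psd[sel].sum()
    total = powers.sum()
    if total <= 0:
        raise ValueError("block has no power in 1-60 Hz")
    return powers / total


def shannon_entropy(block: EEGBlock | np.ndarray, n_bins: int = 10) -> float:
    """Shannon entropy (nats) of the amplitude histogram.

    ``n_bins`` uniform bins span ``[min, max]`` of the data; empty bins
    contribute zero.  A constant block has zero entropy by convention
    (warned).  The maximum is ``ln(n_bins)``.
    """
    x = block.data if isinstance(block, EEGBlock) else np.asarray(block, float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if lo == hi:
        warnings.warn("constant block: Shannon entropy is 0 by convention")
        return 0.0
    counts, _ = np.histogram(x, bins=n_bins, range=(lo, hi))
    p = counts[counts > 0] / x.size
    return float(-(p * np.log(p)).sum())


@njit(cache=False)
def _sampen_pairs(x, m, r2, chebyshev):  # pragma: no cover - jitted
    """Unordered template pair counts at lengths m (B) and m+1 (A).

    Templates of length q start at i = 0..N-q-1 (the last valid start is
    deliberately excluded, following the printed normalization
    1/((N-q)(N-q-1))).  With a Euclidean metric an (m+1)-match implies an
    m-match, so both levels are counted in one pass; ``r2`` is r squared
    (Euclidean) or r (Chebyshev).
    """
    n = x.shape[0]
    n_m = n - m          # number of length-m templates
    b_count = 0
    a_count = 0
    for i in range(n_m - 1):
        for k in range(i + 1, n_m):
            d = 0.0
            if chebyshev:
                for j in range(m):
                    dj = abs(x[i + j] - x[k + j])
                    if dj > d:
                        d = dj
            else:
                for j in range(m):
                    dj = x[i + j] - x[k + j]
                    d += dj * dj
            if d <= r2:
                b_count += 1
                if i < n_m - 1 and k < n_m - 1:
                    if chebyshev:
                        dj = abs(x[i + m] - x[k + m])
                        if dj > d:
                            d = dj
                    else:
                        dj = x[i + m] - x[k + m]
                        d += dj * dj
                    if d <= r2:
                        a_count += 1
    return b_count, a_count


def sample_entropy(block: EEGBlock | np.ndarray,
                   cfg: SampEnConfig = SampEnConfig()) -> float:
    """SampEn(m, r) = -ln(U^{m+1}(r) / U^m(r)).

    ``U^q(r)`` is the fraction of ordered template pairs (i != k, both in
    the first N-q starts) whose distance is at most ``r = r_factor *
    sigma`` with sigma the standard deviation of the block itself.
    Returns ``+inf`` when no (m+1)-length match exists.
    """
    x = np.asarray(block.data if isinstance(block, EEGBlock) else block, float)
    n = x.size
    m = cfg.m
    if n <= m + 1:
        raise ValueError(f"need more than m+1={m + 1} samples, got {n}")
    sigma = float(np.std(x))
    if sigma == 0:
        raise ValueError("constant block: sample-entropy tolerance r would be 0")
    r = cfg.r_factor * sigma
    cheb = cfg.metric == "chebyshev"
    b_count, a_count = _sampen_pairs(x, m, r if cheb else r * r, cheb)
    if b_count == 0 or a_count == 0:
        return float("inf")
    u_m = 2.0 * b_count / ((n - m) * (n - m - 1.0))
    u_m1 = 2.0 * a_count / ((n - m - 1.0) * (n - m - 2.0))
    return float(-math.log(u_m1 / u_m))


def feature_vector(block: EEGBlock,
                   sampen_cfg: SampEnConfig = SampEnConfig(),
                   n_bins: int = 10) -> FeatureVector:
    """Bundle the three feature families for one block.

    The block is normalized to zero mean / unit SD first; the features
    themselves are scale-invariant, so this only fixes the stored scale.
    """
    norm = block.normalized()
    return FeatureVector(
        band_powers=band_powers(norm),
        shannon=shannon_entropy(norm, n_bins=n_bins),
        sampen=sample_entropy(norm, sampen_cfg),
    )
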