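"""Synthetic EEG-like surrogate blocks and study-shaped datasets.

The study's recordings are not public, so every pipeline input is
generated here with the statistical structure the analysis assumes:

* *surrogate* blocks — band-limited Gaussian noise shaped to a target
  fractional band-power profile plus a 1/f broadband floor, emulating
  resting eyes-closed (EC) / eyes-open (EO) spectra of control (CTL) and
  Alzheimer's (AD) subjects: EC-CTL alpha-dominant, EC-AD slightly
  theta-dominant, EO flat from upper-delta to lower-beta;
* *model* blocks — direct simulations of the stochastic oscillator pair
  at known parameters, the ground truth for fit-recovery tests;
* *artifact injection* — smooth high-amplitude transients (eye/muscle
  artifact lookalikes) with a ground-truth mask for the 4.5-sigma
  detection and spectral-repair stage.

Default condition profiles are free choices constrained by the
qualitative spectral descriptions above; they are configuration data and
can be overridden or loaded from YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

from .block import EEGBlock
from .features import BANDS, BAND_NAMES
from .model import OscillatorParams, SimulationConfig, simulate_em

__all__ = [
    "SurrogateProfile",
    "ArtifactSpec",
    "CONDITION_PARAMS",
    "DEFAULT_PROFILES",
    "generate_surrogate_blocks",
    "generate_model_blocks",
    "inject_artifacts",
    "generate_study_dataset",
    "load_profiles",
]

#: Published group-mean oscillator parameters for the four condition
#: groups, used as simulation inputs (velocity-of-oscillator-2 output).
CONDITION_PARAMS: dict[str, OscillatorParams] = {
    "EC-CTL": OscillatorParams(7286.5, 4523.5, 232.05, 10.78, 33.60, 0.97, 2.34),
    "EO-CTL": OscillatorParams(2427.2, 499.92, 95.61, 103.36, 48.89, 28.75, 1.82),
    "EC-AD": OscillatorParams(1742.1, 1270.8, 771.99, 1.91, 63.7, 20.7, 1.78),
    "EO-AD": OscillatorParams(3139.9, 650.32, 101.1, 81.3, 56.3, 19.12, 1.74),
}


@dataclass(frozen=True)
class SurrogateProfile:
    """Target spectral make-up of one condition's surrogate blocks.

    ``band_fractions`` are the 7 fractional band powers (lower-delta,
    upper-delta, theta, alpha, lower-beta, upper-beta, gamma) of the
    generated blocks; ``noise_floor`` is the fraction of total power
    carried by a broadband 1/f component (its in-band share counts
    toward the fractions, so the realized spectrum matches
    ``band_fractions``).
    """

    condition: str
    band_fractions: tuple
    noise_floor: float = 0.3
    fs: float = 125.0
    duration: float = 40.0

    def __post_init__(self) -> None:
        bf = np.asarray(self.band_fractions, dtype=float)
        if bf.shape != (len(BANDS),):
            raise ValueError(f"need {len(BANDS)} band fractions")
        if np.any(bf < 0) or abs(bf.sum() - 1.0) > 1e-6:
            raise ValueError("band fractions must be non-negative and sum to 1")
        if not 0 <= self.noise_floor < 1:
            raise ValueError("noise_floor must be in [0, 1)")
        object.__setattr__(self, "band_fractions", tuple(bf))


#: Default profiles for the four study conditions (free choices bounded
#: by the qualitative descriptions: EC-CTL alpha-dominant, EC-AD theta >=
#: alpha, EO flat with no band above 0.35 across upper-delta..lower-beta).
DEFAULT_PROFILES: dict[str, SurrogateProfile] = {
    "EC-CTL": SurrogateProfile("EC-CTL", (0.02, 0.06, 0.16, 0.42, 0.16, 0.10, 0.08)),
    "EO-CTL": SurrogateProfile("EO-CTL", (0.04, 0.20, 0.23, 0.22, 0.19, 0.08, 0.04)),
    "EC-AD": SurrogateProfile("EC-AD", (0.03, 0.08, 0.33, 0.26, 0.15, 0.09, 0.06)),
    "EO-AD": SurrogateProfile("EO-AD", (0.05, 0.22, 0.25, 0.20, 0.16, 0.08, 0.04)),
}


@dataclass(frozen=True)
class ArtifactSpec:
    """Injected transient artifacts: ``rate`` bumps per block of the
    given amplitude (multiples of the clean block SD) and width."""

    rate: int = 3
    amplitude: float = 8.0
    width: int = 12

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be non-negative")
        if self.amplitude <= 4.5:
            raise ValueError(
                "amplitude must exceed 4.5 so injected artifacts are "
                "detectable by the 4.5-sigma rule"
            )
        if self.width < 1:
            raise ValueError("width must be >= 1")


def _condition_labels(condition: str) -> tuple[str | None, str | None]:
    if "-" in condition:
        cond, group = condition.split("-", 1)
        return cond, group
    return condition or None, None


def generate_surrogate_blocks(profile: SurrogateProfile, n_blocks: int,
                              seed: int) -> list[EEGBlock]:
    """Model-independent EEG-like blocks matching the profile's spectrum.

    Each block is synthesized in the Fourier domain: a white complex
    Gaussian spectrum is shaped by the square root of the target power
    density (the seven flat band components plus the 1/f floor, all
    restricted to 1-60 Hz), inverse-transformed and normalized to unit
    SD.  Realized fractional band powers average to the profile's
    fractions; per-block deviations shrink with block duration.
    """
    n = int(round(profile.duration * profile.fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / profile.fs)
    in_band = (freqs >= BANDS[0].lo) & (freqs <= BANDS[-1].hi)

    # 1/f floor density over 1-60 Hz, normalized to unit total power
    floor = np.zeros_like(freqs)
    floor[in_band] = 1.0 / freqs[in_band]
    floor /= floor.sum()

    density = profile.noise_floor * floor
    bf = np.asarray(profile.band_fractions)
    for j, band in enumerate(BANDS):
        if band is BANDS[-1]:
            sel = (freqs >= band.lo) & (freqs <= band.hi)
        else:
            sel = (freqs >= band.lo) & (freqs < band.hi)
        floor_share = profile.noise_floor * floor[sel].sum()
        extra = max(bf[j] - floor_share, 0.0)
        if sel.sum():
            density[sel] += extra / sel.sum()

    amp = np.sqrt(density)
    cond, group = _condition_labels(profile.condition)
    rng = np.random.default_rng(seed)
    blocks = []
    for i in range(n_blocks):
        z = rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
        spec = amp * z
        spec[0] = 0.0  # no DC
        x = np.fft.irfft(spec, n=n)
        x = (x - x.mean()) / x.std()
        blocks.append(EEGBlock(
            x, fs=profile.fs, condition=cond, group=group,
            meta={"profile": {
                "condition": profile.condition,
                "band_fractions": {bn: float(v) for bn, v in
                                   zip(BAND_NAMES, profile.band_fractions)},
                "noise_floor": profile.noise_floor,
            }, "seed": seed, "index": i},
        ))
    return blocks


def generate_model_blocks(params: OscillatorParams, n_blocks: int, seed: int,
                          config: SimulationConfig = SimulationConfig(),
                          condition: str = "") -> list[EEGBlock]:
    """Independent oscillator simulations tagged with ground-truth params.

    Block ``i`` uses the derived seed ``seed + i``; the same ``seed``
    regenerates the identical block set.
    """
    cond, group = _condition_labels(condition)
    blocks = []
    for i in range(n_blocks):
        blk = simulate_em(params, replace(config, seed=seed + i))
        blk.condition, blk.group = cond, group
        blk.meta["index"] = i
        blocks.append(blk)
    return blocks


def inject_artifacts(block: EEGBlock, spec: ArtifactSpec,
                     seed: int) -> tuple[EEGBlock, np.ndarray]:
    """Add smooth high-amplitude transients; return (block, truth mask).

    Bumps are Hann-windowed pulses of ``spec.amplitude`` clean-block SDs
    and ``spec.width`` samples, at uniformly drawn non-overlapping
    positions (re-drawn on collision, at most 100 attempts each).
    """
    out = block.copy()
    mask = np.zeros(block.n_samples, dtype=bool)
    if spec.rate == 0:
        return out, mask
    rng = np.random.default_rng(seed)
    sigma = float(np.std(block.data))
    bump = np.hanning(spec.width + 2)[1:-1]  # strictly positive interior
    for _ in range(spec.rate):
        for _attempt in range(100):
            pos = int(rng.integers(0, block.n_samples - spec.width))
            if not mask[pos: pos + spec.width].any():
                break
        else:
            raise RuntimeError("could not place a non-overlapping artifact")
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[pos: pos + spec.width] += sign * spec.amplitude * sigma * bump
        mask[pos: pos + spec.width] = True
    out.meta = {**out.meta, "injected_artifacts": int(spec.rate)}
    return out, mask


def generate_study_dataset(seed: int,
                           profiles: dict[str, SurrogateProfile] | None = None,
                           group_sizes: dict[str, int] | None = None
                           ) -> list[EEGBlock]:
    """Study-shaped surrogate dataset.

    Defaults mirror the study design: 20 EC and 20 EO blocks from
    controls, 10 EC and 10 EO blocks from AD subjects (60 blocks of 40 s
    at 125 Hz).  Per-condition generator seeds are derived from ``seed``.
    """
    profiles = profiles or DEFAULT_PROFILES
    group_sizes = group_sizes or {"EC-CTL": 20, "EO-CTL": 20,
                                  "EC-AD": 10, "EO-AD": 10}
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(group_sizes)) % (2**31 - 1)
    blocks = []
    for (condition, n), child in zip(sorted(group_sizes.items()), child_seeds):
        blocks.extend(
            generate_surrogate_blocks(profiles[condition], n, int(child))
        )
    return blocks


def load_profiles(path) -> dict[str, SurrogateProfile]:
    """Load condition profiles from a YAML mapping
    ``{condition: {band_fractions: [...7...], noise_floor: f}}``."""
    raw = yaml.safe_load(open(path))
    out = {}
    for condition, cfg in raw.items():
        out[condition] = SurrogateProfile(
            condition=condition,
            band_fractions=tuple(cfg["band_fractions"]),
            noise_floor=float(cfg.get("noise_floor", 0.3)),
            fs=float(cfg.get("fs", 125.0)),
            duration=float(cfg.get("duration", 40.0)),
        )
    return out
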