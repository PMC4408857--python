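"""Stochastic coupled Duffing-van der Pol oscillator pair.

The EEG-like signal is modeled as the output of two coupled second-order
oscillators, each combining a cubic (Duffing) stiffness term with van der
Pol self-excited damping, driven by additive white noise on the second
oscillator's velocity:

.. math::

    \\ddot x_1 + (k_1+k_2)x_1 - k_2 x_2 &=
        -b_1 x_1^3 - b_2 (x_1-x_2)^3 + \\epsilon_1 \\dot x_1 (1-x_1^2) \\\\
    \\ddot x_2 - k_2 x_1 + k_2 x_2 &=
        b_2 (x_1-x_2)^3 + \\epsilon_2 \\dot x_2 (1-x_2^2) + \\mu\\, dW

with :math:`dW` a Wiener increment.  The system is integrated by the
explicit Euler-Maruyama scheme on a fine internal grid (``substeps``
internal steps per output sample) and the velocity of the second
oscillator, which receives the noise directly, is taken as the simulated
EEG channel.

Stiffness values up to :math:`10^4` 1/s^2 give angular frequencies around
100 rad/s, so integrating directly on the 125 Hz output grid (h = 8 ms)
is marginally stable for explicit Euler; the default of 10 internal
substeps (h = 0.8 ms) keeps the scheme well inside its stability region.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numba import njit

from .block import EEGBlock

__all__ = [
    "OscillatorParams",
    "OscillatorState",
    "SimulationConfig",
    "SimulationBlowUp",
    "drift",
    "simulate_em",
    "convergence_check",
]

_CHANNELS = ("x1", "v1", "x2", "v2")


@dataclass(frozen=True)
class OscillatorParams:
    """The seven physical decision variables of the oscillator pair.

    ``k1, k2`` linear stiffness (1/s^2), ``b1, b2`` cubic (Duffing)
    stiffness, ``eps1, eps2`` van der Pol damping coefficients, ``mu``
    white-noise intensity.  All must be positive except ``mu`` which may
    be zero.  The tighter feasibility box used by the fitter
    (``b_i <= k_i/2`` etc.) is enforced separately by
    :func:`eegosc.fitting.check_bounds`.
    """

    k1: float
    k2: float
    b1: float
    b2: float
    eps1: float
    eps2: float
    mu: float

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"non-finite oscillator parameters: {self}")
        if min(self.k1, self.k2, self.b1, self.b2, self.eps1, self.eps2) <= 0:
            raise ValueError("k, b and eps parameters must be strictly positive")
        if self.mu < 0:
            raise ValueError("noise intensity mu must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.k1, self.k2, self.b1, self.b2, self.eps1, self.eps2, self.mu]
        )

    @classmethod
    def from_array(cls, arr) -> "OscillatorParams":
        return cls(*map(float, arr))

    def as_dict(self) -> dict:
        return {
            "k1": self.k1, "k2": self.k2, "b1": self.b1, "b2": self.b2,
            "eps1": self.eps1, "eps2": self.eps2, "mu": self.mu,
        }

    @property
    def names(self) -> tuple[str, ...]:
        return PARAM_NAMES


PARAM_NAMES = ("k1", "k2", "b1", "b2", "eps1", "eps2", "mu")


@dataclass(frozen=True)
class OscillatorState:
    """Positions and velocities of the two oscillators."""

    x1: float = 0.0
    v1: float = 0.0
    x2: float = 0.0
    v2: float = 0.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, self.as_tuple())):
            raise ValueError(f"non-finite oscillator state: {self}")

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.x1, self.v1, self.x2, self.v2)


@dataclass(frozen=True)
class SimulationConfig:
    """Integration settings for :func:`simulate_em`.

    ``fs`` output sampling rate (Hz); ``duration`` returned block length
    (s); ``substeps`` internal Euler-Maruyama steps per output sample;
    ``burn_in`` seconds simulated before the returned block and discarded
    (removes dependence on the arbitrary zero initial state);
    ``output_channel`` one of ``x1, v1, x2, v2``.
    """

    fs: float = 125.0
    duration: float = 40.0
    substeps: int = 10
    seed: int = 0
    initial_state: OscillatorState = field(default_factory=OscillatorState)
    output_channel: str = "v2"
    burn_in: float = 2.0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")
        if self.output_channel not in _CHANNELS:
            raise ValueError(f"output_channel must be one of {_CHANNELS}")
        if self.burn_in < 0:
            raise ValueError("burn_in must be non-negative")


class SimulationBlowUp(RuntimeError):
    """Raised when the integrator leaves the finite range.

    Carries the internal step index and the offending parameters so that
    an optimizer can convert the failure into a penalty.
    """

    def __init__(self, step: int, params: OscillatorParams):
        self.step = step
        self.params = params
        super().__init__(
            f"non-finite state at internal step {step} for params {params}"
        )


def drift(state: OscillatorState, params: OscillatorParams) -> tuple:
    """Deterministic drift (x1', v1', x2', v2') of the coupled system.

    The stochastic term ``mu dW`` is *not* included here; the integrator
    adds it to the second oscillator's velocity only.
    """
    if not all(map(math.isfinite, state.as_tuple())):
        raise ValueError(f"non-finite state: {state}")
    x1, v1, x2, v2 = state.as_tuple()
    p = params
    rel = x1 - x2
    a1 = (
        -(p.k1 + p.k2) * x1
        + p.k2 * x2
        - p.b1 * x1**3
        - p.b2 * rel**3
        + p.eps1 * v1 * (1.0 - x1 * x1)
    )
    a2 = p.k2 * x1 - p.k2 * x2 + p.b2 * rel**3 + p.eps2 * v2 * (1.0 - x2 * x2)
    return (v1, a1, v2, a2)


@njit(cache=False)
def _em_kernel(k1, k2, b1, b2, e1, e2, mu, h, substeps, noise,
               x1, v1, x2, v2, channel, out):  # pragma: no cover - jitted
    sqh = math.sqrt(h)
    n_internal = noise.shape[0]
    j = 0
    for i in range(n_internal):
        rel = x1 - x2
        a1 = (-(k1 + k2) * x1 + k2 * x2 - b1 * x1 ** 3 - b2 * rel ** 3
              + e1 * v1 * (1.0 - x1 * x1))
        a2 = (k2 * x1 - k2 * x2 + b2 * rel ** 3
              + e2 * v2 * (1.0 - x2 * x2))
        x1 = x1 + h * v1
        v1 = v1 + h * a1
        x2 = x2 + h * v2
        v2 = v2 + h * a2 + mu * sqh * noise[i]
        if not (math.isfinite(x1) and math.isfinite(v1)
                and math.isfinite(x2) and math.isfinite(v2)):
            return i, x1, v1, x2, v2
        if (i + 1) % substeps == 0:
            if channel == 0:
                out[j] = x1
            elif channel == 1:
                out[j] = v1
            elif channel == 2:
                out[j] = x2
            else:
                out[j] = v2
            j += 1
    return -1, x1, v1, x2, v2


def _run_kernel(params: OscillatorParams, config: SimulationConfig,
                noise: np.ndarray, n_out: int):
    h = 1.0 / (config.fs * config.substeps)
    out = np.empty(n_out)
    s = config.initial_state
    status, x1, v1, x2, v2 = _em_kernel(
        params.k1, params.k2, params.b1, params.b2,
        params.eps1, params.eps2, params.mu,
        h, config.substeps, noise,
        s.x1, s.v1, s.x2, s.v2,
        _CHANNELS.index(config.output_channel), out,
    )
    if status >= 0:
        raise SimulationBlowUp(status, params)
    return out, OscillatorState(x1, v1, x2, v2)


def simulate_em(params: OscillatorParams, config: SimulationConfig) -> EEGBlock:
    """Integrate the stochastic system and return the sampled output channel.

    The internal step is ``h = 1/(fs*substeps)``; per internal step the
    second oscillator's velocity receives ``mu*sqrt(h)*z`` with ``z`` a
    standard normal draw.  The internal trajectory is decimated to ``fs``.
    ``burn_in`` seconds are simulated first and discarded.  Identical
    ``(params, config)`` (including seed) give bit-identical output.
    """
    n_burn = int(round(config.burn_in * config.fs))
    n_keep = int(round(config.duration * config.fs))
    n_out = n_burn + n_keep
    rng = np.random.default_rng(config.seed)
    noise = rng.standard_normal(n_out * config.substeps)
    out, _ = _run_kernel(params, config, noise, n_out)
    return EEGBlock(
        out[n_burn:],
        fs=config.fs,
        meta={
            "params": params.as_dict(),
            "seed": config.seed,
            "substeps": config.substeps,
            "burn_in": config.burn_in,
            "output_channel": config.output_channel,
        },
    )


def convergence_check(params: OscillatorParams, config: SimulationConfig,
                      horizon: float = 1.0) -> pd.DataFrame:
    """Strong-convergence self-check of the Euler-Maruyama integrator.

    Integrates over a short horizon at ``substeps``, ``2*substeps`` and
    ``4*substeps`` on a *common* Wiener path (increments aggregated from
    the finest grid, ``8*substeps``) and reports the endpoint error
    against the finest solution.  The error must shrink as the step is
    refined; in the deterministic limit (``mu = 0``) the scheme is plain
    explicit Euler with order-1 error.
    """
    if horizon <= 0 or horizon > 2.0:
        raise ValueError("horizon must be in (0, 2] seconds")
    base = config.substeps
    levels = [base, 2 * base, 4 * base]
    finest = 8 * base
    n_out = int(round(horizon * config.fs))
    rng = np.random.default_rng(config.seed)
    fine_noise = rng.standard_normal(n_out * finest)

    def endpoint(substeps: int) -> np.ndarray:
        cfg = replace(config, substeps=substeps, duration=horizon, burn_in=0.0)
        ratio = finest // substeps
        # aggregate fine Wiener increments: sum of `ratio` unit normals,
        # rescaled back to a unit normal at the coarser step
        agg = fine_noise.reshape(-1, ratio).sum(axis=1) / math.sqrt(ratio)
        _, state = _run_kernel(params, cfg, agg, n_out)
        return np.array(state.as_tuple())

    ref = endpoint(finest)
    rows = []
    for s in levels:
        err = float(np.linalg.norm(endpoint(s) - ref))
        rows.append({"substeps": s, "h": 1.0 / (config.fs * s), "endpoint_error": err})
    return pd.DataFrame(rows)
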