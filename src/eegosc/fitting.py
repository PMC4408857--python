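"""Fit oscillator parameters to a target feature vector.

The objective matches the model output to a target block in feature
space:

.. math::

    \\min_p J = \\sum_{j=1}^{m} (P_{Ej} - P_{Oj})^2
             + w_1 |S_E - S_O| + w_2 |SP_E - SP_O|,

where :math:`P_j` are fractional band powers, :math:`S` Shannon and
:math:`SP` sample entropies of the (unit-SD normalized) target and model
output, and :math:`w_1 = w_2 = 0.35` balance entropy against spectrum.
The search is a multi-start bounded derivative-free minimization: starts
are drawn uniformly inside the feasible box

    0 < k_i <= 1e4,   0 < b_i <= k_i/2,   0 < eps_i <= k_i/3,
    0 <= mu <= 2,

and each is refined by Nelder-Mead in a rescaled unit cube in which the
coupled ``b <= k/2`` / ``eps <= k/3`` constraints hold by construction.
The objective is stochastic (fresh Wiener path per simulation); a
``frozen`` noise mode re-uses one set of realization seeds for every
evaluation (common random numbers), which makes the landscape smooth
enough for the simplex to descend reliably, while ``fresh`` redraws the
noise at every evaluation, mirroring a literal per-iteration redraw.
Integration blow-ups are converted to a large penalty so the search
simply avoids that region.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .features import (
    BANDS,
    FeatureVector,
    SampEnConfig,
    band_powers,
    sample_entropy,
    shannon_entropy,
)
from .model import (
    OscillatorParams,
    PARAM_NAMES,
    SimulationConfig,
    SimulationBlowUp,
    simulate_em,
)

__all__ = [
    "ObjectiveWeights",
    "BoundsVerdict",
    "FitResult",
    "K_MAX",
    "MU_MAX",
    "check_bounds",
    "objective",
    "objective_terms",
    "multistart_fit",
]

logger = logging.getLogger(__name__)

K_MAX = 1e4
MU_MAX = 2.0
_PENALTY = 1e6  # objective value assigned to infeasible / blown-up params


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights on the Shannon (w1) and sample-entropy (w2) error terms."""

    w1: float = 0.35
    w2: float = 0.35

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0:
            raise ValueError("weights must be non-negative")


@dataclass(frozen=True)
class BoundsVerdict:
    feasible: bool
    violations: dict = field(default_factory=dict)


def check_bounds(params: OscillatorParams) -> BoundsVerdict:
    """Feasibility of the decision-variable box.

    ``0 < k_i <= 1e4``, ``0 < b_i <= k_i/2``, ``0 < eps_i <= k_i/3``,
    ``0 <= mu <= 2``.  The fractional couplings keep the oscillators out
    of the chaotic regime.
    """
    v: dict[str, str] = {}
    for i, (k, b, e) in enumerate(
        [(params.k1, params.b1, params.eps1), (params.k2, params.b2, params.eps2)],
        start=1,
    ):
        if not (0 < k <= K_MAX):
            v[f"k{i}"] = f"k{i}={k} outside (0, {K_MAX:g}]"
        if not (0 < b <= k / 2):
            v[f"b{i}"] = f"b{i}={b} outside (0, k{i}/2={k / 2:g}]"
        if not (0 < e <= k / 3):
            v[f"eps{i}"] = f"eps{i}={e} outside (0, k{i}/3={k / 3:g}]"
    if not (0 <= params.mu <= MU_MAX):
        v["mu"] = f"mu={params.mu} outside [0, {MU_MAX:g}]"
    return BoundsVerdict(feasible=not v, violations=v)


@dataclass
class FitResult:
    """Best parameters found, objective value and fit provenance."""

    params: OscillatorParams
    J: float
    term_errors: dict
    n_starts: int
    seeds: dict
    n_realizations: int
    n_evals: int = 0
    start_values: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "params": self.params.as_dict(),
            "J": self.J,
            "term_errors": self.term_errors,
            "n_starts": self.n_starts,
            "seeds": self.seeds,
            "n_realizations": self.n_realizations,
            "n_evals": self.n_evals,
            "start_values": self.start_values,
        }


def _average_features(params: OscillatorParams, sim_cfg: SimulationConfig,
                      seeds, sampen_cfg: SampEnConfig) -> dict:
    bp = np.zeros(len(BANDS))
    sh = 0.0
    se = 0.0
    for s in seeds:
        blk = simulate_em(params, replace(sim_cfg, seed=int(s))).normalized()
        bp += band_powers(blk)
        sh += shannon_entropy(blk)
        se += sample_entropy(blk, sampen_cfg)
    n = len(seeds)
    return {"band_powers": bp / n, "shannon": sh / n, "sampen": se / n}


def objective_terms(params: OscillatorParams, target: FeatureVector,
                    weights: ObjectiveWeights, sim_cfg: SimulationConfig,
                    seeds, sampen_cfg: SampEnConfig = SampEnConfig(),
                    band_indices=None) -> tuple[float, dict]:
    """Objective value plus its per-term decomposition.

    ``band_indices`` restricts the squared-error sum to a subset of the
    seven bands (the hardware-reliable five exclude lower-delta and
    gamma); default is all seven.
    """
    if not check_bounds(params).feasible:
        return _PENALTY, {"infeasible": True}
    try:
        feats = _average_features(params, sim_cfg, seeds, sampen_cfg)
    except SimulationBlowUp as exc:
        logger.debug("blow-up during objective evaluation: %s", exc)
        return _PENALTY, {"blow_up": True}
    idx = np.arange(len(BANDS)) if band_indices is None else np.asarray(band_indices)
    band_err = (target.band_powers[idx] - feats["band_powers"][idx]) ** 2
    sh_err = abs(target.shannon - feats["shannon"])
    se_err = abs(target.sampen - feats["sampen"])
    j = float(band_err.sum() + weights.w1 * sh_err + weights.w2 * se_err)
    terms = {
        "band_sq_errors": {BANDS[i].name: float(band_err[k]) for k, i in enumerate(idx)},
        "shannon_abs_error": float(sh_err),
        "sampen_abs_error": float(se_err),
    }
    return j, terms


def objective(params: OscillatorParams, target: FeatureVector,
              weights: ObjectiveWeights, sim_cfg: SimulationConfig,
              n_realizations: int = 5, seeds=None,
              sampen_cfg: SampEnConfig = SampEnConfig(),
              band_indices=None) -> float:
    """Stochastic objective J(p) against a target feature vector.

    Simulates ``n_realizations`` independent outputs (seeded from
    ``sim_cfg.seed`` unless explicit ``seeds`` are given), averages their
    features and evaluates the weighted error above.  Out-of-bounds
    parameters and integration blow-ups return a large penalty.
    """
    if seeds is None:
        seeds = [sim_cfg.seed + i for i in range(n_realizations)]
    j, _ = objective_terms(params, target, weights, sim_cfg, seeds,
                           sampen_cfg, band_indices)
    return j


# Mapping between the feasible box and the unit search cube.  The k's
# span three decades and the admissible b/eps ranges scale with k, so
# the cube is log-scaled: k log-uniform over [K_MIN, K_MAX], b and eps
# log-uniform fractions of their k-dependent caps (down to FRAC_MIN of
# the cap), mu linear over [0, MU_MAX].  Every cube point is feasible by
# construction, uniform sampling covers all scales, and simplex steps
# become multiplicative in the physical parameters.

K_MIN = 10.0     # search floor for k (0.5 Hz); the formal bound is k > 0
FRAC_MIN = 1e-4  # search floor for b/(k/2) and eps/(k/3)


def _cube_to_params(z: np.ndarray) -> OscillatorParams:
    z = np.clip(z, 0.0, 1.0)
    k1 = K_MIN * (K_MAX / K_MIN) ** z[0]
    k2 = K_MIN * (K_MAX / K_MIN) ** z[1]
    return OscillatorParams(
        k1=k1, k2=k2,
        b1=(k1 / 2) * FRAC_MIN ** (1 - z[2]),
        b2=(k2 / 2) * FRAC_MIN ** (1 - z[3]),
        eps1=(k1 / 3) * FRAC_MIN ** (1 - z[4]),
        eps2=(k2 / 3) * FRAC_MIN ** (1 - z[5]),
        mu=z[6] * MU_MAX,
    )


def _params_to_cube(p: OscillatorParams) -> np.ndarray:
    span = math.log(K_MAX / K_MIN)
    return np.array([
        math.log(p.k1 / K_MIN) / span,
        math.log(p.k2 / K_MIN) / span,
        1 - math.log(p.b1 / (p.k1 / 2)) / math.log(FRAC_MIN),
        1 - math.log(p.b2 / (p.k2 / 2)) / math.log(FRAC_MIN),
        1 - math.log(p.eps1 / (p.k1 / 3)) / math.log(FRAC_MIN),
        1 - math.log(p.eps2 / (p.k2 / 3)) / math.log(FRAC_MIN),
        p.mu / MU_MAX,
    ])


def multistart_fit(target: FeatureVector, n_starts: int = 20,
                   weights: ObjectiveWeights = ObjectiveWeights(),
                   sim_cfg: SimulationConfig = SimulationConfig(),
                   seed: int = 0, noise_mode: str = "frozen",
                   n_realizations: int = 5,
                   sampen_cfg: SampEnConfig = SampEnConfig(),
                   band_indices=None, max_evals: int = 500,
                   tol: float = 1e-4, n_candidates: int = 200) -> FitResult:
    """Multi-start bounded Nelder-Mead minimization of the objective.

    Draws ``n_starts`` uniform feasible starting points, refines each
    with a bounded simplex search (at most ``max_evals`` objective
    evaluations per start, function tolerance ``tol``) and returns the
    best feasible result.  Fully reproducible for a given ``seed``.
    """
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    if noise_mode not in ("frozen", "fresh"):
        raise ValueError("noise_mode must be 'frozen' or 'fresh'")
    rng = np.random.default_rng(seed)
    frozen_seeds = [int(s) for s in
                    rng.integers(0, 2**31 - 1, size=n_realizations)]
    eval_counter = [0]

    def eval_seeds():
        if noise_mode == "frozen":
            return frozen_seeds
        return [int(s) for s in rng.integers(0, 2**31 - 1, size=n_realizations)]

    def fun(z):
        eval_counter[0] += 1
        p = _cube_to_params(z)
        return objective(p, target, weights, sim_cfg,
                         seeds=eval_seeds(), sampen_cfg=sampen_cfg,
                         band_indices=band_indices)

    # Candidate filtering: score a uniform pool once and refine only the
    # ``n_starts`` most promising points, in the spirit of multi-start
    # scatter-search methods.  Penalized (blown-up) candidates are never
    # selected, so no simplex is started on the flat penalty plateau.
    # The pool size is independent of ``n_starts`` so that the refined
    # start sets are nested: the best objective is non-increasing in
    # ``n_starts`` for a fixed seed.
    n_candidates = max(n_candidates, n_starts)
    candidates = rng.uniform(0.0, 1.0, size=(n_candidates, 7))
    scores = np.array([fun(z) for z in candidates])
    order = np.argsort(scores)[:n_starts]

    best_z, best_j = None, np.inf
    start_values = []
    for z0 in candidates[order]:
        res = optimize.minimize(
            fun, z0, method="Nelder-Mead",
            bounds=[(0.0, 1.0)] * 7,
            options={"maxfev": max_evals, "fatol": tol, "xatol": 1e-3,
                     "adaptive": True},
        )
        start_values.append(float(res.fun))
        if res.fun < best_j:
            best_j, best_z = float(res.fun), res.x
    if best_z is None or best_j >= _PENALTY:
        raise RuntimeError(
            f"all {n_starts} starts failed (infeasible or blown up); "
            f"best objective {best_j}"
        )
    best_params = _cube_to_params(best_z)
    j, terms = objective_terms(best_params, target, weights, sim_cfg,
                               frozen_seeds, sampen_cfg, band_indices)
    return FitResult(
        params=best_params,
        J=float(j),
        term_errors=terms,
        n_starts=n_starts,
        seeds={"master": seed, "frozen_realization_seeds": frozen_seeds,
               "noise_mode": noise_mode},
        n_realizations=n_realizations,
        n_evals=eval_counter[0],
        start_values=start_values,
    )
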