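"""Surrogate-based derivative-free global minimization.

A compact radial-basis-function surrogate optimizer for expensive
black-box objectives on box domains: Latin-hypercube initialization,
thin-plate-spline interpolation of the (outlier-clipped) observed
values, candidate-point search that cycles between exploration of
under-sampled regions and exploitation of the surrogate minimum, and
periodic gradient-based descent on the surrogate itself.  All randomness
flows from a single seed, so runs are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence, Tuple

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.optimize import minimize
from scipy.stats import qmc

__all__ = ["OptimizationResult", "minimize_rbf"]

# exploitation weights cycled over iterations (high = trust the surrogate)
_WEIGHT_CYCLE = (0.9, 0.6, 0.3)
# spread of the local candidate cloud around the incumbent, in box units
_SIGMA_CYCLE = (0.15, 0.05, 0.015)
# every k-th iteration descends the surrogate directly
_DESCENT_EVERY = 3
# quantile at which observed values are clipped before the surrogate fit
_CLIP_Q = 0.90
# last evaluations switch to pure exploitation with a tight local cloud
_FINAL_EXPLOIT = 10


@dataclass
class OptimizationResult:
    x: np.ndarray
    fun: float
    n_eval: int
    x_history: np.ndarray
    f_history: np.ndarray


def minimize_rbf(
    fun: Callable[[np.ndarray], float],
    bounds: Sequence[Tuple[float, float]],
    budget: int = 100,
    seed: int = 0,
    n_candidates: int = 1000,
) -> OptimizationResult:
    """Minimize ``fun`` over a box with at most ``budget`` evaluations.

    The objective is evaluated on a Latin hypercube first; afterwards
    each iteration fits an RBF surrogate to all evaluated points and
    evaluates one new point, chosen either from a scored random candidate
    pool (weighted blend of predicted value and distance to the evaluated
    set) or, periodically, by quasi-Newton descent on the surrogate from
    the incumbent.
    """
    bounds = np.asarray(bounds, dtype=float)
    d = bounds.shape[0]
    if budget < d:
        raise ValueError(f"budget {budget} < dimension {d}")
    lo, span = bounds[:, 0], bounds[:, 1] - bounds[:, 0]
    span = np.where(span > 0, span, 1.0)
    rng = np.random.default_rng(seed)

    n_init = min(max(2 * (d + 1), 12), max(budget // 2, d + 2))
    X = qmc.LatinHypercube(d=d, seed=int(rng.integers(2 ** 31))).random(n_init)
    y = np.array([fun(lo + span * x) for x in X], dtype=float)

    it = 0
    while len(y) < budget:
        # clip the upper tail so penalty plateaus do not warp the surrogate
        y_fit = np.minimum(y, np.quantile(y, _CLIP_Q))
        try:
            surrogate = RBFInterpolator(
                X, y_fit, kernel="thin_plate_spline", degree=1)
        except np.linalg.LinAlgError:
            surrogate = RBFInterpolator(
                X, y_fit, kernel="thin_plate_spline", degree=1,
                smoothing=1e-8)
        x_best = X[int(np.argmin(y))]

        if it % _DESCENT_EVERY == _DESCENT_EVERY - 1:
            # pure exploitation: descend the surrogate from the incumbent
            res = minimize(
                lambda z: float(surrogate(z[None, :])[0]),
                x_best, method="L-BFGS-B",
                bounds=[(0.0, 1.0)] * d,
                options={"maxiter": 60})
            x_new = np.clip(res.x, 0.0, 1.0)
            if np.sqrt(((X - x_new) ** 2).sum(axis=1)).min() <= 1e-9:
                x_new = None  # already evaluated; fall through to candidates
        else:
            x_new = None

        if x_new is None:
            endgame = budget - len(y) <= _FINAL_EXPLOIT
            sigma = 0.01 if endgame else _SIGMA_CYCLE[it % len(_SIGMA_CYCLE)]
            n_local = n_candidates // 2
            cand = np.vstack([
                rng.random((n_candidates, d)),
                np.clip(x_best + rng.standard_normal((n_local, d))
                        * sigma, 0.0, 1.0),
            ])
            pred = surrogate(cand)
            d2 = ((cand[:, None, :] - X[None, :, :]) ** 2).sum(-1)
            mind = np.sqrt(d2.min(axis=1))
            fresh = mind > 1e-9
            if not fresh.any():
                break
            cand, pred, mind = cand[fresh], pred[fresh], mind[fresh]
            p_rng = pred.max() - pred.min()
            v_score = ((pred - pred.min()) / p_rng if p_rng > 0
                       else np.zeros_like(pred))
            m_rng = mind.max() - mind.min()
            e_score = 1.0 - ((mind - mind.min()) / m_rng if m_rng > 0
                             else np.zeros_like(mind))
            if endgame:
                w = 1.0  # endgame: pure exploitation of the surrogate
            else:
                w = _WEIGHT_CYCLE[it % len(_WEIGHT_CYCLE)]
            x_new = cand[int(np.argmin(w * v_score + (1.0 - w) * e_score))]

        X = np.vstack([X, x_new])
        y = np.append(y, fun(lo + span * x_new))
        it += 1

    i_best = int(np.argmin(y))
    return OptimizationResult(
        x=lo + span * X[i_best], fun=float(y[i_best]), n_eval=len(y),
        x_history=lo + span * X, f_history=y)
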