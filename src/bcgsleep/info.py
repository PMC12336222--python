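"""Weighted-mean-of-vectors (INFO) population optimizer.

A population metaheuristic whose position update runs in three stages per
generation:

1. *Updating rule* — each member moves along a weighted mean of difference
   vectors formed from its own position, three distinct random members and
   the current best/better/worst solutions, with fitness-derived weights
   (cosine-damped, exponentially scaled by fitness gaps) and a
   convergence-acceleration term toward the best.
2. *Vector combining* — the two candidate updates are stochastically mixed
   with each other and with the current position to balance exploration
   and exploitation.
3. *Local search* — with probability 0.5 a solution is resampled around
   the global best / a fitness-weighted mean position, guarding against
   premature convergence.

Bounds are enforced by clipping, non-finite objective values reject the
candidate, discrete parameters are rounded at evaluation time, and
elitism makes the best-so-far history monotone.  Used here to tune the
selection and classifier hyperparameters; behind the generic
``optimize(space)`` interface any minimizer (e.g. random search) can
substitute in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np


@dataclass
class SearchSpace:
    bounds: Sequence[tuple[float, float]]
    objective: Callable[[np.ndarray], float]
    integer_mask: Sequence[bool] | None = None
    population: int = 20
    iterations: int = 200
    seed: int = 0
    max_evals: int | None = None

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4 (needs distinct a, b, c)")
        for lo, hi in self.bounds:
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("bounds must be finite with lo < hi")


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    history: list[float] = field(default_factory=list)
    n_evals: int = 0

    def to_json(self, path) -> None:
        """Tuning report: per-iteration best loss and final parameters."""
        import json
        from pathlib import Path

        Path(path).write_text(json.dumps({
            "best_parameters": np.asarray(self.x).tolist(),
            "best_loss": self.fun,
            "best_loss_per_iteration": self.history,
            "n_evaluations": self.n_evals,
        }, indent=2))


def _round_discrete(x: np.ndarray, mask) -> np.ndarray:
    if mask is None:
        return x
    out = x.copy()
    m = np.asarray(mask, dtype=bool)
    out[m] = np.round(out[m])
    return out


def optimize(space: SearchSpace) -> OptimizeResult:
    """Minimize ``space.objective`` with the INFO three-stage update."""
    rng = np.random.default_rng(space.seed)
    lo = np.array([b[0] for b in space.bounds], dtype=float)
    hi = np.array([b[1] for b in space.bounds], dtype=float)
    dim = len(space.bounds)
    npop = space.population
    budget = space.max_evals or np.inf
    evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        val = space.objective(_round_discrete(x, space.integer_mask))
        return float(val) if np.isfinite(val) else np.inf

    X = lo + rng.random((npop, dim)) * (hi - lo)
    f = np.array([evaluate(x) for x in X])
    history = []
    eps = 1e-25

    for it in range(space.iterations):
        if evals >= budget:
            break
        # rejected (infinite) fitnesses enter the weights as a large finite
        # penalty so the difference arithmetic stays well defined
        finite = f[np.isfinite(f)]
        ceil = (finite.max() + 1.0) * 2.0 if finite.size else 1e12
        fsafe = np.where(np.isfinite(f), f, ceil)
        order = np.argsort(fsafe, kind="stable")
        xb, fb = X[order[0]], fsafe[order[0]]  # best
        xbt, fbt = X[order[1]], fsafe[order[1]]  # better
        xw, fw = X[order[-1]], fsafe[order[-1]]  # worst
        alpha = 2.0 * np.exp(-4.0 * (it + 1) / space.iterations)

        X_new = X.copy()
        f_new = f.copy()
        for i in range(npop):
            if evals >= budget:
                break
            others = [j for j in range(npop) if j != i]
            a, b, c = rng.choice(others, size=3, replace=False)

            # --- stage 1: updating rule
            sigma = 2.0 * alpha * rng.random() - alpha
            def _wm(f1, x1, f2, x2, f3, x3):
                # fitness-weighted mean of pairwise difference vectors
                w1 = np.cos(f1 - f2 + np.pi) * np.exp(-np.abs((f1 - f2) / _om))
                w2 = np.cos(f1 - f3 + np.pi) * np.exp(-np.abs((f1 - f3) / _om))
                w3 = np.cos(f2 - f3 + np.pi) * np.exp(-np.abs((f2 - f3) / _om))
                tot = np.abs(w1) + np.abs(w2) + np.abs(w3) + eps
                return (w1 * (x1 - x2) + w2 * (x1 - x3) + w3 * (x2 - x3)) / tot

            _om = max(abs(fb), abs(fw), 1.0)
            mean_rule_a = _wm(fsafe[a], X[a], fsafe[b], X[b], fsafe[c], X[c])
            mean_rule_b = _wm(fb, xb, fbt, xbt, fw, xw)
            r = rng.random()
            mean_rule = r * mean_rule_a + (1 - r) * mean_rule_b
            # convergence acceleration toward the best
            ca = rng.standard_normal(dim) * (xb - X[a]) / (np.abs(fb - fsafe[a]) + eps)
            if rng.random() < 0.5:
                z1 = X[i] + sigma * (rng.random(dim) * mean_rule) + 0.05 * ca
                z2 = xb + sigma * (rng.random(dim) * mean_rule) + 0.05 * ca
            else:
                z1 = X[a] + sigma * (rng.random(dim) * mean_rule) + 0.05 * ca
                z2 = xbt + sigma * (rng.random(dim) * mean_rule) + 0.05 * ca

            # --- stage 2: vector combining
            u = np.empty(dim)
            mu = 0.05 * rng.standard_normal(dim)
            for d in range(dim):
                l1 = rng.random() < 0.5
                l2 = rng.random() < 0.5
                if l1:
                    u[d] = z1[d] + mu[d] * abs(z1[d] - z2[d]) if l2 else \
                        z2[d] + mu[d] * abs(z1[d] - z2[d])
                else:
                    u[d] = X[i, d]

            # --- stage 3: local search around the best / weighted mean
            if rng.random() < 0.5:
                mean_pos = (xb + xbt + xw) / 3.0
                v1 = rng.random()
                if rng.random() < 0.5:
                    u = xb + rng.standard_normal(dim) * (
                        mean_rule + rng.random(dim) * (xb - X[a])
                    )
                else:
                    u = mean_pos + rng.standard_normal(dim) * (
                        mean_rule + rng.random(dim) * (v1 * xb - mean_pos)
                    )

            u = np.clip(u, lo, hi)
            fu = evaluate(u)
            if fu < f_new[i]:
                X_new[i], f_new[i] = u, fu
        X, f = X_new, f_new
        history.append(float(f.min()))

    best = int(np.argmin(f))
    x_best = _round_discrete(X[best], space.integer_mask)
    # elitist history: monotone best-so-far
    mono = np.minimum.accumulate(history) if history else [float(f[best])]
    return OptimizeResult(x=x_best, fun=float(f[best]), history=list(map(float, mono)),
                          n_evals=evals)
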