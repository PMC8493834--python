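"""Minimal (mu/mu_w, lambda)-CMA-ES with cumulative step-size adaptation.

Covariance matrix adaptation evolution strategy, the field's standard global
optimizer for ion-channel kinetics fitting, in its basic form: weighted
recombination, rank-one and rank-mu covariance updates, and CSA step-size
control.  Box constraints are handled by clipping candidates into the box
and adding a quadratic out-of-box penalty.  Deterministic under a seeded
generator.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = ["cma_es_minimize"]


def cma_es_minimize(
    fun: Callable[[np.ndarray], float],
    x0: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    rng: np.random.Generator,
    sigma0: float = 0.3,
    max_evals: int = 2000,
    popsize: int | None = None,
    ftol_rel: float = 1e-8,
) -> tuple[np.ndarray, float, int]:
    """Minimize ``fun`` within a box; returns (x_best, f_best, n_evals).

    The search runs in coordinates normalized to the box ([0, 1]^n), with
    initial step ``sigma0`` in box units.
    """
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    span = upper - lower
    n = len(lower)

    def to_x(z: np.ndarray) -> np.ndarray:
        return lower + z * span

    lam = popsize or (4 + int(3 * math.log(n)))
    mu = lam // 2
    w = math.log(mu + 0.5) - np.log(np.arange(1, mu + 1))
    w /= w.sum()
    mu_eff = 1.0 / float(w @ w)

    cc = (4 + mu_eff / n) / (n + 4 + 2 * mu_eff / n)
    cs = (mu_eff + 2) / (n + mu_eff + 5)
    c1 = 2 / ((n + 1.3) ** 2 + mu_eff)
    cmu = min(1 - c1, 2 * (mu_eff - 2 + 1 / mu_eff) / ((n + 2) ** 2 + mu_eff))
    damps = 1 + 2 * max(0.0, math.sqrt((mu_eff - 1) / (n + 1)) - 1) + cs
    chi_n = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n * n))

    mean = np.clip((np.asarray(x0, dtype=float) - lower) / span, 0.0, 1.0)
    sigma = sigma0
    cov = np.eye(n)
    pc = np.zeros(n)
    ps = np.zeros(n)

    best_x = to_x(mean)
    best_f = fun(best_x)
    n_evals = 1
    prev_best = best_f

    while n_evals + lam <= max_evals:
        try:
            a_chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            cov = np.eye(n)
            a_chol = cov.copy()
        zs = rng.standard_normal((lam, n))
        ys = zs @ a_chol.T
        cands = mean + sigma * ys
        fs = np.empty(lam)
        for i in range(lam):
            clipped = np.clip(cands[i], 0.0, 1.0)
            pen = float(np.sum((cands[i] - clipped) ** 2))
            fs[i] = fun(to_x(clipped)) + pen * (1.0 + abs(best_f))
            n_evals += 1
            if fs[i] < best_f:
                best_f = float(fs[i])
                best_x = to_x(clipped)
        order = np.argsort(fs)
        y_sel = ys[order[:mu]]
        y_w = w @ y_sel
        mean = mean + sigma * y_w

        # CSA step-size path (whitened)
        inv_y = np.linalg.solve(a_chol, y_w)
        ps = (1 - cs) * ps + math.sqrt(cs * (2 - cs) * mu_eff) * inv_y
        h_sig = float(
            np.linalg.norm(ps) / math.sqrt(1 - (1 - cs) ** (2 * n_evals / lam))
            < (1.4 + 2 / (n + 1)) * chi_n
        )
        pc = (1 - cc) * pc + h_sig * math.sqrt(cc * (2 - cc) * mu_eff) * y_w
        rank_mu = sum(wi * np.outer(yi, yi) for wi, yi in zip(w, y_sel))
        cov = (
            (1 - c1 - cmu) * cov
            + c1 * (np.outer(pc, pc) + (1 - h_sig) * cc * (2 - cc) * cov)
            + cmu * rank_mu
        )
        sigma *= math.exp((cs / damps) * (np.linalg.norm(ps) / chi_n - 1))
        sigma = min(sigma, 2.0)

        gen = n_evals // lam
        if gen % 20 == 0:
            if abs(prev_best - best_f) <= ftol_rel * (abs(prev_best) + 1e-12):
                break
            prev_best = best_f
    return best_x, best_f, n_evals
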