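"""Covariance-matrix-adaptation evolution strategy ((mu/mu_w, lambda)-CMA-ES).

A compact implementation of the standard algorithm (weighted recombination,
cumulative step-size adaptation, rank-one and rank-mu covariance updates)
for minimization of noisy black-box objectives of moderate dimension.
Exposes the usual ask/tell interface plus a convenience driver.
"""

from __future__ import annotations

import math

import numpy as np


class CMAES:
    def __init__(self, x0, sigma0: float, seed: int | None = None,
                 popsize: int | None = None):
        self.mean = np.asarray(x0, dtype=float).copy()
        self.sigma = float(sigma0)
        self.n = len(self.mean)
        n = self.n
        self.lam = popsize if popsize is not None else 4 + int(3 * math.log(n))
        self.mu = self.lam // 2
        w = math.log(self.mu + 0.5) - np.log(np.arange(1, self.mu + 1))
        self.weights = w / w.sum()
        self.mueff = 1.0 / np.sum(self.weights ** 2)
        self.cc = (4 + self.mueff / n) / (n + 4 + 2 * self.mueff / n)
        self.cs = (self.mueff + 2) / (n + self.mueff + 5)
        self.c1 = 2 / ((n + 1.3) ** 2 + self.mueff)
        self.cmu = min(1 - self.c1,
                       2 * (self.mueff - 2 + 1 / self.mueff)
                       / ((n + 2) ** 2 + self.mueff))
        self.damps = 1 + 2 * max(0.0, math.sqrt((self.mueff - 1) / (n + 1)) - 1) + self.cs
        self.pc = np.zeros(n)
        self.ps = np.zeros(n)
        self.C = np.eye(n)
        self.chiN = math.sqrt(n) * (1 - 1 / (4 * n) + 1 / (21 * n ** 2))
        self.rng = np.random.default_rng(seed)
        self.generation = 0
        self.best_x = self.mean.copy()
        self.best_f = math.inf
        self._decompose()

    def _decompose(self) -> None:
        self.C = (self.C + self.C.T) / 2
        eigvals, B = np.linalg.eigh(self.C)
        eigvals = np.maximum(eigvals, 1e-20)
        self.B = B
        self.D = np.sqrt(eigvals)

    def ask(self) -> np.ndarray:
        """Sample lambda candidate solutions (rows)."""
        z = self.rng.standard_normal((self.lam, self.n))
        self._y = z * self.D @ self.B.T
        return self.mean + self.sigma * self._y

    def tell(self, xs: np.ndarray, fs) -> None:
        """Update the distribution from candidates and their (to-minimize) values."""
        fs = np.asarray(fs, dtype=float)
        order = np.argsort(fs)
        if fs[order[0]] < self.best_f:
            self.best_f = float(fs[order[0]])
            self.best_x = np.array(xs[order[0]], dtype=float)
        y_sel = self._y[order[: self.mu]]
        y_w = self.weights @ y_sel
        self.mean = self.mean + self.sigma * y_w
        # cumulative step-size adaptation
        C_inv_half = self.B @ np.diag(1 / self.D) @ self.B.T
        self.ps = ((1 - self.cs) * self.ps
                   + math.sqrt(self.cs * (2 - self.cs) * self.mueff)
                   * (C_inv_half @ y_w))
        hsig = (np.linalg.norm(self.ps)
                / math.sqrt(1 - (1 - self.cs) ** (2 * (self.generation + 1)))
                < (1.4 + 2 / (self.n + 1)) * self.chiN)
        self.pc = ((1 - self.cc) * self.pc
                   + (math.sqrt(self.cc * (2 - self.cc) * self.mueff) * y_w
                      if hsig else 0.0))
        rank_mu = (y_sel.T * self.weights) @ y_sel
        self.C = ((1 - self.c1 - self.cmu) * self.C
                  + self.c1 * (np.outer(self.pc, self.pc)
                               + (0.0 if hsig else self.c1 * self.cc * (2 - self.cc)) * self.C)
                  + self.cmu * rank_mu)
        self.sigma *= math.exp(min(1.0, (self.cs / self.damps)
                                   * (np.linalg.norm(self.ps) / self.chiN - 1)))
        self.generation += 1
        self._decompose()


def minimize(func, x0, sigma0: float, max_evals: int, seed: int | None = None,
             popsize: int | None = None):
    """Drive CMA-ES on a scalar function of a vector; returns (x_best, f_best)."""
    es = CMAES(x0, sigma0, seed=seed, popsize=popsize)
    evals = 0
    while evals < max_evals:
        xs = es.ask()
        fs = [func(x) for x in xs]
        evals += len(fs)
        es.tell(xs, fs)
    return es.best_x, es.best_f
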