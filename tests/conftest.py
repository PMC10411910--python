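"""Shared helpers for the test suite.

The only nontrivial helper is a bootstrap standard error for sample Fano
factors and covariances, used to compare stochastic-simulation estimates
against the exact analytic moments on a "within k standard errors" basis.
"""

from __future__ import annotations

import numpy as np


def boot_se(values: np.ndarray, stat, n_boot: int = 500, seed: int = 0) -> float:
    """Bootstrap standard error of ``stat`` over a 1D (or row-paired 2D) sample."""
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        out[b] = stat(values[idx])
    return float(out.std(ddof=1))


def fano(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.var(ddof=1) / x.mean())


def fano_se(x: np.ndarray, n_boot: int = 500, seed: int = 0) -> float:
    return boot_se(np.asarray(x, dtype=float), fano, n_boot=n_boot, seed=seed)


def cov_pair(xy: np.ndarray) -> float:
    return float(np.cov(xy[:, 0], xy[:, 1], ddof=1)[0, 1])


def cov_se(x: np.ndarray, y: np.ndarray, n_boot: int = 500, seed: int = 0) -> float:
    xy = np.column_stack([x, y]).astype(float)
    return boot_se(xy, cov_pair, n_boot=n_boot, seed=seed)
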