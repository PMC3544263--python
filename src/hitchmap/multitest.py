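"""Storey q-value false discovery rates with bootstrap pi0 estimation.

Given the P-value list of one neutrality test, the proportion of true null
hypotheses pi0 is estimated as pi0(lambda) = #{p > lambda} / (m (1-lambda))
on a grid of lambda, with the bootstrap rule of Storey & Tibshirani picking
the lambda whose resampled pi0 has smallest estimated MSE around the most
optimistic (minimum) plug-in value.  q-values follow by the step-down
minimisation q(p_(i)) = min_{j >= i} pi0 * m * p_(j) / j.  With pi0 = 1 the
procedure reduces exactly to Benjamini-Hochberg adjusted P-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["QValueResult", "DEFAULT_LAMBDA_GRID", "estimate_pi0_bootstrap", "qvalues", "qvalue_pipeline"]

DEFAULT_LAMBDA_GRID: np.ndarray = np.round(np.arange(0.0, 0.95, 0.05), 2)  # 0, 0.05, ..., 0.90


@dataclass
class QValueResult:
    pvalues: np.ndarray = field(repr=False)
    pi0: float
    lambda_grid: np.ndarray = field(repr=False)
    qvalues: np.ndarray = field(repr=False)


def _check_pvalues(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("need a one-dimensional, nonempty P-value list")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("P-values must lie in (0, 1]")
    return p


def estimate_pi0_bootstrap(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_boot: int = 100,
    seed: int = 0,
) -> float:
    """Bootstrap estimate of the proportion of true nulls, clamped to (0, 1]."""
    p = _check_pvalues(pvalues)
    if p.size < 20:
        raise ValueError("pi0 estimation needs >= 20 P-values")
    lam = np.asarray(lambda_grid, dtype=float)
    m = p.size

    def pi0_of(sample: np.ndarray) -> np.ndarray:
        return (sample[:, None] > lam[None, :]).sum(axis=0) / (m * (1.0 - lam))

    pi0_lam = pi0_of(p)
    min_pi0 = pi0_lam.min()
    if min_pi0 <= 0:
        floor = 1.0 / (m * (1.0 - lam.max()))
        if pi0_lam.max() <= 0:
            warnings.warn("all P-values below the lambda grid; pi0 set to its floor")
            return floor
        min_pi0 = max(min_pi0, floor)

    rng = np.random.default_rng(seed)
    mse = np.zeros_like(lam)
    for _ in range(n_boot):
        boot = rng.choice(p, size=m, replace=True)
        mse += (pi0_of(boot) - min_pi0) ** 2
    best = int(np.argmin(mse))
    pi0 = float(pi0_lam[best])
    if pi0 <= 0:
        warnings.warn("pi0 estimate nonpositive; clamped to its smallest attainable value")
        pi0 = 1.0 / (m * (1.0 - lam[best]))
    return min(pi0, 1.0)


def qvalues(pvalues: np.ndarray, pi0: float = 1.0) -> np.ndarray:
    """Step-down q-values for a P-value list at a given pi0."""
    p = _check_pvalues(pvalues)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ps = p[order]
    raw = pi0 * m * ps / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def qvalue_pipeline(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    n_boot: int = 100,
    seed: int = 0,
) -> QValueResult:
    """Estimate pi0 by bootstrap, then q-values, in one call."""
    p = _check_pvalues(pvalues)
    pi0 = estimate_pi0_bootstrap(p, lambda_grid=lambda_grid, n_boot=n_boot, seed=seed)
    return QValueResult(
        pvalues=p, pi0=pi0, lambda_grid=np.asarray(lambda_grid, float), qvalues=qvalues(p, pi0)
    )
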