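"""Monte-Carlo calibration of the correlation-change test.

Vectorized simulations of the two-subset change test under a known truth:
type-I error under the null (equal population correlation in both
subsets) and power under a planted difference. Used by the test suite and
the acceptance script to check that the normal-theory Fisher-z test
behaves as advertised at the study's sample sizes.
"""

from __future__ import annotations

import numpy as np

from .diffnet import correlation_change_test


def _simulate_r(rho: float, n: int, reps: int, rng: np.random.Generator) -> np.ndarray:
    """Empirical Pearson r of `reps` independent bivariate-normal samples."""
    x = rng.standard_normal((reps, n))
    e = rng.standard_normal((reps, n))
    y = rho * x + np.sqrt(1.0 - rho * rho) * e
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    return num / den


def change_test_simulation(
    rho_a: float,
    rho_b: float,
    n_a: int,
    n_b: int,
    reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Simulate `reps` independent pair-tests at a fixed truth.

    Returns the empirical rejection rate at ``alpha``, the p-values, and
    the Monte-Carlo standard error of the rate.
    """
    rng = np.random.default_rng(seed)
    r_a = _simulate_r(rho_a, n_a, reps, rng)
    r_b = _simulate_r(rho_b, n_b, reps, rng)
    q, p = correlation_change_test(r_a, np.full(reps, n_a), r_b, np.full(reps, n_b))
    rate = float(np.mean(p < alpha))
    return {
        "rejection_rate": rate,
        "mc_se": float(np.sqrt(rate * (1 - rate) / reps)),
        "p_values": p,
        "q_values": q,
    }


def null_rejection_simulation(
    rho: float = 0.3, n: int = 40, reps: int = 2000,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Type-I error check: both subsets share the same population ρ."""
    return change_test_simulation(rho, rho, n, n, reps, alpha=alpha, seed=seed)


def power_simulation(
    rho_a: float = 0.2, rho_b: float = 0.8, n: int = 40, reps: int = 1000,
    alpha: float = 0.05, seed: int = 0,
) -> dict:
    """Empirical power under a planted correlation difference."""
    return change_test_simulation(rho_a, rho_b, n, n, reps, alpha=alpha, seed=seed)
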