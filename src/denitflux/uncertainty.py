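"""First-order (linear) error propagation with a Monte-Carlo oracle.

Derived quantities throughout the pipeline (yields, balances, deconvolved
phase rates) carry standard deviations obtained by first-order propagation
of the input rate uncertainties.  Partial derivatives are taken by central
finite differences so any pipeline expression is propagatable without a
hand-derived Jacobian; inputs are treated as independent unless a
covariance matrix is supplied.  :func:`propagate_monte_carlo` provides an
independent resampling estimate used to validate the linearisation.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

__all__ = ["UncertainValue", "propagate_linear", "propagate_monte_carlo"]


@dataclass(frozen=True)
class UncertainValue:
    """A scalar with a standard deviation (sd >= 0)."""

    value: float
    sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    def as_tuple(self) -> tuple[float, float]:
        return (self.value, self.sd)


def _means_sds(inputs: Sequence[UncertainValue]) -> tuple[np.ndarray, np.ndarray]:
    means = np.array([u.value for u in inputs], dtype=float)
    sds = np.array([u.sd for u in inputs], dtype=float)
    return means, sds


def propagate_linear(
    f: Callable[[np.ndarray], float],
    inputs: Sequence[UncertainValue],
    rel_step: float = 1e-6,
    cov: np.ndarray | None = None,
) -> UncertainValue:
    """Propagate input sds through ``f`` by first-order Taylor expansion.

    ``sd_out = sqrt(g @ Sigma @ g)`` with gradient ``g`` from central
    finite differences (relative step *rel_step*, absolute fallback for
    zero-valued inputs) and ``Sigma`` diagonal unless *cov* is given.
    """
    means, sds = _means_sds(inputs)
    with np.errstate(divide="ignore", invalid="ignore"):
        value = float(f(means))
    if not np.isfinite(value):
        raise ValueError("function not finite at the input means")

    grad = np.zeros_like(means)
    for i in range(means.size):
        h = rel_step * max(abs(means[i]), 1.0)
        up = means.copy()
        dn = means.copy()
        up[i] += h
        dn[i] -= h
        grad[i] = (float(f(up)) - float(f(dn))) / (2.0 * h)

    if cov is None:
        var = float(np.sum(grad**2 * sds**2))
    else:
        cov = np.asarray(cov, dtype=float)
        var = float(grad @ cov @ grad)
    return UncertainValue(value, float(np.sqrt(max(var, 0.0))))


def propagate_monte_carlo(
    f: Callable[[np.ndarray], float],
    inputs: Sequence[UncertainValue],
    n_draws: int = 10_000,
    seed: int = 0,
) -> UncertainValue:
    """Empirical mean/sd of ``f`` over independent normal draws.

    Deterministic given *seed*; serves as the resampling oracle for
    :func:`propagate_linear`.
    """
    if n_draws < 1000:
        raise ValueError("n_draws must be at least 1000 for a stable sd")
    means, sds = _means_sds(inputs)
    rng = np.random.default_rng(seed)
    draws = rng.normal(means, sds, size=(n_draws, means.size))
    try:  # vectorised path: f may broadcast over a trailing axis
        out = np.asarray(f(draws.T), dtype=float)
        if out.shape != (n_draws,):
            raise ValueError
    except Exception:
        out = np.array([float(f(row)) for row in draws])
    return UncertainValue(float(np.mean(out)), float(np.std(out, ddof=1)))
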