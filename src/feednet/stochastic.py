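"""Seedable random primitives.

Moment-matched log-normal draws, correlated normal/logistic draws through a
Cholesky factor of the correlation matrix (Gaussian copula for the logistic
family so the stated marginals are exact), and Poisson draws.

Reproducibility contract: every draw comes from a ``numpy.random.Generator``
keyed by ``(master_seed, stream_id)``; identical keys and draw order give
identical values, and distinct stream ids give statistically independent
streams.  The engine uses one stream per iteration, so a simulation can be
extended to a larger count (the convergence loop) without re-drawing earlier
iterations, and run order never matters.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import ndtr  # standard normal CDF, elementwise ufunc

__all__ = [
    "stream",
    "lognormal_params",
    "lognormal_draw",
    "cholesky_factor",
    "correlated_standard_normal",
    "correlated_draws",
    "poisson_draw",
]


def stream(master_seed: int, stream_id: int = 0) -> np.random.Generator:
    """An independent generator keyed by ``(master_seed, stream_id)``."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, stream_id))))


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """Log-scale ``(mu, sigma)`` matching a natural-scale mean and SD.

    sigma^2 = ln(1 + sd^2/mean^2), mu = ln(mean) - sigma^2/2, so draws
    ``exp(mu + sigma Z)`` recover the requested first two moments exactly.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("lognormal mean must be > 0 and sd >= 0")
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def lognormal_draw(mean: float, sd: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` positive draws with natural-scale mean/SD ``(mean, sd)``."""
    if sd == 0:
        return np.full(n, float(mean))
    mu, sigma = lognormal_params(mean, sd)
    return np.exp(mu + sigma * rng.standard_normal(n))


_CHOL_CACHE: dict[bytes, np.ndarray] = {}


def cholesky_factor(corr: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor; raises ``np.linalg.LinAlgError`` if not PD.

    Factors are memoized by matrix content — the engine asks for the same
    handful of small matrices once per iteration.
    """
    corr = np.asarray(corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError(f"correlation matrix must be square, got shape {corr.shape}")
    key = corr.tobytes()
    cached = _CHOL_CACHE.get(key)
    if cached is None:
        if len(_CHOL_CACHE) > 64:
            _CHOL_CACHE.clear()
        cached = _CHOL_CACHE.setdefault(key, np.linalg.cholesky(corr))
    return cached


def _apply_chol(z: np.ndarray, chol: np.ndarray) -> np.ndarray:
    # Explicit column accumulation (k <= 4) keeps the floating-point operation
    # order identical whether z is one row or a big batch, which the
    # vectorized-vs-loop engine equivalence relies on.
    k = chol.shape[0]
    out = np.empty_like(z)
    for j in range(k):
        acc = chol[j, 0] * z[..., 0]
        for m in range(1, j + 1):
            acc = acc + chol[j, m] * z[..., m]
        out[..., j] = acc
    return out


def correlated_standard_normal(chol: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n x k`` standard normal rows with correlation ``chol @ chol.T``."""
    k = chol.shape[0]
    z = rng.standard_normal((n, k))
    return _apply_chol(z, chol)


def correlated_draws(
    locations,
    scales,
    corr: np.ndarray,
    family: str,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """``n x k`` draws with the requested marginals and correlation structure.

    ``family='normal'``: location + scale * correlated Z.
    ``family='logistic'``: Gaussian copula — correlated Z mapped through the
    normal CDF then the logistic quantile function, so each marginal is exactly
    Logistic(location, scale) while the copula carries the dependence.
    """
    locations = np.asarray(locations, dtype=float)
    scales = np.asarray(scales, dtype=float)
    k = locations.shape[0]
    if scales.shape[0] != k:
        raise ValueError("locations and scales must have equal length")
    if np.any(scales < 0):
        raise ValueError("scales must be >= 0")
    chol = cholesky_factor(corr)
    if chol.shape[0] != k:
        raise ValueError(f"correlation matrix is {chol.shape[0]}x{chol.shape[0]}, expected {k}x{k}")
    y = correlated_standard_normal(chol, n, rng)
    if family == "normal":
        return locations + scales * y
    if family == "logistic":
        u = ndtr(y)
        # logistic quantile; u in (0,1) strictly since ndtr of finite z
        return locations + scales * np.log(u / (1.0 - u))
    raise ValueError(f"unknown family: {family!r}")


def poisson_draw(lam, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` Poisson counts with mean ``lam`` (scalar or length-n array)."""
    lam = np.asarray(lam, dtype=float)
    if np.any(lam < 0):
        raise ValueError("Poisson rate must be >= 0")
    return rng.poisson(lam, size=n)
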