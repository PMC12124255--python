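"""Economic scenario simulation.

One corn price per pen (grain assumed contracted, so it is shared across
endpoints), four correlated log-normal live fed-cattle prices (one per
endpoint, mimicking selling the pen on different weeks), dressed base prices
as live price divided by the dressing ratio, uniform selection of one of
three Quality Grade grids and one of three interest rates, and the three
price regressions (feed+yardage from corn, cull-cow/removal price from the
live price, Prime/sub-Select grid values from the Select discount).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters, CorrelationSet
from .stochastic import cholesky_factor, correlated_standard_normal, lognormal_params

__all__ = [
    "MarketDraw",
    "simulate_prices",
    "simulate_corn",
    "fyp_from_corn",
    "cull_cow_price",
    "removal_price",
    "qg_grid_values",
    "select_scenario",
]


@dataclass
class MarketDraw:
    """Per-pen economic scenario."""

    corn: float                 # $/bushel, shared across endpoints
    live_price: np.ndarray      # $/cwt, one per endpoint (EP1..EP4)
    dressed_base: np.ndarray    # $/cwt, live / dress_ratio
    grid_id: int                # 1-based index of the selected QG grid
    interest_rate: float        # yearly simple rate
    fyp: float                  # $/dry US ton


def simulate_corn(params: ModelParameters, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` moment-matched log-normal corn prices, $/bu."""
    mu, sigma = lognormal_params(params.corn_price.mean, params.corn_price.sd)
    return np.exp(mu + sigma * rng.standard_normal(n))


def simulate_prices(
    params: ModelParameters, corrs: CorrelationSet, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw ``(corn, live, dressed_base)`` for ``n`` pens.

    ``live`` is ``n x 4`` with identical log-normal marginals per endpoint and
    the between-endpoint correlation applied on the log scale (so marginals
    stay exactly log-normal).  ``dressed_base = live / dress_ratio``.
    """
    corn = simulate_corn(params, n, rng)
    mu, sigma = lognormal_params(params.live_price.mean, params.live_price.sd)
    chol = cholesky_factor(corrs.live_price_eps)
    z = correlated_standard_normal(chol, n, rng)
    live = np.exp(mu + sigma * z)
    dressed = live / params.dress_ratio
    return corn, live, dressed


def fyp_from_corn(corn, params: ModelParameters | None = None):
    """Feed + yardage price, $/dry US ton, as a quadratic in corn $/bu."""
    a, b, c = params.fyp_coeffs if params is not None else (26.80, 71.64, -2.97)
    corn = np.asarray(corn, dtype=float)
    return a + corn * b + corn**2 * c


def cull_cow_price(live_price_prior_ep, params: ModelParameters | None = None):
    """Cull cow price, $/cwt HCW, linear in the prior endpoint's live price."""
    a, b = params.cow_coeffs if params is not None else (-27.18, 1.30)
    return a + np.asarray(live_price_prior_ep, dtype=float) * b


def removal_price(live_price_prior_ep, params: ModelParameters | None = None):
    """Price received for railers: cull cow price scaled by the cull factor."""
    factor = params.cull_factor if params is not None else 0.92
    return cull_cow_price(live_price_prior_ep, params) * factor


def _round_quarter(x):
    return np.round(np.asarray(x, dtype=float) * 4.0) / 4.0


def qg_grid_values(select_discount: float, params: ModelParameters | None = None):
    """Quality Grade grid (Prime, Choice, Select, sub-Select), $/cwt.

    Prime premium and sub-Select discount are quadratic regressions in the
    signed Select discount (a negative number), rounded to the nearest $0.25;
    Choice is fixed at 0 (grids anchor on the Choice–Select spread).

    Note the shipped default grids use the printed industry values directly;
    this function serves user-defined Select discounts, and its Prime output
    can differ from the shipped grids (the sub-Select output matches them).
    """
    if select_discount > 0:
        raise ValueError("the Select discount must be <= 0 (a discount)")
    pa, pb, pc = params.prime_coeffs if params is not None else (17.05, 0.35, 0.02)
    sa, sb, sc = params.subselect_coeffs if params is not None else (-14.61, 1.00, 0.004)
    p = float(select_discount)
    prime = float(_round_quarter(pa + p * pb + p * p * pc))
    sub = float(_round_quarter(sa + p * sb + p * p * sc))
    return (prime, 0.0, float(_round_quarter(p)), sub)


def select_scenario(rng: np.random.Generator, n: int = 1, params: ModelParameters | None = None):
    """Uniform, independent picks of QG grid id (1..3) and yearly interest rate."""
    rates = params.interest_rates if params is not None else (0.05, 0.07, 0.09)
    grid_id = rng.integers(1, 4, size=n)
    rate = np.asarray(rates)[rng.integers(0, len(rates), size=n)]
    if n == 1:
        return int(grid_id[0]), float(rate[0])
    return grid_id, rate
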