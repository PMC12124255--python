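"""Revenue, cost, and net-return accounting (partial budget).

Only events after the baseline endpoint enter the budget: EP1 contributes
gross revenue alone (all earlier costs are sunk and shared across the
endpoints being compared), later endpoints add feed/yardage cost with simple
interest, an opportunity-cost "penalty" for delaying EP1 revenue, and health
costs, against extra weight-gain revenue and salvage revenue from removals.
The final outcome is the marginal net-return difference versus marketing at
EP1, per pen and per animal sold.

All functions are elementwise ufunc arithmetic, so they accept scalars or
aligned arrays interchangeably; currency stays at full float precision.
"""

from __future__ import annotations

import numpy as np

from .params import ModelParameters

__all__ = [
    "revenue_live",
    "revenue_dressed",
    "grid_adjustment",
    "revenue_grid",
    "removal_revenue",
    "interest_fraction",
    "opportunity_cost",
    "feed_yardage_cost",
    "health_cost",
    "net_return_difference",
]

CWT_KG = 45.4


def revenue_live(head, fbw, price, cwt_kg: float = CWT_KG):
    """Pen live-basis revenue, $: head x mean live weight (kg) x $/cwt / cwt."""
    return head * fbw * price / cwt_kg


def revenue_dressed(head, hcw, dressed_base, cwt_kg: float = CWT_KG):
    """Pen dressed-cash revenue, $: head x mean HCW (kg) x dressed $/cwt / cwt."""
    return head * hcw * dressed_base / cwt_kg


def grid_adjustment(qg, yg, heavy_frac, qg_grid, yg_grid, heavy_discount):
    """Net grid premium/discount, $/cwt, for a pen's carcass mix.

    Dot product of the Quality and Yield Grade proportion vectors with their
    grid values (both ordered highest grade first) plus the heavyweight
    fraction times the heavyweight discount.  Grade vectors may be batched
    (``... x k``), with grids broadcastable against them.
    """
    qg = np.asarray(qg, dtype=float)
    yg = np.asarray(yg, dtype=float)
    qg_part = np.sum(qg * np.asarray(qg_grid, dtype=float), axis=-1)
    yg_part = np.sum(yg * np.asarray(yg_grid, dtype=float), axis=-1)
    return qg_part + yg_part + np.asarray(heavy_frac, dtype=float) * heavy_discount


def revenue_grid(head, hcw, dressed_base, grid_adj, cwt_kg: float = CWT_KG):
    """Pen grid-basis revenue, $: dressed base price adjusted by the grid."""
    return head * hcw * (dressed_base + grid_adj) / cwt_kg


def removal_revenue(rem_count, hcw_prior_ep, removal_price, cwt_kg: float = CWT_KG):
    """Salvage revenue for one interval's removals, $.

    Removals are valued at the prior endpoint's simulated pen mean HCW and the
    removal price derived from the prior endpoint's live price; callers
    accumulate across intervals.
    """
    return rem_count * hcw_prior_ep * removal_price / cwt_kg


def interest_fraction(rate, extra_dof):
    """Simple (uncompounded) interest fraction for the added days on feed."""
    return np.asarray(rate, dtype=float) * np.asarray(extra_dof, dtype=float) / 365.0


def opportunity_cost(tr_ep1_basis, interest_frac):
    """Interest forgone on EP1 revenue while delaying marketing, $.

    Computed from the same sale basis's EP1 total revenue that the net-return
    comparison uses.
    """
    return tr_ep1_basis * interest_frac


def feed_yardage_cost(fyp, dmi_total, interest_frac, ton_kg: float = 907.0):
    """Feed + yardage cost with interest on half the feed bill, $.

    ``fyp`` is $/dry US ton, ``dmi_total`` total pen intake in kg; borrowing
    is assumed on 50% of the feed cost for the added period.
    """
    feed = fyp / ton_kg * dmi_total
    return feed + feed * np.asarray(interest_frac, dtype=float) / 2.0


def health_cost(morb_total, mort_total, params: ModelParameters | None = None):
    """Treatment cost per cumulative morbidity plus render fee per mortality, $."""
    treat = params.treat_cost if params is not None else 23.60
    render = params.render_cost if params is not None else 40.50
    return treat * np.asarray(morb_total, dtype=float) + render * np.asarray(mort_total, dtype=float)


def net_return_difference(tr_ep, tc_ep, tr_ep1, head_ep, rem_total):
    """Marginal net-return difference vs marketing at EP1.

    Returns ``(per pen $, per animal sold $)``; the per-animal denominator
    counts finished head plus cumulative removals (every animal that produced
    revenue).
    """
    denom = np.asarray(head_ep, dtype=float) + np.asarray(rem_total, dtype=float)
    if np.any(denom <= 0):
        raise ValueError("head + removals must be > 0")
    pen = tr_ep - tc_ep - tr_ep1
    return pen, pen / denom
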