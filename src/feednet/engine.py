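"""Simulation engine.

Each iteration simulates one pen of steers under four what-if marketing
endpoints (EP1 baseline plus 14, 28, and 42 added days on feed) and three
sale bases (live, dressed-cash, grid), producing the marginal net-return
difference per animal sold for each later endpoint versus EP1.

Randomness contract
-------------------
Iteration ``i`` draws everything from its own stream keyed by
``(master_seed, i)``, in a frozen order: EP1 weights -> weight gains -> YG
threshold logits -> QG threshold logits -> YG shift betas -> QG shift betas
-> per-interval health events (morbidity, mortality, removal; three
intervals) -> DMI -> corn price -> live prices -> grid pick -> rate pick.
Because streams are per-iteration, a run can be extended (the convergence
loop) without disturbing earlier iterations, and the vectorized and plain
per-pen paths consume identical draws.

``run_simulation(..., vectorized=False)`` is the unvectorized reference path:
it orchestrates each pen in scalar Python through the same component
functions, serving as an oracle for the batched path.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cattle, economics, health, market
from .cattle import RepairCounter
from .params import ModelParameters, CorrelationSet
from .stochastic import stream

logger = logging.getLogger("feednet")

__all__ = [
    "EXTRA_DOF",
    "ConvergenceReport",
    "run_iteration",
    "run_simulation",
    "check_convergence",
    "run_to_convergence",
    "BASES",
]

EXTRA_DOF = {2: 14, 3: 28, 4: 42}
BASES = ("live", "dressed", "grid")


# ---------------------------------------------------------------------------
# per-iteration draws (shared by both compute paths)


def _draw_raw(params: ModelParameters, corrs: CorrelationSet,
              rng: np.random.Generator, counter: RepairCounter | None = None) -> dict:
    """All stochastic inputs for one pen, in the frozen draw order."""
    w = cattle.simulate_ep1_weights(params, corrs, 1, rng)[0]
    g = cattle.simulate_gains(params, corrs, 1, rng)[0]
    yg_l1 = cattle.simulate_baseline_grade_logits(
        params.yg_intercepts, corrs.yg_intercepts, 1, rng, counter=counter)[0]
    qg_l1 = cattle.simulate_baseline_grade_logits(
        params.qg_intercepts, corrs.qg_intercepts, 1, rng, counter=counter)[0]
    yg_b = cattle.simulate_grade_betas(params.yg_betas, corrs.yg_betas, 1, rng)[0]
    qg_b = cattle.simulate_grade_betas(params.qg_betas, corrs.qg_betas, 1, rng)[0]

    ledger = health.HealthLedger(head=params.pen_size)
    for _ in range(3):
        events = health.simulate_interval_events(ledger.head, params, rng)
        ledger = health.advance_ledger(ledger, events, dof=params.dof_step)

    dmi = cattle.simulate_dmi(params, 1, rng)[0]
    corn, live, dressed = market.simulate_prices(params, corrs, 1, rng)
    grid_id, rate = market.select_scenario(rng, 1, params)
    return {
        "fbw1": w[0], "hcw1": w[1], "ldg": g[0], "cdg": g[1],
        "yg_l1": yg_l1, "qg_l1": qg_l1, "yg_b": yg_b, "qg_b": qg_b,
        "morb": np.array(ledger.morb), "mort": np.array(ledger.mort),
        "rem": np.array(ledger.rem), "hddays": np.array(ledger.hddays),
        "head_final": ledger.head,
        "dmi": dmi, "corn": corn[0], "live": live[0], "dressed": dressed[0],
        "grid_id": grid_id, "rate": rate,
    }


# ---------------------------------------------------------------------------
# scalar reference path

_YG_NAMES = ("yg5", "yg4", "yg3", "yg2", "yg1")
_QG_NAMES = ("qg_prime", "qg_choice", "qg_select", "qg_subselect")


def run_iteration(params: ModelParameters, corrs: CorrelationSet,
                  rng: np.random.Generator, counter: RepairCounter | None = None) -> dict:
    """Simulate one pen end to end in plain scalar arithmetic.

    Returns one result row (a flat dict of floats) with the same columns the
    vectorized path produces.
    """
    raw = _draw_raw(params, corrs, rng, counter)
    row: dict[str, float] = {}
    yg_grid = np.asarray(params.yg_grid)
    qg_grid = np.asarray(params.qg_grids[raw["grid_id"] - 1])

    row["corn"] = float(raw["corn"])
    row["grid_id"] = float(raw["grid_id"])
    row["interest_rate"] = float(raw["rate"])
    row["ldg"], row["cdg"], row["dmi"] = map(float, (raw["ldg"], raw["cdg"], raw["dmi"]))
    fyp = market.fyp_from_corn(raw["corn"], params)
    row["fyp"] = float(fyp)

    # per-endpoint biology and grade mixes
    fbw, hcw, heavy, yg_prop, qg_prop, grid_adj = {}, {}, {}, {}, {}, {}
    for ep in (1, 2, 3, 4):
        extra = 0 if ep == 1 else EXTRA_DOF[ep]
        fbw[ep] = cattle.weights_at_endpoint(raw["fbw1"], raw["ldg"], extra)
        hcw[ep] = cattle.weights_at_endpoint(raw["hcw1"], raw["cdg"], extra)
        heavy[ep] = cattle.heavyweight_fraction(hcw[ep], params)
        if ep == 1:
            yg_l, qg_l = raw["yg_l1"], raw["qg_l1"]
        else:
            yg_l = cattle.shift_grade_logits(raw["yg_l1"], raw["yg_b"][ep - 2])
            qg_l = cattle.shift_grade_logits(raw["qg_l1"], raw["qg_b"][ep - 2])
        yg_prop[ep] = cattle.cumlogits_to_proportions(yg_l)
        qg_prop[ep] = cattle.cumlogits_to_proportions(qg_l)
        grid_adj[ep] = economics.grid_adjustment(
            qg_prop[ep], yg_prop[ep], heavy[ep], qg_grid, yg_grid, params.heavy_discount)
        row[f"fbw_ep{ep}"] = float(fbw[ep])
        row[f"hcw_ep{ep}"] = float(hcw[ep])
        row[f"heavy_ep{ep}"] = float(heavy[ep])
        row[f"live_price_ep{ep}"] = float(raw["live"][ep - 1])
        row[f"dressed_base_ep{ep}"] = float(raw["dressed"][ep - 1])
        for name, v in zip(_YG_NAMES, yg_prop[ep]):
            row[f"{name}_ep{ep}"] = float(v)
        for name, v in zip(_QG_NAMES, qg_prop[ep]):
            row[f"{name}_ep{ep}"] = float(v)

    # EP1 revenue per basis (the baseline the budget compares against)
    tr1 = {
        "live": economics.revenue_live(params.pen_size, fbw[1], raw["live"][0], params.cwt_kg),
        "dressed": economics.revenue_dressed(params.pen_size, hcw[1], raw["dressed"][0], params.cwt_kg),
        "grid": economics.revenue_grid(params.pen_size, hcw[1], raw["dressed"][0],
                                       grid_adj[1], params.cwt_kg),
    }
    for basis in BASES:
        row[f"tr_ep1_{basis}"] = float(tr1[basis])

    head = params.pen_size
    morb_tot = mort_tot = rem_tot = 0
    hddays_tot = 0.0
    rrem_tot = 0.0
    for ep in (2, 3, 4):
        k = ep - 2
        head = head - int(raw["mort"][k]) - int(raw["rem"][k])
        morb_tot += int(raw["morb"][k])
        mort_tot += int(raw["mort"][k])
        rem_tot += int(raw["rem"][k])
        hddays_tot = hddays_tot + raw["hddays"][k]
        p_rem = market.removal_price(raw["live"][ep - 2], params)
        rrem_tot = rrem_tot + economics.removal_revenue(
            raw["rem"][k], hcw[ep - 1], p_rem, params.cwt_kg)

        ifrac = economics.interest_fraction(raw["rate"], EXTRA_DOF[ep])
        dmi_total = health.pen_total_dmi(raw["dmi"], hddays_tot)
        fyc = economics.feed_yardage_cost(fyp, dmi_total, ifrac, params.ton_kg)
        healthc = economics.health_cost(morb_tot, mort_tot, params)
        row[f"mort_total_ep{ep}"] = float(mort_tot)
        row[f"rem_total_ep{ep}"] = float(rem_tot)
        row[f"morb_total_ep{ep}"] = float(morb_tot)
        row[f"hd_ep{ep}"] = float(head)
        row[f"hddays_total_ep{ep}"] = float(hddays_tot)
        row[f"rrem_total_ep{ep}"] = float(rrem_tot)
        row[f"fyc_ep{ep}"] = float(fyc)
        row[f"healthc_ep{ep}"] = float(healthc)
        row[f"live_diff_ep{ep}"] = float(raw["live"][ep - 1] - raw["live"][0])
        row[f"dressed_diff_ep{ep}"] = float(raw["dressed"][ep - 1] - raw["dressed"][0])

        fcr = {
            "live": economics.revenue_live(head, fbw[ep], raw["live"][ep - 1], params.cwt_kg),
            "dressed": economics.revenue_dressed(head, hcw[ep], raw["dressed"][ep - 1], params.cwt_kg),
            "grid": economics.revenue_grid(head, hcw[ep], raw["dressed"][ep - 1],
                                           grid_adj[ep], params.cwt_kg),
        }
        for basis in BASES:
            oc = economics.opportunity_cost(tr1[basis], ifrac)
            tc = oc + fyc + healthc
            tr = fcr[basis] + rrem_tot
            pen, per_head = economics.net_return_difference(tr, tc, tr1[basis], head, rem_tot)
            row[f"oc_{basis}_ep{ep}"] = float(oc)
            row[f"dnr_head_{basis}_ep{ep}"] = float(per_head)
    return row


# ---------------------------------------------------------------------------
# vectorized path


def _stack_raws(raws: list[dict]) -> dict[str, np.ndarray]:
    out = {}
    for key in raws[0]:
        out[key] = np.stack([np.asarray(r[key]) for r in raws])
    return out


def _compute_block(params: ModelParameters, raw: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Array counterpart of :func:`run_iteration`'s accounting."""
    n = raw["fbw1"].shape[0]
    cols: dict[str, np.ndarray] = {}
    yg_grid = np.asarray(params.yg_grid)
    qg_grids = np.asarray(params.qg_grids)
    qg_grid = qg_grids[raw["grid_id"].astype(int) - 1]

    cols["corn"] = raw["corn"]
    cols["grid_id"] = raw["grid_id"].astype(float)
    cols["interest_rate"] = raw["rate"]
    cols["ldg"], cols["cdg"], cols["dmi"] = raw["ldg"], raw["cdg"], raw["dmi"]
    fyp = market.fyp_from_corn(raw["corn"], params)
    cols["fyp"] = fyp

    fbw, hcw, heavy, yg_prop, qg_prop, grid_adj = {}, {}, {}, {}, {}, {}
    for ep in (1, 2, 3, 4):
        extra = 0 if ep == 1 else EXTRA_DOF[ep]
        fbw[ep] = cattle.weights_at_endpoint(raw["fbw1"], raw["ldg"], extra)
        hcw[ep] = cattle.weights_at_endpoint(raw["hcw1"], raw["cdg"], extra)
        heavy[ep] = cattle.heavyweight_fraction(hcw[ep], params)
        if ep == 1:
            yg_l, qg_l = raw["yg_l1"], raw["qg_l1"]
        else:
            yg_l = cattle.shift_grade_logits(raw["yg_l1"], raw["yg_b"][:, ep - 2])
            qg_l = cattle.shift_grade_logits(raw["qg_l1"], raw["qg_b"][:, ep - 2])
        yg_prop[ep] = cattle.cumlogits_to_proportions(yg_l)
        qg_prop[ep] = cattle.cumlogits_to_proportions(qg_l)
        grid_adj[ep] = economics.grid_adjustment(
            qg_prop[ep], yg_prop[ep], heavy[ep], qg_grid, yg_grid, params.heavy_discount)
        cols[f"fbw_ep{ep}"] = fbw[ep]
        cols[f"hcw_ep{ep}"] = hcw[ep]
        cols[f"heavy_ep{ep}"] = heavy[ep]
        cols[f"live_price_ep{ep}"] = raw["live"][:, ep - 1]
        cols[f"dressed_base_ep{ep}"] = raw["dressed"][:, ep - 1]
        for j, name in enumerate(_YG_NAMES):
            cols[f"{name}_ep{ep}"] = yg_prop[ep][:, j]
        for j, name in enumerate(_QG_NAMES):
            cols[f"{name}_ep{ep}"] = qg_prop[ep][:, j]

    tr1 = {
        "live": economics.revenue_live(params.pen_size, fbw[1], raw["live"][:, 0], params.cwt_kg),
        "dressed": economics.revenue_dressed(params.pen_size, hcw[1], raw["dressed"][:, 0], params.cwt_kg),
        "grid": economics.revenue_grid(params.pen_size, hcw[1], raw["dressed"][:, 0],
                                       grid_adj[1], params.cwt_kg),
    }
    for basis in BASES:
        cols[f"tr_ep1_{basis}"] = tr1[basis]

    head = np.full(n, float(params.pen_size))
    morb_tot = np.zeros(n)
    mort_tot = np.zeros(n)
    rem_tot = np.zeros(n)
    hddays_tot = np.zeros(n)
    rrem_tot = np.zeros(n)
    for ep in (2, 3, 4):
        k = ep - 2
        head = head - raw["mort"][:, k] - raw["rem"][:, k]
        morb_tot = morb_tot + raw["morb"][:, k]
        mort_tot = mort_tot + raw["mort"][:, k]
        rem_tot = rem_tot + raw["rem"][:, k]
        hddays_tot = hddays_tot + raw["hddays"][:, k]
        p_rem = market.removal_price(raw["live"][:, ep - 2], params)
        rrem_tot = rrem_tot + economics.removal_revenue(
            raw["rem"][:, k], hcw[ep - 1], p_rem, params.cwt_kg)

        ifrac = economics.interest_fraction(raw["rate"], EXTRA_DOF[ep])
        dmi_total = health.pen_total_dmi(raw["dmi"], hddays_tot)
        fyc = economics.feed_yardage_cost(fyp, dmi_total, ifrac, params.ton_kg)
        healthc = economics.health_cost(morb_tot, mort_tot, params)
        cols[f"mort_total_ep{ep}"] = mort_tot.astype(float)
        cols[f"rem_total_ep{ep}"] = rem_tot.astype(float)
        cols[f"morb_total_ep{ep}"] = morb_tot.astype(float)
        cols[f"hd_ep{ep}"] = head.astype(float)
        cols[f"hddays_total_ep{ep}"] = hddays_tot
        cols[f"rrem_total_ep{ep}"] = rrem_tot
        cols[f"fyc_ep{ep}"] = fyc
        cols[f"healthc_ep{ep}"] = healthc
        cols[f"live_diff_ep{ep}"] = raw["live"][:, ep - 1] - raw["live"][:, 0]
        cols[f"dressed_diff_ep{ep}"] = raw["dressed"][:, ep - 1] - raw["dressed"][:, 0]

        fcr = {
            "live": economics.revenue_live(head, fbw[ep], raw["live"][:, ep - 1], params.cwt_kg),
            "dressed": economics.revenue_dressed(head, hcw[ep], raw["dressed"][:, ep - 1], params.cwt_kg),
            "grid": economics.revenue_grid(head, hcw[ep], raw["dressed"][:, ep - 1],
                                           grid_adj[ep], params.cwt_kg),
        }
        for basis in BASES:
            oc = economics.opportunity_cost(tr1[basis], ifrac)
            tc = oc + fyc + healthc
            tr = fcr[basis] + rrem_tot
            pen, per_head = economics.net_return_difference(tr, tc, tr1[basis], head, rem_tot)
            cols[f"oc_{basis}_ep{ep}"] = oc
            cols[f"dnr_head_{basis}_ep{ep}"] = per_head
    return cols


def run_simulation(
    params: ModelParameters,
    corrs: CorrelationSet,
    n: int,
    master_seed: int,
    vectorized: bool = True,
    start: int = 0,
) -> pd.DataFrame:
    """Simulate iterations ``start .. start+n-1``, one row per iteration.

    The two paths (vectorized and plain per-pen) consume the same
    per-iteration streams and produce identical tables.  ``start`` lets the
    convergence loop append new blocks without re-drawing earlier iterations.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    counter = RepairCounter()
    t0 = time.perf_counter()
    ids = range(start, start + n)
    if vectorized:
        raws = [_draw_raw(params, corrs, stream(master_seed, i), counter) for i in ids]
        cols = _compute_block(params, _stack_raws(raws))
        df = pd.DataFrame(cols)
    else:
        rows = [run_iteration(params, corrs, stream(master_seed, i), counter) for i in ids]
        df = pd.DataFrame(rows)
    df.insert(0, "iteration", np.arange(start, start + n))
    if counter.redraws or counter.fallback_sorts:
        logger.info("grade-threshold monotonicity repairs: %d redraws, %d fallback sorts",
                    counter.redraws, counter.fallback_sorts)
    logger.info("simulated %d iterations in %.1f s (%s path)",
                n, time.perf_counter() - t0, "vectorized" if vectorized else "reference")
    return df


# ---------------------------------------------------------------------------
# convergence

CONVERGENCE_PERCENTILES = (0.5, 2.5, 10.0, 25.0, 75.0, 90.0, 97.5, 99.5)
_DNR_COLS = [f"dnr_head_{b}_ep{ep}" for b in BASES for ep in (2, 3, 4)]


@dataclass
class ConvergenceReport:
    """Percentile stability between successive cumulative iteration counts."""

    counts: list[int] = field(default_factory=list)
    max_rel_change: float = float("nan")
    failing: list[str] = field(default_factory=list)
    converged: bool = False

    @property
    def final_n(self) -> int:
        return self.counts[-1] if self.counts else 0


def check_convergence(
    results: pd.DataFrame,
    prev_n: int,
    percentiles=CONVERGENCE_PERCENTILES,
    tol: float = 0.01,
    floor: float = 0.01,
) -> ConvergenceReport:
    """Compare the listed percentiles of every net-return series at the
    previous cumulative count (first ``prev_n`` rows) against the full table.

    Converged iff every percentile of every basis x endpoint series moved by
    less than ``tol`` relative change (denominator floored at ``floor`` $ so a
    percentile sitting near zero cannot block convergence; the median is
    deliberately not part of the gate).
    """
    if not (0 < prev_n < len(results)):
        raise ValueError("need two distinct cumulative counts to compare")
    q = np.asarray(percentiles) / 100.0
    report = ConvergenceReport(counts=[prev_n, len(results)])
    worst = 0.0
    for col in _DNR_COLS:
        prev = results[col].iloc[:prev_n].quantile(q).to_numpy()
        curr = results[col].quantile(q).to_numpy()
        rel = np.abs(curr - prev) / np.maximum(np.abs(prev), floor)
        worst = max(worst, float(rel.max()))
        for pct, r in zip(percentiles, rel):
            if r >= tol:
                report.failing.append(f"{col}@p{pct}: {r:.3%}")
    report.max_rel_change = worst
    report.converged = not report.failing
    return report


def run_to_convergence(
    params: ModelParameters,
    corrs: CorrelationSet,
    master_seed: int,
    initial: int = 135_000,
    step: int = 45_000,
    max_n: int = 1_035_000,
    tol: float = 0.01,
) -> tuple[pd.DataFrame, ConvergenceReport]:
    """Grow the simulation ``initial, +step, ...`` until percentiles stabilize.

    Because streams are keyed per iteration, the cumulative table after each
    growth step is identical to a single run of that size.
    """
    df = run_simulation(params, corrs, initial, master_seed)
    counts = [initial]
    while True:
        block = run_simulation(params, corrs, step, master_seed, start=len(df))
        prev_n = len(df)
        df = pd.concat([df, block], ignore_index=True)
        counts.append(len(df))
        report = check_convergence(df, prev_n, tol=tol)
        report.counts = counts.copy()
        if report.converged:
            logger.info("converged at n=%d (max relative change %.3f%%)",
                        len(df), 100 * report.max_rel_change)
            return df, report
        if len(df) + step > max_n:
            logger.warning("stopping at n=%d without convergence", len(df))
            return df, report
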