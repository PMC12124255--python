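"""Pen-level cattle biology.

Baseline (EP1) final body weight and hot carcass weight, linear weight gain
to the later endpoints, the within-pen heavyweight carcass fraction, the
cumulative-logit Yield/Quality Grade machinery (baseline threshold draws,
proportional-odds shifts for later endpoints, differencing into grade
proportion vectors), and dry matter intake.

The pen — not the individual animal — is the unit of simulation.  Grade
vectors are ordered highest grade first (YG5..YG1; Prime..sub-Select),
matching the cumulative "grade j or better" thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, ndtr

from .params import ModelParameters, CorrelationSet
from .stochastic import cholesky_factor, correlated_draws

__all__ = [
    "RepairCounter",
    "simulate_ep1_weights",
    "simulate_gains",
    "weights_at_endpoint",
    "heavyweight_fraction",
    "simulate_baseline_grade_logits",
    "simulate_grade_betas",
    "cumlogits_to_proportions",
    "shift_grade_logits",
    "simulate_dmi",
]


@dataclass
class RepairCounter:
    """Counts of monotonicity repairs applied to grade-threshold draws."""

    redraws: int = 0
    fallback_sorts: int = 0


def simulate_ep1_weights(
    params: ModelParameters, corrs: CorrelationSet, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n x 2`` correlated normal draws of EP1 (FBW, HCW) pen means, kg."""
    locs = [params.ep1_fbw.mean, params.ep1_hcw.mean]
    scales = [params.ep1_fbw.sd, params.ep1_hcw.sd]
    return correlated_draws(locs, scales, corrs.fbw_hcw_ep1, "normal", n, rng)


def simulate_gains(
    params: ModelParameters, corrs: CorrelationSet, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n x 2`` correlated normal draws of (live, carcass) daily gain, kg/day."""
    locs = [params.live_gain.mean, params.carcass_gain.mean]
    scales = [params.live_gain.sd, params.carcass_gain.sd]
    return correlated_draws(locs, scales, corrs.gains, "normal", n, rng)


def weights_at_endpoint(ep1_weight, gain, extra_dof):
    """Pen mean weight after ``extra_dof`` additional days at ``gain`` kg/day.

    The same drawn gain is reused across all later endpoints of one pen, so
    weight grows exactly linearly in added days on feed.
    """
    extra_dof = np.asarray(extra_dof)
    if np.any(extra_dof < 0):
        raise ValueError("extra_dof must be >= 0")
    return ep1_weight + gain * extra_dof


def heavyweight_fraction(hcw_mean, params: ModelParameters):
    """Fraction of individual carcasses above the heavyweight threshold.

    Individual carcasses are taken as Normal(pen mean HCW, fixed within-pen
    SD); the heavy fraction is the upper tail beyond the threshold:
    ``1 - Phi((threshold - hcw_mean) / sd)``.
    """
    z = (params.heavy_threshold - hcw_mean) / params.within_pen_hcw_sd
    return 1.0 - ndtr(z)


def _rows_monotone(logits: np.ndarray) -> np.ndarray:
    return np.all(np.diff(logits, axis=-1) > 0.0, axis=-1)


def simulate_baseline_grade_logits(
    intercepts,
    corr: np.ndarray,
    n: int,
    rng: np.random.Generator,
    max_redraws: int = 100,
    counter: RepairCounter | None = None,
) -> np.ndarray:
    """``n x k`` correlated logistic draws of cumulative-logit thresholds.

    ``intercepts`` is a sequence of ``(location, scale)`` pairs ordered from
    the highest-grade threshold downward with strictly increasing locations.
    Correlated draws can rarely produce a crossed (non-monotone) threshold
    vector; offending rows are re-drawn up to ``max_redraws`` times and, if
    still crossed, repaired by sorting ascending (equivalently sorting the
    cumulative probabilities descending).  ``counter`` accumulates how often
    either repair fired.
    """
    locs = np.asarray([p[0] for p in intercepts], dtype=float)
    scales = np.asarray([p[1] for p in intercepts], dtype=float)
    if not np.all(np.diff(locs) > 0):
        raise ValueError("threshold locations must be strictly increasing")
    out = correlated_draws(locs, scales, corr, "logistic", n, rng)
    bad = ~_rows_monotone(out)
    tries = 0
    while np.any(bad) and tries < max_redraws:
        nbad = int(bad.sum())
        if counter is not None:
            counter.redraws += nbad
        out[bad] = correlated_draws(locs, scales, corr, "logistic", nbad, rng)
        bad = ~_rows_monotone(out)
        tries += 1
    if np.any(bad):
        if counter is not None:
            counter.fallback_sorts += int(bad.sum())
        out[bad] = np.sort(out[bad], axis=-1)
    return out


def simulate_grade_betas(
    betas, corr: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """``n x 3`` correlated logistic draws of proportional-odds shifts (EP2–EP4)."""
    locs = [p[0] for p in betas]
    scales = [p[1] for p in betas]
    return correlated_draws(locs, scales, corr, "logistic", n, rng)


def cumlogits_to_proportions(logits) -> np.ndarray:
    """Difference increasing cumulative logits into grade proportions.

    For thresholds ``L_1 < ... < L_k`` (highest grade first), the top category
    gets ``f(L_1)``, interior category ``j`` gets ``f(L_j) - f(L_{j-1})``, and
    the bottom (referent) category gets ``1 - f(L_k)``, with ``f`` the logistic
    function; the k+1 proportions sum to 1 by construction.  Accepts a single
    vector or an ``... x k`` batch.
    """
    logits = np.asarray(logits, dtype=float)
    if not np.all(np.diff(logits, axis=-1) > 0.0):
        raise ValueError("cumulative logits must be strictly increasing")
    cum = expit(logits)
    top = cum[..., :1]
    interior = np.diff(cum, axis=-1)
    bottom = 1.0 - cum[..., -1:]
    return np.concatenate([top, interior, bottom], axis=-1)


def shift_grade_logits(baseline_logits, beta):
    """Shift every threshold by the same beta (proportional odds).

    Positive beta moves cumulative probability upward, i.e. more mass on
    higher grades at every cumulative cut.
    """
    baseline_logits = np.asarray(baseline_logits, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.ndim:
        beta = beta[..., None]
    return baseline_logits + beta


def simulate_dmi(params: ModelParameters, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` normal draws of per-animal daily dry matter intake, kg/day.

    One value per pen, reused across every later endpoint of that pen (the
    source trial found no evidence of intake changing over these added days).
    """
    return params.dmi.mean + params.dmi.sd * rng.standard_normal(n)
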