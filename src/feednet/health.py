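"""Health events and animal-day accounting.

Morbidity, mortality, and removal counts are Poisson over the animal-days at
risk in each 14-day interval between endpoints.  Mortalities and removals
leave the pen (reducing exposure for later intervals) and are assumed to exit
midway through their interval; morbidities accumulate cost but keep the
animal on feed.  Cumulative counts carry over endpoint to endpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters
from .stochastic import poisson_draw

__all__ = [
    "HealthLedger",
    "expected_animal_days",
    "simulate_interval_events",
    "advance_ledger",
    "pen_total_dmi",
    "simulate_health_paths",
]


def expected_animal_days(head_at_start, dof):
    """Animal-days at risk for an interval: head count x days on feed."""
    head_at_start = np.asarray(head_at_start)
    if np.any(head_at_start < 0):
        raise ValueError("head count must be >= 0")
    return head_at_start * dof


def _cap_events(head, mort, rem):
    # Total fallouts cannot exceed the animals present: truncate removals
    # first, then mortalities.  Astronomically rare at the default rates but
    # keeps the update total.
    head = np.asarray(head)
    mort = np.asarray(mort)
    rem = np.asarray(rem)
    over = np.maximum(mort + rem - head, 0)
    rem = rem - np.minimum(rem, over)
    mort = np.minimum(mort, head - rem)
    return mort, rem


def simulate_interval_events(head_at_start, params: ModelParameters, rng: np.random.Generator):
    """Draw (morb, mort, rem) counts for one interval.

    Each count is Poisson with mean ``rate x head x dof_step``; mort + rem is
    capped at the available head count.  ``head_at_start`` may be a scalar or
    an array (one pen per entry).
    """
    exp_days = expected_animal_days(head_at_start, params.dof_step)
    n = np.asarray(exp_days).size
    scalar = np.ndim(head_at_start) == 0
    morb = poisson_draw(params.morb_rate * exp_days, n, rng)
    mort = poisson_draw(params.mort_rate * exp_days, n, rng)
    rem = poisson_draw(params.rem_rate * exp_days, n, rng)
    mort, rem = _cap_events(head_at_start, mort, rem)
    if scalar:
        return int(morb[0]), int(mort[0]), int(rem[0])
    return morb, mort, rem


@dataclass
class HealthLedger:
    """Running per-pen health state across the 14-day intervals.

    ``head`` is the count after the most recent interval; per-interval lists
    are indexed by interval (EP2, EP3, EP4).  Totals are running sums from
    zero at EP1.
    """

    head: int = 200
    morb: list[int] = field(default_factory=list)
    mort: list[int] = field(default_factory=list)
    rem: list[int] = field(default_factory=list)
    hddays: list[float] = field(default_factory=list)

    @property
    def morb_total(self) -> int:
        return sum(self.morb)

    @property
    def mort_total(self) -> int:
        return sum(self.mort)

    @property
    def rem_total(self) -> int:
        return sum(self.rem)

    @property
    def hddays_total(self) -> float:
        return sum(self.hddays)


def advance_ledger(ledger: HealthLedger, interval_events, dof: int = 14) -> HealthLedger:
    """Apply one interval's (morb, mort, rem) and return the next-EP ledger.

    Head drops by the fallouts; the interval's effective animal-days credit
    the full ``dof`` to survivors and half to fallouts (midpoint exit).
    """
    morb, mort, rem = interval_events
    if mort + rem > ledger.head:
        raise ValueError("mort + rem exceeds available head count")
    hddays = ledger.head * dof - (mort + rem) * (dof / 2.0)
    return HealthLedger(
        head=ledger.head - mort - rem,
        morb=ledger.morb + [morb],
        mort=ledger.mort + [mort],
        rem=ledger.rem + [rem],
        hddays=ledger.hddays + [hddays],
    )


def pen_total_dmi(dmi_per_day, cumulative_hddays):
    """Total pen dry matter intake, kg: per-animal daily DMI x animal-days."""
    dmi_per_day = np.asarray(dmi_per_day)
    cumulative_hddays = np.asarray(cumulative_hddays)
    if np.any(dmi_per_day < 0) or np.any(cumulative_hddays < 0):
        raise ValueError("inputs must be >= 0")
    return dmi_per_day * cumulative_hddays


def simulate_health_paths(
    params: ModelParameters, n: int, rng: np.random.Generator, n_intervals: int = 3
) -> dict[str, np.ndarray]:
    """Vectorized health ledgers for ``n`` pens over the between-EP intervals.

    Returns arrays: ``morb``/``mort``/``rem`` (n x intervals, per interval),
    ``head`` (n x intervals+1, including the starting pen size), ``hddays``
    (n x intervals), and cumulative ``*_total``/``hddays_total`` counterparts.
    """
    head = np.full(n, params.pen_size, dtype=np.int64)
    heads = [head.copy()]
    morb = np.empty((n, n_intervals), dtype=np.int64)
    mort = np.empty((n, n_intervals), dtype=np.int64)
    rem = np.empty((n, n_intervals), dtype=np.int64)
    hddays = np.empty((n, n_intervals), dtype=float)
    for t in range(n_intervals):
        mo, mt, rm = simulate_interval_events(head, params, rng)
        hddays[:, t] = head * params.dof_step - (mt + rm) * (params.dof_step / 2.0)
        head = head - mt - rm
        morb[:, t], mort[:, t], rem[:, t] = mo, mt, rm
        heads.append(head.copy())
    return {
        "morb": morb,
        "mort": mort,
        "rem": rem,
        "head": np.stack(heads, axis=1),
        "hddays": hddays,
        "morb_total": np.cumsum(morb, axis=1),
        "mort_total": np.cumsum(mort, axis=1),
        "rem_total": np.cumsum(rem, axis=1),
        "hddays_total": np.cumsum(hddays, axis=1),
    }
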