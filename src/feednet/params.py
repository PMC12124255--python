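"""Model parameters and correlation structure.

Every constant the simulation uses — distribution means and SDs, fixed prices,
the premium/discount grids, regression coefficients, and unit conversions —
lives in :class:`ModelParameters`.  The within- and between-variable
correlation matrices live in :class:`CorrelationSet`.  The packaged YAML file
``data/default_params.yaml`` is the single source of the default values; user
configs override any subset of keys.

Grade-ordered vectors follow one convention throughout the package: Yield
Grade proportions and grid values are ordered YG5, YG4, YG3, YG2, YG1 and
Quality Grade vectors Prime, Choice, Select, sub-Select (highest cumulative
threshold first), matching the cumulative-logit thresholds.
"""

from __future__ import annotations

import copy
import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field, fields

import numpy as np
import yaml

logger = logging.getLogger("feednet")

__all__ = [
    "MeanSD",
    "ModelParameters",
    "CorrelationSet",
    "load_default_parameters",
    "load_default_correlations",
    "load_defaults",
    "load_overrides",
    "save_config",
    "validate",
]


@dataclass(frozen=True)
class MeanSD:
    """A (mean, SD) pair on the natural scale of the variable."""

    mean: float
    sd: float


def _pairs(x) -> tuple[tuple[float, float], ...]:
    return tuple((float(a), float(b)) for a, b in x)


@dataclass
class ModelParameters:
    """All scalar and tabular inputs of the simulation.

    Cumulative-logit entries are ``(location, scale)`` pairs on the log-odds
    scale; health rates are events per animal-day.
    """

    corn_price: MeanSD
    live_price: MeanSD
    dmi: MeanSD
    ep1_fbw: MeanSD
    ep1_hcw: MeanSD
    live_gain: MeanSD
    carcass_gain: MeanSD
    within_pen_hcw_sd: float
    heavy_threshold: float
    mort_rate: float
    rem_rate: float
    morb_rate: float
    yg_intercepts: tuple[tuple[float, float], ...]
    yg_betas: tuple[tuple[float, float], ...]
    qg_intercepts: tuple[tuple[float, float], ...]
    qg_betas: tuple[tuple[float, float], ...]
    dress_ratio: float
    cwt_kg: float
    ton_kg: float
    dof_step: int
    pen_size: int
    yg_grid: tuple[float, ...]
    heavy_discount: float
    qg_grids: tuple[tuple[float, ...], ...]
    interest_rates: tuple[float, ...]
    treat_cost: float
    render_cost: float
    fyp_coeffs: tuple[float, float, float]
    cow_coeffs: tuple[float, float]
    cull_factor: float
    prime_coeffs: tuple[float, float, float]
    subselect_coeffs: tuple[float, float, float]

    def to_dict(self) -> dict:
        return {
            "corn_price": {"mean": self.corn_price.mean, "sd": self.corn_price.sd},
            "live_price": {"mean": self.live_price.mean, "sd": self.live_price.sd},
            "dmi": {"mean": self.dmi.mean, "sd": self.dmi.sd},
            "ep1_fbw": {"mean": self.ep1_fbw.mean, "sd": self.ep1_fbw.sd},
            "ep1_hcw": {"mean": self.ep1_hcw.mean, "sd": self.ep1_hcw.sd},
            "live_gain": {"mean": self.live_gain.mean, "sd": self.live_gain.sd},
            "carcass_gain": {"mean": self.carcass_gain.mean, "sd": self.carcass_gain.sd},
            "within_pen_hcw_sd": self.within_pen_hcw_sd,
            "heavy_threshold": self.heavy_threshold,
            "mort_rate": self.mort_rate,
            "rem_rate": self.rem_rate,
            "morb_rate": self.morb_rate,
            "yg_intercepts": [list(p) for p in self.yg_intercepts],
            "yg_betas": [list(p) for p in self.yg_betas],
            "qg_intercepts": [list(p) for p in self.qg_intercepts],
            "qg_betas": [list(p) for p in self.qg_betas],
            "dress_ratio": self.dress_ratio,
            "cwt_kg": self.cwt_kg,
            "ton_kg": self.ton_kg,
            "dof_step": self.dof_step,
            "pen_size": self.pen_size,
            "yg_grid": list(self.yg_grid),
            "heavy_discount": self.heavy_discount,
            "qg_grids": [list(g) for g in self.qg_grids],
            "interest_rates": list(self.interest_rates),
            "treat_cost": self.treat_cost,
            "render_cost": self.render_cost,
            "fyp_coeffs": list(self.fyp_coeffs),
            "cow_coeffs": list(self.cow_coeffs),
            "cull_factor": self.cull_factor,
            "prime_coeffs": list(self.prime_coeffs),
            "subselect_coeffs": list(self.subselect_coeffs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(d)
        if missing:
            raise KeyError(f"missing parameter keys: {sorted(missing)}")
        ms = lambda v: MeanSD(float(v["mean"]), float(v["sd"]))
        return cls(
            corn_price=ms(d["corn_price"]),
            live_price=ms(d["live_price"]),
            dmi=ms(d["dmi"]),
            ep1_fbw=ms(d["ep1_fbw"]),
            ep1_hcw=ms(d["ep1_hcw"]),
            live_gain=ms(d["live_gain"]),
            carcass_gain=ms(d["carcass_gain"]),
            within_pen_hcw_sd=float(d["within_pen_hcw_sd"]),
            heavy_threshold=float(d["heavy_threshold"]),
            mort_rate=float(d["mort_rate"]),
            rem_rate=float(d["rem_rate"]),
            morb_rate=float(d["morb_rate"]),
            yg_intercepts=_pairs(d["yg_intercepts"]),
            yg_betas=_pairs(d["yg_betas"]),
            qg_intercepts=_pairs(d["qg_intercepts"]),
            qg_betas=_pairs(d["qg_betas"]),
            dress_ratio=float(d["dress_ratio"]),
            cwt_kg=float(d["cwt_kg"]),
            ton_kg=float(d["ton_kg"]),
            dof_step=int(d["dof_step"]),
            pen_size=int(d["pen_size"]),
            yg_grid=tuple(float(v) for v in d["yg_grid"]),
            heavy_discount=float(d["heavy_discount"]),
            qg_grids=tuple(tuple(float(v) for v in g) for g in d["qg_grids"]),
            interest_rates=tuple(float(v) for v in d["interest_rates"]),
            treat_cost=float(d["treat_cost"]),
            render_cost=float(d["render_cost"]),
            fyp_coeffs=tuple(float(v) for v in d["fyp_coeffs"]),
            cow_coeffs=tuple(float(v) for v in d["cow_coeffs"]),
            cull_factor=float(d["cull_factor"]),
            prime_coeffs=tuple(float(v) for v in d["prime_coeffs"]),
            subselect_coeffs=tuple(float(v) for v in d["subselect_coeffs"]),
        )


_CORR_FIELDS = {
    "fbw_hcw_ep1": 2,
    "gains": 2,
    "live_price_eps": 4,
    "yg_intercepts": 4,
    "qg_intercepts": 3,
    "yg_betas": 3,
    "qg_betas": 3,
}


@dataclass
class CorrelationSet:
    """Correlation matrices for the correlated draw blocks.

    Each matrix must be symmetric, positive definite, with unit diagonal.
    ``placeholder`` marks matrices that stand in for unpublished values.
    """

    fbw_hcw_ep1: np.ndarray
    gains: np.ndarray
    live_price_eps: np.ndarray
    yg_intercepts: np.ndarray
    qg_intercepts: np.ndarray
    yg_betas: np.ndarray
    qg_betas: np.ndarray
    placeholder: bool = False

    def __post_init__(self):
        for name, k in _CORR_FIELDS.items():
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"correlations.{name}: expected shape ({k}, {k}), got {m.shape}")
            setattr(self, name, m)

    def to_dict(self) -> dict:
        d = {name: getattr(self, name).tolist() for name in _CORR_FIELDS}
        d["placeholder"] = bool(self.placeholder)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CorrelationSet":
        unknown = set(d) - set(_CORR_FIELDS) - {"placeholder"}
        if unknown:
            raise KeyError(f"unknown correlation keys: {sorted(unknown)}")
        missing = set(_CORR_FIELDS) - set(d)
        if missing:
            raise KeyError(f"missing correlation keys: {sorted(missing)}")
        return cls(
            **{name: np.asarray(d[name], dtype=float) for name in _CORR_FIELDS},
            placeholder=bool(d.get("placeholder", False)),
        )


# ---------------------------------------------------------------------------
# loading / saving


def _read_packaged_defaults() -> dict:
    ref = importlib.resources.files("feednet").joinpath("data/default_params.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def load_default_parameters() -> ModelParameters:
    """Return the packaged default :class:`ModelParameters`."""
    return ModelParameters.from_dict(_read_packaged_defaults()["parameters"])


def load_default_correlations() -> CorrelationSet:
    """Return the packaged default (placeholder) :class:`CorrelationSet`."""
    corrs = CorrelationSet.from_dict(_read_packaged_defaults()["correlations"])
    if corrs.placeholder:
        logger.warning(
            "using PLACEHOLDER correlation matrices; supply the published "
            "matrices via a config override for faithful tail spreads"
        )
    return corrs


def load_defaults() -> tuple[ModelParameters, CorrelationSet]:
    return load_default_parameters(), load_default_correlations()


def _deep_merge(base: dict, override: dict, path: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        here = f"{path}.{key}" if path else key
        if key not in base:
            raise KeyError(f"unknown config key: {here}")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(base[key], val, here)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_overrides(path) -> tuple[ModelParameters, CorrelationSet]:
    """Load defaults with user overrides from a YAML (or JSON) file.

    The file may contain any subset of the ``parameters`` / ``correlations``
    keys of the packaged default file; unknown keys raise ``KeyError``, and the
    merged result must still satisfy all invariants (:func:`validate` raises a
    ``ValueError`` listing every violation otherwise).
    """
    with open(path) as fh:
        user = yaml.safe_load(fh)
    defaults = _read_packaged_defaults()
    if user is None:
        user = {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    top_unknown = set(user) - {"parameters", "correlations"}
    if top_unknown:
        raise KeyError(f"unknown top-level config keys: {sorted(top_unknown)}")
    merged = _deep_merge(defaults, user)
    if "correlations" in user:
        # user matrices replace the placeholders wholesale
        merged["correlations"]["placeholder"] = bool(
            user["correlations"].get("placeholder", False)
        )
    params = ModelParameters.from_dict(merged["parameters"])
    corrs = CorrelationSet.from_dict(merged["correlations"])
    violations = validate(params, corrs)
    if violations:
        raise ValueError("invalid merged config:\n  " + "\n  ".join(violations))
    return params, corrs


def save_config(params: ModelParameters, corrs: CorrelationSet, path) -> None:
    """Serialize a full configuration to YAML (round-trips bit-exactly)."""
    doc = {"parameters": params.to_dict(), "correlations": corrs.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# validation


def _check_corr(name: str, m: np.ndarray, out: list[str]) -> None:
    if not np.allclose(m, m.T, atol=1e-12):
        out.append(f"correlations.{name}: not symmetric")
        return
    if not np.allclose(np.diag(m), 1.0, atol=1e-12):
        out.append(f"correlations.{name}: diagonal not 1")
    try:
        np.linalg.cholesky(m)
    except np.linalg.LinAlgError:
        out.append(f"correlations.{name}: Cholesky decomposition failed (not positive definite)")


def validate(params: ModelParameters, corrs: CorrelationSet | None = None) -> list[str]:
    """Check every invariant; return a list of human-readable violations.

    Empty list means the configuration is valid.  This reports rather than
    raises so callers can surface all problems at once.
    """
    v: list[str] = []
    for name in ("corn_price", "live_price", "dmi", "ep1_fbw", "ep1_hcw",
                 "live_gain", "carcass_gain"):
        p: MeanSD = getattr(params, name)
        if p.mean <= 0:
            v.append(f"{name}.mean must be > 0")
        if p.sd <= 0:
            v.append(f"{name}.sd must be > 0")
    for name in ("within_pen_hcw_sd", "heavy_threshold", "mort_rate", "rem_rate",
                 "morb_rate", "cwt_kg", "ton_kg", "treat_cost", "render_cost",
                 "cull_factor"):
        if getattr(params, name) <= 0:
            v.append(f"{name} must be > 0")
    if not (0.0 < params.dress_ratio < 1.0):
        v.append("dress_ratio must be in (0, 1)")
    if params.dof_step <= 0:
        v.append("dof_step must be > 0")
    if params.pen_size <= 0:
        v.append("pen_size must be > 0")

    for name, npairs in (("yg_intercepts", 4), ("qg_intercepts", 3),
                         ("yg_betas", 3), ("qg_betas", 3)):
        pairs = getattr(params, name)
        if len(pairs) != npairs:
            v.append(f"{name}: expected {npairs} (location, scale) pairs")
            continue
        if any(s <= 0 for _, s in pairs):
            v.append(f"{name}: all scales must be > 0")
    locs = [loc for loc, _ in params.yg_intercepts]
    if not all(a < b for a, b in zip(locs, locs[1:])):
        v.append("yg_intercepts: locations must be strictly increasing (YG5 to YG2 threshold)")
    locs = [loc for loc, _ in params.qg_intercepts]
    if not all(a < b for a, b in zip(locs, locs[1:])):
        v.append("qg_intercepts: locations must be strictly increasing (Prime to Select threshold)")

    if len(params.yg_grid) != 5:
        v.append("yg_grid: expected 5 values (YG5..YG1)")
    if len(params.qg_grids) != 3:
        v.append("qg_grids: expected exactly 3 grids")
    for i, grid in enumerate(params.qg_grids, start=1):
        if len(grid) != 4:
            v.append(f"qg_grids[{i}]: expected 4 values (Prime, Choice, Select, sub-Select)")
            continue
        if grid[1] != 0.0:
            v.append(f"qg_grids[{i}]: Choice entry must be exactly 0 (grids anchor on the "
                     f"Choice-Select spread), got {grid[1]}")
    if len(params.interest_rates) != 3:
        v.append("interest_rates: expected exactly 3 rates")
    if any(r <= 0 for r in params.interest_rates):
        v.append("interest_rates: all rates must be > 0")

    if corrs is not None:
        for name in _CORR_FIELDS:
            _check_corr(name, getattr(corrs, name), v)
        lp = corrs.live_price_eps
        # nearer marketing weeks must be at least as correlated as distant ones
        for i in range(4):
            off = [lp[i, j] for j in range(4) if j != i]
            dists = [abs(i - j) for j in range(4) if j != i]
            order = np.argsort(dists)
            vals = np.asarray(off)[order]
            if np.any(np.diff(vals) > 1e-12):
                v.append("correlations.live_price_eps: entries must be non-increasing "
                         "with distance from the diagonal")
                break
    return v
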