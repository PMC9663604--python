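"""Nonlinear least-squares estimation of MRH parameters.

Fits are seeded multi-start trust-region-reflective least squares
(:func:`scipy.optimize.least_squares`) inside physiologic bounds, so a
fixed config+seed always yields bit-identical results.  Repeat-level
summaries average per-repeat parameters and per-repeat derived
quantities (the mean saturation point is the mean of the per-repeat
saturation points, never the saturation point of the mean parameters).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .curve_core import (
    CardinalPoints,
    MRHParameters,
    ResponseCurve,
    cardinal_points,
    mrh_predict,
    r_squared,
)

__all__ = [
    "FitError",
    "FitConfig",
    "FitResult",
    "RepeatSummary",
    "default_initialization",
    "fit_mrh",
    "aggregate_repeats",
    "brute_force_sse_oracle",
]

log = logging.getLogger(__name__)

#: Parameter order used throughout this module.
PARAM_NAMES = ("e", "m", "n", "cp")

DEFAULT_SEED = 20221114


class FitError(RuntimeError):
    """Every start failed to converge; carries best partial diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass(frozen=True)
class FitConfig:
    """Controls for :func:`fit_mrh` (and, via sharing, the RLC fitter).

    ``bounds`` maps parameter name to a (lo, hi) pair and overrides the
    axis-kind defaults from :func:`default_bounds`.
    """

    n_starts: int = 8
    seed: int = DEFAULT_SEED
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_nfev: int = 2000
    bounds: Optional[Mapping[str, tuple[float, float]]] = None

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.max_nfev < 1:
            raise ValueError("max_nfev must be >= 1")

    @classmethod
    def from_dict(cls, data: Mapping) -> "FitConfig":
        known = {k: data[k] for k in data if k in cls.__dataclass_fields__}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown FitConfig keys: {sorted(unknown)}")
        if "bounds" in known and known["bounds"] is not None:
            known["bounds"] = {k: tuple(v) for k, v in known["bounds"].items()}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "FitConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)


@dataclass(frozen=True)
class FitResult:
    params: MRHParameters
    cardinal: CardinalPoints
    fitted_values: np.ndarray
    residual_sum_of_squares: float
    converged: bool
    n_iterations: int
    seed: int
    axis_kind: str
    repeat_id: str = ""


@dataclass(frozen=True)
class RepeatSummary:
    """Per-repeat fits plus arithmetic means of parameters and deriveds."""

    per_repeat: tuple[FitResult, ...]
    mean_params: MRHParameters
    mean_cardinal: CardinalPoints


def default_bounds(curve: ResponseCurve) -> dict[str, tuple[float, float]]:
    """Physiologic box constraints for the MRH fit.

    CP is capped at the smallest driver with positive observed rate:
    below its compensation point the leaf is a net CO₂ source, so any
    positive observation places CP beneath it.  N's negative branch is
    excluded (no printed fit needs it); its light/CO₂ upper bounds differ
    by the driver scale.
    """
    x = curve.drivers
    y = curve.rates
    positive = x[y > 0]
    cp_hi = float(positive.min()) if positive.size else float(x.min())
    n_hi = 1.0 if curve.axis_kind == "light" else 0.01
    return {
        "e": (1e-9, 1.0),
        "m": (0.0, 0.01),
        "n": (1e-8, n_hi),
        "cp": (0.0, max(cp_hi, 1e-6)),
    }


def default_initialization(curve: ResponseCurve) -> MRHParameters:
    """Data-driven starting point.

    E and CP come from a least-squares line through the three
    lowest-driver points (slope, and its zero crossing clamped to
    [0, min driver]); M and N start at small axis-appropriate values.
    Degenerate low-driver points fall back to fixed defaults with a
    warning.
    """
    x = curve.drivers
    y = curve.rates
    order = np.argsort(x, kind="stable")
    xs, ys = x[order][:3], y[order][:3]
    n0 = 1e-3 if curve.axis_kind == "light" else 1e-6
    if len(xs) < 3 or np.ptp(xs) == 0:
        warnings.warn(
            "degenerate low-driver points; falling back to fixed initialization",
            stacklevel=2,
        )
        log.info("initialization fallback used for repeat %r", curve.repeat_id)
        return MRHParameters(e=0.01, m=1e-4, n=n0, cp=float(x.min()) / 2.0)
    design = np.vstack([xs, np.ones_like(xs)]).T
    (slope, intercept), *_ = np.linalg.lstsq(design, ys, rcond=None)
    if slope <= 0 or not np.isfinite(slope):
        warnings.warn(
            "non-positive low-driver slope; falling back to fixed initialization",
            stacklevel=2,
        )
        log.info("initialization fallback used for repeat %r", curve.repeat_id)
        return MRHParameters(e=0.01, m=1e-4, n=n0, cp=float(x.min()) / 2.0)
    cp0 = float(np.clip(-intercept / slope, 0.0, x.min()))
    return MRHParameters(e=float(slope), m=1e-4, n=n0, cp=cp0)


def _clip_interior(theta: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    # least_squares(trf) accepts on-boundary starts and nudges them inward
    return np.clip(theta, lo, hi)


def _sse(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> float:
    e, m, n, cp = theta
    pred = e * (1.0 - m * x) * (x - cp) / (1.0 + n * x)
    return float(np.sum((pred - y) ** 2))


def fit_mrh(curve: ResponseCurve, config: Optional[FitConfig] = None) -> FitResult:
    """Estimate MRH parameters for one response curve.

    Multi-start bounded least squares: the first start is
    :func:`default_initialization`, the remaining ``n_starts − 1`` are
    seeded log-scale perturbations of it.  Returns the least-SSE solution
    across all converged starts, with fitted values, R² and cardinal
    points attached.
    """
    config = config or FitConfig()
    x = curve.drivers
    y = curve.rates
    if len(curve) < 5:
        raise ValueError(f"need >= 5 points to fit, got {len(curve)}")
    if np.ptp(x) == 0:
        raise ValueError("drivers are all equal; curve is unfittable")

    bounds = dict(default_bounds(curve))
    if config.bounds:
        bounds.update({k: tuple(v) for k, v in config.bounds.items()})
    lo = np.array([bounds[k][0] for k in PARAM_NAMES])
    hi = np.array([bounds[k][1] for k in PARAM_NAMES])

    init = default_initialization(curve)
    theta0 = np.array([init.e, init.m, init.n, init.cp])
    theta0 = _clip_interior(theta0, lo, hi)
    log.info(
        "fit_mrh repeat=%r axis=%s init=%s bounds=%s",
        curve.repeat_id,
        curve.axis_kind,
        dict(zip(PARAM_NAMES, theta0)),
        bounds,
    )

    rng = np.random.default_rng(config.seed)
    starts = [theta0]
    for _ in range(config.n_starts - 1):
        pert = theta0.copy()
        pert[0] *= np.exp(rng.normal(0.0, 0.7))          # E
        pert[1] = theta0[1] * 10.0 ** rng.uniform(-1, 1)  # M
        pert[2] = theta0[2] * 10.0 ** rng.uniform(-1.5, 1.5)  # N
        pert[3] = rng.uniform(lo[3], hi[3])               # CP
        starts.append(_clip_interior(pert, lo, hi))

    def residuals(theta):
        e, m, n, cp = theta
        return e * (1.0 - m * x) * (x - cp) / (1.0 + n * x) - y

    best = None
    best_sse = np.inf
    total_nfev = 0
    failures = []
    for k, start in enumerate(starts):
        try:
            res = least_squares(
                residuals,
                start,
                bounds=(lo, hi),
                method="trf",
                ftol=config.ftol,
                xtol=config.xtol,
                gtol=1e-12,
                max_nfev=config.max_nfev,
                x_scale=np.maximum(np.abs(start), [1e-3, 1e-5, 1e-7, 1.0]),
            )
        except Exception as exc:  # pragma: no cover - scipy internal failure
            failures.append(f"start {k}: {exc}")
            continue
        total_nfev += res.nfev
        sse = 2.0 * res.cost
        log.info("fit_mrh start %d: status=%d nfev=%d sse=%.6g", k, res.status, res.nfev, sse)
        if res.status <= 0:
            failures.append(f"start {k}: status {res.status} ({res.message})")
            continue
        if sse < best_sse:
            best, best_sse = res, sse

    if best is None:
        raise FitError(
            "fit_mrh: no start converged",
            diagnostics={"failures": failures, "n_starts": len(starts)},
        )

    e, m, n, cp = best.x
    if n < 0:
        warnings.warn(f"fitted N is negative ({n}); outside the physiologic branch")
    params = MRHParameters(e=float(e), m=float(m), n=float(n), cp=float(cp))
    fitted = np.asarray(mrh_predict(params, x), dtype=float)
    cardinal = cardinal_points(params, observed=y, predicted=fitted)
    return FitResult(
        params=params,
        cardinal=cardinal,
        fitted_values=fitted,
        residual_sum_of_squares=best_sse,
        converged=True,
        n_iterations=total_nfev,
        seed=config.seed,
        axis_kind=curve.axis_kind,
        repeat_id=curve.repeat_id,
    )


def aggregate_repeats(results: Sequence[FitResult]) -> RepeatSummary:
    """Average parameters and derived quantities across repeats.

    Every mean field is the arithmetic mean of the corresponding
    per-repeat field, matching the convention of a per-column "Average"
    row (mean LSP = mean of per-repeat LSPs).
    """
    if not results:
        raise ValueError("aggregate_repeats needs at least one FitResult")
    kinds = {r.axis_kind for r in results}
    if len(kinds) > 1:
        raise ValueError(f"cannot aggregate mixed axis kinds: {sorted(kinds)}")

    def mean(getter):
        return float(np.mean([getter(r) for r in results]))

    mean_params = MRHParameters(
        e=mean(lambda r: r.params.e),
        m=mean(lambda r: r.params.m),
        n=mean(lambda r: r.params.n),
        cp=mean(lambda r: r.params.cp),
    )
    mean_cardinal = CardinalPoints(
        sp=mean(lambda r: r.cardinal.sp),
        rate_at_sp=mean(lambda r: r.cardinal.rate_at_sp),
        dark_respiration=mean(lambda r: r.cardinal.dark_respiration),
        r_squared=mean(lambda r: r.cardinal.r_squared),
    )
    return RepeatSummary(
        per_repeat=tuple(results),
        mean_params=mean_params,
        mean_cardinal=mean_cardinal,
    )


def brute_force_sse_oracle(
    curve: ResponseCurve, grid: Mapping[str, Sequence[float]]
) -> tuple[MRHParameters, float]:
    """Exhaustive SSE minimum over a finite parameter grid (test oracle).

    ``grid`` maps each of e/m/n/cp to a finite sequence of candidate
    values.  Independent of the optimizer by construction.
    """
    missing = set(PARAM_NAMES) - set(grid)
    if missing:
        raise ValueError(f"grid missing parameters: {sorted(missing)}")
    axes = [np.asarray(grid[k], dtype=float) for k in PARAM_NAMES]
    if any(a.size == 0 for a in axes):
        raise ValueError("empty grid axis")
    x = curve.drivers
    y = curve.rates
    best_theta, best_sse = None, np.inf
    for theta in itertools.product(*axes):
        sse = _sse(np.array(theta), x, y)
        if sse < best_sse:
            best_theta, best_sse = theta, sse
    e, m, n, cp = best_theta
    return MRHParameters(e=e, m=m, n=n, cp=cp), best_sse
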