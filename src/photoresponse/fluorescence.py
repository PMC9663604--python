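"""Chlorophyll-fluorescence computations.

Covers the PAM-side analyses: PSII electron transport rate from
effective quantum yield, the Eilers–Peeters rapid-light-curve (RLC)
model ``ETR = PAR/(a·PAR² + b·PAR + c)`` with seeded multi-start fitting,
cardinal RLC quantities (α, ETRmax, Ik), quantum-yield partitioning from
raw fluorescence traces, and the scaled dark-adapted maximal yield
``(Fm − Fo)/Fm · factor/2``.

Conventions: ETR = PAR · Y(II) · absorptance · PSII fraction with
defaults 0.84 and 0.5 (product 0.42); both constants are explicit
arguments everywhere they enter.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import least_squares

from .curve_core import DomainError, r_squared
from .fitting import DEFAULT_SEED, FitConfig, FitError

__all__ = [
    "DEFAULT_ABSORPTANCE",
    "DEFAULT_PSII_FRACTION",
    "FluorPoint",
    "FluorTrace",
    "TraceStep",
    "EPParameters",
    "RLCDerived",
    "EPFitResult",
    "etr_from_yield",
    "ep_predict",
    "fit_ep",
    "ep_cardinals",
    "partition_from_trace",
    "fvfm_scaled",
]

log = logging.getLogger(__name__)

DEFAULT_ABSORPTANCE = 0.84
DEFAULT_PSII_FRACTION = 0.5

ArrayLike = Union[float, Sequence[float], np.ndarray]


@dataclass(frozen=True)
class FluorPoint:
    """Per-light-step yield partition as reported by a PAM instrument."""

    par: float
    y_ii: float
    y_npq: float
    y_no: float
    npq: Optional[float] = None
    q_n: Optional[float] = None
    q_p: Optional[float] = None
    q_l: Optional[float] = None
    etr: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("y_ii", "y_npq", "y_no"):
            v = getattr(self, name)
            # small negative slack: closure-derived yields can undershoot 0
            # by float rounding
            if not -1e-9 <= v <= 1.0 + 1e-9:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.par < 0:
            raise ValueError(f"par must be >= 0, got {self.par}")

    @property
    def yield_closure(self) -> float:
        return self.y_ii + self.y_npq + self.y_no


@dataclass(frozen=True)
class TraceStep:
    """Raw fluorescence levels at one actinic light step."""

    par: float
    f_s: float
    fm_prime: float
    fo_prime: float


@dataclass(frozen=True)
class FluorTrace:
    """Dark-adapted Fo/Fm plus per-step raw fluorescence levels."""

    fo: float
    fm: float
    steps: tuple[TraceStep, ...]

    def __post_init__(self) -> None:
        if not (self.fm > self.fo > 0):
            raise ValueError(f"need Fm > Fo > 0, got Fm={self.fm}, Fo={self.fo}")
        object.__setattr__(self, "steps", tuple(self.steps))
        for i, s in enumerate(self.steps):
            if not (self.fm >= s.fm_prime >= s.f_s):
                raise ValueError(
                    f"step {i}: need Fm >= Fm' >= Fs, got "
                    f"Fm={self.fm}, Fm'={s.fm_prime}, Fs={s.f_s}"
                )
            if s.fo_prime <= 0:
                raise ValueError(f"step {i}: Fo' must be > 0, got {s.fo_prime}")


@dataclass(frozen=True)
class EPParameters:
    """Eilers–Peeters coefficients of ETR = PAR/(a·PAR² + b·PAR + c)."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.a + self.b + self.c):
            raise ValueError("EP parameters must be finite")
        if self.c <= 0:
            raise ValueError(f"c must be > 0, got {self.c}")


@dataclass(frozen=True)
class RLCDerived:
    """Cardinal RLC quantities; ``i_k · alpha == etr_max`` always holds."""

    alpha: float
    etr_max: float
    i_k: float
    fvfm_etr_half: float = math.nan
    saturating_fit: bool = True


@dataclass(frozen=True)
class EPFitResult:
    params: EPParameters
    r_squared: float
    fitted_values: np.ndarray
    residual_sum_of_squares: float
    converged: bool
    n_iterations: int
    seed: int


def etr_from_yield(
    par: ArrayLike,
    y_ii: ArrayLike,
    absorptance: float = DEFAULT_ABSORPTANCE,
    psii_fraction: float = DEFAULT_PSII_FRACTION,
) -> Union[float, np.ndarray]:
    """PSII electron transport rate: PAR · Y(II) · absorptance · fraction."""
    p = np.asarray(par, dtype=float)
    y = np.asarray(y_ii, dtype=float)
    if np.any(p < 0):
        raise ValueError("par must be >= 0")
    if np.any((y < 0) | (y > 1)):
        raise ValueError("y_ii must be in [0, 1]")
    out = p * y * absorptance * psii_fraction
    if np.ndim(par) == 0 and np.ndim(y_ii) == 0:
        return float(out)
    return out


def ep_predict(params: EPParameters, par: ArrayLike) -> Union[float, np.ndarray]:
    """Evaluate the Eilers–Peeters model; exactly 0 at PAR = 0."""
    p = np.asarray(par, dtype=float)
    denom = params.a * p * p + params.b * p + params.c
    bad = denom <= 0
    if np.any(bad):
        offending = np.atleast_1d(p)[np.atleast_1d(bad)][0]
        raise DomainError(
            f"non-positive denominator at PAR={offending} "
            f"(a={params.a}, b={params.b}, c={params.c})"
        )
    out = p / denom
    if np.ndim(par) == 0:
        return float(out)
    return out


def _ep_initialization(par: np.ndarray, etr: np.ndarray) -> np.ndarray:
    """c from the inverse initial slope, b from the two highest-PAR points,
    a = 0."""
    pos = par > 0
    slope = np.nan
    if pos.any():
        i = np.argmin(np.where(pos, par, np.inf))
        if etr[i] > 0:
            slope = etr[i] / par[i]
    c0 = 1.0 / slope if np.isfinite(slope) and slope > 0 else 10.0
    order = np.argsort(par)
    top = order[-2:]
    bs = []
    for j in top:
        if etr[j] > 0 and par[j] > 0:
            bs.append((par[j] / etr[j] - c0) / par[j])
    b0 = float(np.mean(bs)) if bs else 0.05
    return np.array([0.0, b0, c0])


def fit_ep(
    points: Sequence[tuple[float, float]], config: Optional[FitConfig] = None
) -> EPFitResult:
    """Least-SSE Eilers–Peeters fit of (PAR, ETR) points.

    Seeded multi-start bounded least squares, sharing :class:`FitConfig`
    (and its default seed) with the gas-exchange fitter.  ``a`` may be
    negative — real RLCs that never saturate fit with a < 0 — but the
    denominator is kept positive over the data by penalty.
    """
    config = config or FitConfig()
    pts = [(float(p), float(v)) for p, v in points]
    if len(pts) < 4:
        raise ValueError(f"need >= 4 points to fit, got {len(pts)}")
    par = np.array([p for p, _ in pts])
    etr = np.array([v for _, v in pts])
    if np.any(par < 0):
        raise ValueError("par must be >= 0")

    lo = np.array([-1e-4, -1.0, 1e-6])
    hi = np.array([1e-4, 1.0, 1e3])
    theta0 = np.clip(_ep_initialization(par, etr), lo, hi)
    log.info("fit_ep init a=%g b=%g c=%g", *theta0)

    rng = np.random.default_rng(config.seed)
    starts = [theta0]
    for _ in range(config.n_starts - 1):
        pert = theta0.copy()
        pert[0] = rng.uniform(-2e-5, 2e-5)
        pert[1] = theta0[1] * np.exp(rng.normal(0.0, 0.7))
        pert[2] = theta0[2] * np.exp(rng.normal(0.0, 0.7))
        starts.append(np.clip(pert, lo, hi))

    def residuals(theta):
        a, b, c = theta
        denom = a * par * par + b * par + c
        resid = np.where(denom > 1e-9, par / np.maximum(denom, 1e-9) - etr, 1e6)
        return resid

    best, best_sse, total_nfev, failures = None, np.inf, 0, []
    for k, start in enumerate(starts):
        res = least_squares(
            residuals,
            start,
            bounds=(lo, hi),
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=1e-12,
            max_nfev=config.max_nfev,
            x_scale=[1e-6, 0.01, 10.0],
        )
        total_nfev += res.nfev
        sse = 2.0 * res.cost
        if res.status <= 0:
            failures.append(f"start {k}: status {res.status}")
            continue
        if sse < best_sse:
            best, best_sse = res, sse

    if best is None:
        raise FitError("fit_ep: no start converged", diagnostics={"failures": failures})

    params = EPParameters(a=float(best.x[0]), b=float(best.x[1]), c=float(best.x[2]))
    fitted = np.asarray(ep_predict(params, par), dtype=float)
    return EPFitResult(
        params=params,
        r_squared=r_squared(etr, fitted),
        fitted_values=fitted,
        residual_sum_of_squares=best_sse,
        converged=True,
        n_iterations=total_nfev,
        seed=config.seed,
    )


def ep_cardinals(
    params: EPParameters,
    par_domain: tuple[float, float],
    fvfm: float = math.nan,
    etr_factor: float = 0.84,
    n_grid: int = 10001,
) -> RLCDerived:
    """Cardinal RLC quantities from Eilers–Peeters coefficients.

    For a > 0 the textbook closed forms apply: α = 1/c,
    ETRmax = 1/(b + 2√(a·c)), Ik = c/(b + 2√(a·c)).  For a ≤ 0 the curve
    has no interior maximum, so ETRmax falls back to the maximum of the
    model over ``par_domain`` (dense grid), Ik = ETRmax·c, and the result
    is flagged non-saturating with a warning.
    """
    lo, hi = float(par_domain[0]), float(par_domain[1])
    if not hi > lo:
        raise ValueError(f"empty par domain [{lo}, {hi}]")
    alpha = 1.0 / params.c
    fvfm_half = (
        fvfm * etr_factor / 2.0 if math.isfinite(fvfm) else math.nan
    )
    if params.a > 0:
        denom = params.b + 2.0 * math.sqrt(params.a * params.c)
        if denom <= 0:
            raise DomainError(
                f"ETRmax undefined: b + 2*sqrt(a*c) = {denom} is not positive"
            )
        etr_max = 1.0 / denom
        i_k = params.c / denom
        return RLCDerived(
            alpha=alpha,
            etr_max=etr_max,
            i_k=i_k,
            fvfm_etr_half=fvfm_half,
            saturating_fit=True,
        )
    warnings.warn(
        f"a = {params.a} <= 0: no interior ETR maximum; "
        "ETRmax taken as the model maximum over the PAR domain",
        stacklevel=2,
    )
    grid = np.linspace(lo, hi, n_grid)
    vals = np.asarray(ep_predict(params, grid))
    etr_max = float(vals.max())
    return RLCDerived(
        alpha=alpha,
        etr_max=etr_max,
        i_k=etr_max * params.c,
        fvfm_etr_half=fvfm_half,
        saturating_fit=False,
    )


def partition_from_trace(
    trace: FluorTrace,
    absorptance: float = DEFAULT_ABSORPTANCE,
    psii_fraction: float = DEFAULT_PSII_FRACTION,
) -> list[FluorPoint]:
    """Quantum-yield partition from raw fluorescence levels.

    Standard saturating-pulse definitions per step:
    Y(II) = (Fm′ − Fs)/Fm′, NPQ = (Fm − Fm′)/Fm′,
    qP = (Fm′ − Fs)/(Fm′ − Fo′), qN = 1 − (Fm′ − Fo′)/(Fm − Fo),
    qL = qP·Fo′/Fs, Y(NO) = 1/(NPQ + 1 + qL·(Fm/Fo − 1)) (lake model),
    Y(NPQ) = 1 − Y(II) − Y(NO), so closure is exact by construction.
    """
    out = []
    for i, s in enumerate(trace.steps):
        if s.fm_prime <= s.fo_prime:
            raise DomainError(f"step {i}: Fm' ({s.fm_prime}) <= Fo' ({s.fo_prime})")
        if s.f_s <= 0:
            raise DomainError(f"step {i}: Fs must be > 0, got {s.f_s}")
        y_ii = (s.fm_prime - s.f_s) / s.fm_prime
        npq = (trace.fm - s.fm_prime) / s.fm_prime
        q_p = (s.fm_prime - s.f_s) / (s.fm_prime - s.fo_prime)
        q_n = 1.0 - (s.fm_prime - s.fo_prime) / (trace.fm - trace.fo)
        q_l = q_p * s.fo_prime / s.f_s
        y_no = 1.0 / (npq + 1.0 + q_l * (trace.fm / trace.fo - 1.0))
        y_npq = 1.0 - y_ii - y_no
        out.append(
            FluorPoint(
                par=s.par,
                y_ii=y_ii,
                y_npq=y_npq,
                y_no=y_no,
                npq=npq,
                q_n=q_n,
                q_p=q_p,
                q_l=q_l,
                etr=etr_from_yield(s.par, y_ii, absorptance, psii_fraction),
            )
        )
    return out


def fvfm_scaled(fo: float, fm: float, etr_factor: float = 0.84) -> float:
    """Dark-adapted maximal PSII yield times half the ETR factor:
    ((Fm − Fo)/Fm) · etr_factor/2."""
    if not (fm > fo > 0):
        raise DomainError(f"need Fm > Fo > 0, got Fm={fm}, Fo={fo}")
    return (fm - fo) / fm * etr_factor / 2.0
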