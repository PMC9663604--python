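"""Modified rectangular hyperbola (MRH) response-curve model.

A single four-parameter model describes both light-response curves
(driver = in-chamber PAR, µmol m⁻² s⁻¹) and CO₂-response curves
(driver = sample-cell CO₂, µmol mol⁻¹)::

    rate = E · (1 − M·x) · (x − CP) / (1 + N·x)

where ``E`` is the apparent quantum (or carboxylation-efficiency) yield —
the initial slope near the compensation point — ``M`` shapes the
supra-optimal decline, ``N`` shapes the approach to saturation and ``CP``
is the compensation point on the driver axis (LCP for light, CCP for CO₂).

Closed forms exist for the saturation point

    SP = (√((M + N)·(1 + N·CP)/M) − 1) / N,

the model rate at SP, and dark respiration ``E·CP``.  These are pure
functions of the parameters; estimation lives in
:mod:`photoresponse.fitting`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

__all__ = [
    "DomainError",
    "NoSaturationPointError",
    "ResponsePoint",
    "ResponseCurve",
    "MRHParameters",
    "CardinalPoints",
    "mrh_predict",
    "saturation_point",
    "dark_respiration",
    "rate_at_saturation",
    "cardinal_points",
    "r_squared",
]

AXIS_KINDS = ("light", "co2")

ArrayLike = Union[float, Sequence[float], np.ndarray]


class DomainError(ValueError):
    """A quantity was requested outside the model's mathematical domain."""


class NoSaturationPointError(DomainError):
    """The closed-form saturation point does not exist for these parameters.

    Raised when M ≤ 0 (no supra-optimal decline, hence no interior
    maximum) or when the radicand of the closed form is negative.
    Distinct from a plain :class:`DomainError` so callers can tell
    "structurally absent" apart from a numeric failure.
    """


def _finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class ResponsePoint:
    """One driver→rate observation, with optional instrument covariates."""

    driver: float
    rate: float
    tleaf: Optional[float] = None
    trmmol: Optional[float] = None
    cond: Optional[float] = None
    ci: Optional[float] = None
    co2s: Optional[float] = None
    pari: Optional[float] = None

    def __post_init__(self) -> None:
        _finite("driver", self.driver)
        _finite("rate", self.rate)
        if self.driver < 0:
            raise ValueError(f"driver must be >= 0, got {self.driver}")
        for name in ("tleaf", "trmmol", "cond", "ci", "co2s", "pari"):
            v = getattr(self, name)
            if v is not None:
                _finite(name, v)


@dataclass(frozen=True)
class ResponseCurve:
    """Ordered driver→rate observations for one repeat.

    ``axis_kind`` is ``"light"`` (driver = PAR) or ``"co2"`` (driver =
    sample-cell CO₂).  At least 5 points are required for fitting; that
    constraint is enforced by the fitter, not here, so partial curves can
    still be constructed and inspected.
    """

    axis_kind: str
    points: tuple[ResponsePoint, ...]
    repeat_id: str = ""

    def __post_init__(self) -> None:
        if self.axis_kind not in AXIS_KINDS:
            raise ValueError(
                f"axis_kind must be one of {AXIS_KINDS}, got {self.axis_kind!r}"
            )
        object.__setattr__(self, "points", tuple(self.points))
        if not self.points:
            raise ValueError("ResponseCurve needs at least one point")

    @property
    def drivers(self) -> np.ndarray:
        return np.array([p.driver for p in self.points], dtype=float)

    @property
    def rates(self) -> np.ndarray:
        return np.array([p.rate for p in self.points], dtype=float)

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class MRHParameters:
    """Parameters of the modified rectangular hyperbola.

    Units: ``e`` in rate units per driver unit, ``m`` and ``n`` per driver
    unit, ``cp`` in driver units.
    """

    e: float
    m: float
    n: float
    cp: float

    def __post_init__(self) -> None:
        for name in ("e", "m", "n", "cp"):
            _finite(name, getattr(self, name))
        if self.e <= 0:
            raise ValueError(f"E must be > 0, got {self.e}")
        if self.cp < 0:
            raise ValueError(f"CP must be >= 0, got {self.cp}")


@dataclass(frozen=True)
class CardinalPoints:
    """Derived quantities of a fitted response curve.

    ``sp`` and ``rate_at_sp`` are NaN when the closed-form saturation
    point does not exist (M ≤ 0), in which case a warning was emitted at
    construction time by the caller.
    """

    sp: float
    rate_at_sp: float
    dark_respiration: float
    r_squared: float


def _check_params(params: MRHParameters) -> MRHParameters:
    if not isinstance(params, MRHParameters):
        raise TypeError(f"expected MRHParameters, got {type(params).__name__}")
    return params


def mrh_predict(params: MRHParameters, driver: ArrayLike) -> Union[float, np.ndarray]:
    """Evaluate the MRH model at ``driver`` (scalar or sequence).

    Exactly zero at ``driver == params.cp``.  Raises :class:`DomainError`
    when ``1 + N·driver`` vanishes for any requested value.
    """
    _check_params(params)
    x = np.asarray(driver, dtype=float)
    denom = 1.0 + params.n * x
    bad = np.abs(denom) < 1e-12
    if np.any(bad):
        offending = np.atleast_1d(x)[np.atleast_1d(bad)][0]
        raise DomainError(
            f"singular denominator 1 + N*driver at driver={offending} (N={params.n})"
        )
    out = params.e * (1.0 - params.m * x) * (x - params.cp) / denom
    if np.ndim(driver) == 0:
        return float(out)
    return out


def saturation_point(params: MRHParameters) -> float:
    """Closed-form driver value at which the model rate is maximal.

    SP = (√((M + N)·(1 + N·CP)/M) − 1)/N.  Requires M > 0, N ≠ 0 and a
    non-negative radicand; otherwise :class:`NoSaturationPointError`.
    """
    _check_params(params)
    if params.m <= 0:
        raise NoSaturationPointError(
            f"no finite saturation point: M must be > 0, got M={params.m}"
        )
    if params.n == 0:
        raise DomainError("saturation point is undefined for N = 0")
    radicand = (params.m + params.n) * (1.0 + params.n * params.cp) / params.m
    if radicand < 0:
        raise NoSaturationPointError(
            f"no finite saturation point: negative radicand {radicand}"
        )
    return (math.sqrt(radicand) - 1.0) / params.n


def dark_respiration(params: MRHParameters) -> float:
    """Dark respiration proxy ``E·CP`` (rate units)."""
    _check_params(params)
    return params.e * params.cp


def rate_at_saturation(params: MRHParameters) -> float:
    """Model rate at the saturation point (PLSP / PCSP)."""
    return float(mrh_predict(params, saturation_point(params)))


def cardinal_points(
    params: MRHParameters,
    observed: Optional[Sequence[float]] = None,
    predicted: Optional[Sequence[float]] = None,
) -> CardinalPoints:
    """Bundle SP, rate at SP, dark respiration and (optionally) R².

    When the saturation point is structurally absent the SP fields are NaN
    and a warning is emitted rather than failing the whole result.
    """
    try:
        sp = saturation_point(params)
        rate_sp = float(mrh_predict(params, sp))
    except NoSaturationPointError as exc:
        warnings.warn(f"saturation point unavailable: {exc}", stacklevel=2)
        sp = math.nan
        rate_sp = math.nan
    rsq = math.nan
    if observed is not None and predicted is not None:
        rsq = r_squared(observed, predicted)
    return CardinalPoints(
        sp=sp,
        rate_at_sp=rate_sp,
        dark_respiration=dark_respiration(params),
        r_squared=rsq,
    )


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 − SSE/SST about the observed mean."""
    o = np.asarray(observed, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if o.shape != p.shape:
        raise ValueError(f"length mismatch: {o.shape} vs {p.shape}")
    if o.size < 2:
        raise ValueError("need at least 2 observations for R²")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0.0:
        raise DomainError("R² undefined: observed values are all equal (SST = 0)")
    sse = float(np.sum((o - p) ** 2))
    return 1.0 - sse / sst
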