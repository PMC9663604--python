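"""Ground-truth simulators for every pipeline stage.

Generates gas-exchange response curves from known MRH parameters,
rapid-light-curve point sets (with internally consistent raw
fluorescence traces) from known Eilers–Peeters parameters, and bimodal
diurnal courses.  All noise is additive homoscedastic Gaussian and all
randomness flows through one seed, so identical configs produce
bit-identical output.

Default driver grids copy the measured designs of the packaged
fixtures: the 13-level PAR ladder of the light-response tables, the
CO₂ staircase of the CO₂-response tables and the 13-step RLC ladder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .curve_core import MRHParameters, ResponseCurve, ResponsePoint, mrh_predict
from .diurnal import DiurnalRecord, format_clock, parse_clock
from .fluorescence import EPParameters, FluorTrace, TraceStep, ep_predict

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "DiurnalTemplate",
    "RLCSample",
    "TABLE2_PAR_GRID",
    "TABLE4_CO2_GRID",
    "RLC_PAR_LADDER",
    "DIURNAL_TIMES",
    "gen_response_curve",
    "gen_rlc",
    "gen_diurnal",
]

#: PAR levels of the light-response design (repeat 1 of the packaged table).
TABLE2_PAR_GRID = (
    2000.5, 1800.1, 1498.9, 1399.9, 1001.2, 801.5, 600.8,
    399.6, 199.7, 150.8, 100.6, 49.6, 20.5,
)

#: Chamber-CO₂ levels of the CO₂-response design (repeat 1).
TABLE4_CO2_GRID = (
    2563.5, 1899.2, 1695.6, 1398.7, 1099.0, 999.8, 800.2,
    600.3, 400.5, 311.7, 139.4, 91.2,
)

#: Actinic ladder of the rapid light curves (dark step included).
RLC_PAR_LADDER = (0, 6, 31, 101, 198, 363, 619, 981, 1386, 2015, 2970, 3588, 4292)

#: Clock times of the diurnal design.
DIURNAL_TIMES = (
    "7:12", "8:01", "9:01", "10:13", "11:04", "12:00", "13:15",
    "14:04", "15:00", "16:00", "17:00", "18:00", "19:00",
)


class ConfigError(ValueError):
    """A simulation config is internally inconsistent or infeasible."""


@dataclass(frozen=True)
class DiurnalTemplate:
    """Bimodal diurnal shape: two Gaussian bumps over a midday trough."""

    morning_peak: float = 0.20
    evening_peak: float = 0.16
    midday_min: float = 0.01
    morning_peak_time: str = "9:00"
    evening_peak_time: str = "17:00"
    width_hours: float = 1.0

    def value(self, minutes: float) -> float:
        w = 60.0 * self.width_hours
        tm = parse_clock(self.morning_peak_time)
        te = parse_clock(self.evening_peak_time)
        bump_m = (self.morning_peak - self.midday_min) * math.exp(
            -((minutes - tm) ** 2) / (2 * w * w)
        )
        bump_e = (self.evening_peak - self.midday_min) * math.exp(
            -((minutes - te) ** 2) / (2 * w * w)
        )
        return self.midday_min + bump_m + bump_e


@dataclass(frozen=True)
class SimulationConfig:
    """Truth parameters plus design for one simulation.

    ``truth`` is :class:`MRHParameters` (response curves),
    :class:`EPParameters` (RLCs) or :class:`DiurnalTemplate` (diurnal
    courses); ``grid`` is the driver/PAR/time design.  The optional
    ladders override the RLC trace construction targets.
    """

    truth: object
    grid: Sequence = ()
    noise_sd: float = 0.0
    seed: int = 0
    n_replicates: int = 1
    axis_kind: str = "light"
    dark_fvfm: float = 0.573
    etr_factor: float = 0.84
    psii_fraction: float = 0.5
    y_ii_ladder: Optional[Sequence[float]] = None
    npq_ladder: Optional[Sequence[float]] = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be >= 1")
        if len(tuple(self.grid)) == 0:
            raise ConfigError("grid must be nonempty")
        if not 0 < self.dark_fvfm < 1:
            raise ConfigError(f"dark_fvfm must be in (0, 1), got {self.dark_fvfm}")


@dataclass(frozen=True)
class RLCSample:
    """One simulated RLC: (PAR, ETR) points plus the raw trace behind them."""

    points: tuple[tuple[float, float], ...]
    trace: FluorTrace


def gen_response_curve(config: SimulationConfig) -> list[ResponseCurve]:
    """Simulate ``n_replicates`` gas-exchange response curves.

    rate = model(truth, driver) + N(0, noise_sd), one rng stream for the
    whole batch.  Covariates are filled with plausible constants so the
    CSV round trip through the readers is complete.
    """
    if not isinstance(config.truth, MRHParameters):
        raise ConfigError("gen_response_curve needs MRHParameters truth")
    grid = np.asarray(tuple(config.grid), dtype=float)
    rng = np.random.default_rng(config.seed)
    covariates = (
        dict(tleaf=28.1, co2s=400.0) if config.axis_kind == "light"
        else dict(tleaf=28.1, pari=1000.0)
    )
    curves = []
    for rep in range(1, config.n_replicates + 1):
        clean = np.asarray(mrh_predict(config.truth, grid), dtype=float)
        noisy = clean + rng.normal(0.0, config.noise_sd, size=grid.shape) \
            if config.noise_sd > 0 else clean
        points = [
            ResponsePoint(
                driver=float(x), rate=float(y), trmmol=0.5, cond=0.03, ci=280.0,
                **covariates,
            )
            for x, y in zip(grid, noisy)
        ]
        curves.append(
            ResponseCurve(
                axis_kind=config.axis_kind, points=points, repeat_id=str(rep)
            )
        )
    return curves


def _build_trace(
    par: np.ndarray,
    y_ii: np.ndarray,
    npq: np.ndarray,
    dark_fvfm: float,
) -> FluorTrace:
    """Construct raw fluorescence levels that invert to the given ladders.

    Fm is normalised to 1; Fo follows from the dark Fv/Fm; per step
    Fm′ = Fm/(1 + NPQ), Fs = Fm′·(1 − Y(II)) and Fo′ uses the
    Oxborough–Baker estimate Fo/(Fv/Fm + Fo/Fm′).
    """
    fm = 1.0
    fo = fm * (1.0 - dark_fvfm)
    fvfm = 1.0 - fo / fm
    steps = []
    for p, y, q in zip(par, y_ii, npq):
        fm_prime = fm / (1.0 + q)
        f_s = fm_prime * (1.0 - y)
        fo_prime = fo / (fvfm + fo / fm_prime)
        if f_s <= 0:
            raise ConfigError(f"infeasible ladder: Fs <= 0 at PAR={p} (Y(II)={y})")
        steps.append(TraceStep(par=float(p), f_s=f_s, fm_prime=fm_prime,
                               fo_prime=fo_prime))
    return FluorTrace(fo=fo, fm=fm, steps=steps)


def gen_rlc(config: SimulationConfig) -> list[RLCSample]:
    """Simulate rapid light curves with matching fluorescence traces.

    ETR = EP(truth, PAR) + N(0, noise_sd); the trace is constructed so
    that partitioning it reproduces a Y(II) ladder consistent with those
    ETRs (Y(II) = ETR/(PAR·absorptance·fraction), dark step from
    ``dark_fvfm``).  Ladder values outside [0, 1] raise
    :class:`ConfigError`.
    """
    if not isinstance(config.truth, EPParameters):
        raise ConfigError("gen_rlc needs EPParameters truth")
    par = np.asarray(tuple(config.grid), dtype=float)
    factor = config.etr_factor * config.psii_fraction
    rng = np.random.default_rng(config.seed)
    samples = []
    for _ in range(config.n_replicates):
        etr = np.asarray(ep_predict(config.truth, par), dtype=float)
        if config.noise_sd > 0:
            etr = etr + rng.normal(0.0, config.noise_sd, size=par.shape)

        if config.y_ii_ladder is not None:
            y_ii = np.asarray(tuple(config.y_ii_ladder), dtype=float)
            if y_ii.shape != par.shape:
                raise ConfigError("y_ii_ladder length must match grid")
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                y_ii = np.where(par > 0, etr / (par * factor), config.dark_fvfm)
        if np.any((y_ii < 0) | (y_ii > 1)):
            bad = y_ii[(y_ii < 0) | (y_ii > 1)][0]
            raise ConfigError(f"infeasible Y(II) target {bad}: outside [0, 1]")

        if config.npq_ladder is not None:
            npq = np.asarray(tuple(config.npq_ladder), dtype=float)
            if npq.shape != par.shape:
                raise ConfigError("npq_ladder length must match grid")
        else:
            npq = 2.1 * (1.0 - np.exp(-par / 120.0))
        if np.any(npq < 0):
            raise ConfigError("NPQ ladder must be non-negative")

        trace = _build_trace(par, y_ii, npq, config.dark_fvfm)
        samples.append(
            RLCSample(
                points=tuple((float(p), float(v)) for p, v in zip(par, etr)),
                trace=trace,
            )
        )
    return samples


def gen_diurnal(config: SimulationConfig) -> list[list[DiurnalRecord]]:
    """Simulate diurnal courses from a bimodal template, one list per repeat."""
    if not isinstance(config.truth, DiurnalTemplate):
        raise ConfigError("gen_diurnal needs DiurnalTemplate truth")
    times = tuple(str(t) for t in config.grid)
    minutes = np.array([parse_clock(t) for t in times], dtype=float)
    rng = np.random.default_rng(config.seed)
    out = []
    for rep in range(1, config.n_replicates + 1):
        clean = np.array([config.truth.value(m) for m in minutes])
        noisy = clean + rng.normal(0.0, config.noise_sd, size=clean.shape) \
            if config.noise_sd > 0 else clean
        records = [
            DiurnalRecord(
                clock_time=t,
                photo=float(v),
                pari=1200.0,
                tleaf=33.0,
                co2s=420.0,
                trmmol=0.1,
                cond=0.001,
                ci=250.0,
                repeat_id=str(rep),
            )
            for t, v in zip(times, noisy)
        ]
        out.append(records)
    return out
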