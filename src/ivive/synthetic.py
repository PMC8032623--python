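"""Synthetic in vitro datasets with the structure the extrapolation assumes.

``generate_biokinetics`` emulates the repeated-exposure flask experiment: a
linear three-pool exchange system (exposure medium <-> cells, medium <->
plastic device) with a small first-order metabolic loss in the cells, dosed
every other day for 14 days, sampled at a handful of time points over 24 h on
day 0 and day 14, with multiplicative log-normal measurement noise.  At each
re-dosing the medium is by default fully replaced with fresh dosing solution
(drug in the removed medium is tracked in a discard pool so that total drug
is conserved); cumulative metabolite formation is tracked as a loss pool.

``generate_chat_response`` draws group-level ChAT-activity summary data
(mean, SD, n per dose group) around a known decreasing truth curve, so that
benchmark-dose recovery can be checked against an analytically known truth.

Default rate constants are calibrated so that day-14 cell-lysate exposure
falls near the 1-2 ug*h/mL range that repeated-exposure brain-cell studies
report, with pronounced plastic adsorption; this is a documented calibration
of the emulation, not ground truth (docs/methods.md).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

from .biokinetics import (
    CompartmentSeries,
    InVitroBiokineticDataset,
    micromolar_to_ugml,
)
from .bmd import DoseResponseData

__all__ = [
    "InVitroSystemParams",
    "ChatTruthParams",
    "simulate_pools",
    "generate_biokinetics",
    "generate_study",
    "generate_chat_response",
    "chat_truth_bmd",
]

#: Default sampling times within a 24 h observation day (5 points; the first
#: sample is drawn immediately after dosing so the 0-24 h metric window is
#: spanned by observations).
DEFAULT_SAMPLING_TIMES = (0.0, 2.0, 6.0, 12.0, 24.0)

AMIODARONE_MW = 645.31  # g/mol


@dataclass(frozen=True)
class InVitroSystemParams:
    """Flask system: volumes, exchange rates, dosing schedule, noise."""

    medium_volume_ml: float = 2.0
    lysate_volume_ml: float = 1.0
    k_medium_to_cells: float = 2.4556e-4  # 1/h, calibrated (see module docstring)
    k_cells_to_medium: float = 2.0e-3  # 1/h, slow efflux -> accumulation
    k_medium_to_plastic: float = 0.05  # 1/h, pronounced plastic adsorption
    k_plastic_to_medium: float = 1.0e-3  # 1/h
    k_metabolism: float = 1.4e-4  # 1/h, small metabolic loss in cells
    level_um: float = 1.25
    molecular_weight: float = AMIODARONE_MW
    n_doses: int = 8  # every other day, days 0, 2, ..., 14
    dose_interval_h: float = 48.0
    sampling_times: tuple[float, ...] = DEFAULT_SAMPLING_TIMES
    observation_days: tuple[int, ...] = (0, 14)
    measurement_cv: float = 0.05
    renewal: Literal["replace", "add"] = "replace"
    seed: int = 0

    def __post_init__(self) -> None:
        rates = (
            self.k_medium_to_cells,
            self.k_cells_to_medium,
            self.k_medium_to_plastic,
            self.k_plastic_to_medium,
            self.k_metabolism,
        )
        if any(r < 0 for r in rates):
            raise ValueError("rate constants must be >= 0")
        if self.medium_volume_ml <= 0 or self.lysate_volume_ml <= 0:
            raise ValueError("volumes must be > 0")
        if self.measurement_cv < 0:
            raise ValueError("measurement CV must be >= 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")
        if any(not 0 <= t <= 24 for t in self.sampling_times):
            raise ValueError("sampling times must lie in [0, 24] h")
        if self.renewal not in ("replace", "add"):
            raise ValueError("renewal must be 'replace' or 'add'")

    @property
    def dose_amount_ug(self) -> float:
        """Drug mass added with each medium change (ug per flask)."""
        return (
            micromolar_to_ugml(self.level_um, self.molecular_weight)
            * self.medium_volume_ml
        )


def _pool_matrix(p: InVitroSystemParams) -> np.ndarray:
    """States: [medium, cells, plastic, metabolite] amounts in ug."""
    kmc, kcm = p.k_medium_to_cells, p.k_cells_to_medium
    kmp, kpm = p.k_medium_to_plastic, p.k_plastic_to_medium
    kmet = p.k_metabolism
    return np.array(
        [
            [-(kmc + kmp), kcm, kpm, 0.0],
            [kmc, -(kcm + kmet), 0.0, 0.0],
            [kmp, 0.0, -kpm, 0.0],
            [0.0, kmet, 0.0, 0.0],
        ]
    )


def simulate_pools(p: InVitroSystemParams, eval_times: Sequence[float]) -> np.ndarray:
    """Noise-free amounts (ug) at ``eval_times`` (absolute hours, sorted).

    Returns shape (n_times, 5): medium, cells, plastic, cumulative
    metabolite, cumulative discard at medium renewal.  The five pools sum to
    the cumulatively dosed amount at all times (exact linear-system
    propagation; doses apply before sampling when times coincide).
    """
    M = _pool_matrix(p)
    eval_times = np.asarray(sorted(eval_times), dtype=float)
    dose_times = [k * p.dose_interval_h for k in range(p.n_doses)]
    events = np.unique(np.concatenate([eval_times, np.asarray(dose_times)]))
    events = events[events >= 0]

    cache: dict[float, np.ndarray] = {}

    def prop(dt: float) -> np.ndarray:
        key = round(dt, 12)
        if key not in cache:
            cache[key] = expm(M * dt)
        return cache[key]

    A = np.zeros(4)
    discarded = 0.0
    out = np.zeros((eval_times.size, 5))
    oi = 0
    t_prev = 0.0
    for t in events:
        dt = t - t_prev
        if dt > 0:
            A = prop(dt) @ A
        for td in dose_times:
            if abs(td - t) < 1e-9:
                if p.renewal == "replace":
                    discarded += A[0]
                    A[0] = p.dose_amount_ug
                else:
                    A[0] += p.dose_amount_ug
        while oi < eval_times.size and abs(eval_times[oi] - t) < 1e-9:
            out[oi, :4] = A
            out[oi, 4] = discarded
            oi += 1
        t_prev = t
    return out


def generate_biokinetics(
    p: InVitroSystemParams, include_metabolite: bool = False
) -> list[InVitroBiokineticDataset]:
    """One dataset per observation day for the configured exposure level.

    Medium is reported as a concentration (ug/mL); cells and plastic as
    per-flask amounts (ug).  Multiplicative log-normal noise with the
    configured CV is applied to every measurement (mean-preserving), seeded.
    """
    rng = np.random.default_rng(p.seed)
    sigma = math.sqrt(math.log(1.0 + p.measurement_cv**2))
    out = []
    for day in p.observation_days:
        abs_times = np.array([day * 24.0 + t for t in p.sampling_times])
        pools = simulate_pools(p, abs_times)

        def noisy(values: np.ndarray) -> np.ndarray:
            if sigma == 0:
                return values
            z = rng.standard_normal(values.shape)
            return values * np.exp(sigma * z - 0.5 * sigma**2)

        times = np.asarray(p.sampling_times, dtype=float)
        series = [
            CompartmentSeries(
                compartment="medium",
                time=times,
                value=noisy(pools[:, 0] / p.medium_volume_ml),
                value_kind="concentration",
            ),
            CompartmentSeries(
                compartment="cells",
                time=times,
                value=noisy(pools[:, 1]),
                value_kind="amount_per_flask",
            ),
            CompartmentSeries(
                compartment="plastic",
                time=times,
                value=noisy(pools[:, 2]),
                value_kind="amount_per_flask",
            ),
        ]
        if include_metabolite:
            series.append(
                CompartmentSeries(
                    compartment="metabolite",
                    time=times,
                    value=noisy(pools[:, 3]),
                    value_kind="amount_per_flask",
                )
            )
        out.append(
            InVitroBiokineticDataset(
                nominal_concentration_um=p.level_um,
                day=int(day),
                series=tuple(series),
                medium_volume_ml=p.medium_volume_ml,
                lysate_volume_ml=p.lysate_volume_ml,
            )
        )
    return out


def generate_study(
    levels: Sequence[float] = (1.25, 2.5),
    base: InVitroSystemParams = InVitroSystemParams(),
    seed: int = 0,
) -> list[InVitroBiokineticDataset]:
    """Datasets for several exposure levels (seed offset per level)."""
    out = []
    for i, level in enumerate(levels):
        p = replace(base, level_um=level, seed=seed + 1000 * i)
        out.extend(generate_biokinetics(p))
    return out


# ---------------------------------------------------------------------------
# ChAT dose-response generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChatTruthParams:
    """A known decreasing truth curve for ChAT activity (% of control).

    Default family is the 4-parameter exponential
    f(x) = a (c + (1 - c) exp(-b x^d)) with control response a = 100%.
    """

    a: float = 100.0
    b: float = 0.04
    c: float = 0.2
    d: float = 1.2
    sd_percent: float = 5.0  # per-group SD in % of control
    n_per_group: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b < 0 or not 0 <= self.c <= 1 or self.d <= 0:
            raise ValueError("invalid truth-curve parameters")
        if self.sd_percent < 0:
            raise ValueError("sd_percent must be >= 0")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")

    def curve(self, doses: np.ndarray) -> np.ndarray:
        x = np.asarray(doses, dtype=float)
        return self.a * (self.c + (1.0 - self.c) * np.exp(-self.b * x**self.d))


def chat_truth_bmd(truth: ChatTruthParams, bmr_magnitude: float = 1.0) -> float:
    """Closed-form benchmark dose of the truth curve for an SD-based BMR.

    Solves a - f(x) = bmr_magnitude * sd_percent:
    x = (-ln(1 - BMR / (a (1 - c))) / b)^(1/d).
    """
    delta = bmr_magnitude * truth.sd_percent
    drop = delta / (truth.a * (1.0 - truth.c))
    if drop >= 1:
        raise ValueError("BMR exceeds the truth curve's maximum decline")
    return float((-math.log(1.0 - drop) / truth.b) ** (1.0 / truth.d))


def generate_chat_response(
    doses: Sequence[float], truth: ChatTruthParams
) -> DoseResponseData:
    """Summary dose-response data around the truth curve, seeded.

    Group means are drawn normal around the truth with SE = SD/sqrt(n);
    group SDs are drawn from the matching scaled chi-square distribution.
    With ``sd_percent == 0`` the means lie exactly on the truth curve.
    """
    doses = np.asarray(doses, dtype=float)
    if doses.size < 3 or not np.any(doses == 0):
        raise ValueError("need >= 3 dose groups including a control at dose 0")
    rng = np.random.default_rng(truth.seed)
    f = truth.curve(doses)
    n = truth.n_per_group
    if truth.sd_percent == 0:
        means = f
        sds = np.full(doses.size, 1e-6)
    else:
        means = rng.normal(f, truth.sd_percent / math.sqrt(n))
        sds = truth.sd_percent * np.sqrt(
            rng.chisquare(n - 1, doses.size) / (n - 1)
        )
    return DoseResponseData(
        doses=doses,
        means=means,
        sds=sds,
        ns=np.full(doses.size, n, dtype=int),
        endpoint="ChAT activity",
    )
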