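"""Reverse dosimetry: find the i.v. dose whose simulated brain metric matches
a measured in vitro metric.

The dose is restricted to a grid of 0.01 mg steps and the grid dose with the
smallest |predicted - measured| difference is selected (ties broken toward
the smaller dose).  Because the disposition model is linear in dose, the
default search predicts the metric at one reference dose, scales
analytically to a candidate, and verifies the candidate and its two grid
neighbours by full simulation; a pure grid scan that simulates every
candidate dose is available as an independent oracle mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .params import DosingRegimen, PBPKParameters
from .pbpk import KineticMetric, simulate, tissue_metric

__all__ = [
    "ReverseDosimetryConfig",
    "DoseEstimate",
    "BoundaryWarning",
    "find_dose",
    "translate_levels",
]


class BoundaryWarning(UserWarning):
    """The optimum dose lies on a scan boundary."""


@dataclass(frozen=True)
class ReverseDosimetryConfig:
    """Search settings and the in vivo regimen template.

    The default regimen template is 14 daily i.v. bolus administrations with
    the day-14 24 h window (hours 312-336), matching the repeated-exposure
    design whose last-day exposure the in vitro metric summarizes.
    """

    dose_step: float = 0.01  # mg
    dose_min: float = 0.01  # mg
    dose_max: float = 2000.0  # mg
    metric: Literal["AUC", "Cmax"] = "AUC"
    compartment: str = "brain:tissue"
    window: tuple[float, float] = (312.0, 336.0)
    interval: float = 24.0  # h
    n_doses: int = 14
    infusion_duration: float = 0.0  # h; 0 = bolus
    grid_step: float = 0.05  # h, simulation output grid
    pure_scan: bool = False

    def __post_init__(self) -> None:
        if self.dose_step <= 0:
            raise ValueError("dose_step must be > 0")
        if not self.dose_min < self.dose_max:
            raise ValueError("dose_min must be < dose_max")
        if self.metric not in ("AUC", "Cmax"):
            raise ValueError(f"unknown metric {self.metric!r}")

    def regimen(self, dose: float) -> DosingRegimen:
        return DosingRegimen(
            dose=dose,
            infusion_duration=self.infusion_duration,
            interval=self.interval,
            n_doses=self.n_doses,
        )

    @property
    def duration(self) -> float:
        return max(self.window[1], self.regimen(0.0).span)


@dataclass(frozen=True)
class DoseEstimate:
    """A selected grid dose and the metric it achieves."""

    dose_mg: float
    dose_mg_per_kg: float
    achieved_metric: KineticMetric
    target_metric: KineticMetric
    residual: float
    at_boundary: bool = False
    level: float | None = None  # the in vitro exposure level this translates

    def __post_init__(self) -> None:
        if self.residual < 0:
            raise ValueError("residual must be >= 0")


def _predict(params: PBPKParameters, cfg: ReverseDosimetryConfig, dose: float) -> KineticMetric:
    res = simulate(params, cfg.regimen(dose), cfg.duration, grid_step=cfg.grid_step)
    return tissue_metric(res, cfg.compartment, cfg.metric, cfg.window)


def _snap(dose: float, cfg: ReverseDosimetryConfig) -> float:
    k = round(dose / cfg.dose_step)
    return float(np.clip(k * cfg.dose_step, cfg.dose_min, cfg.dose_max))


def find_dose(
    params: PBPKParameters,
    cfg: ReverseDosimetryConfig,
    target: KineticMetric,
) -> DoseEstimate:
    """Grid dose minimizing |simulated metric - target| (ties -> smaller dose).

    Default mode exploits dose linearity: simulate a reference dose, scale to
    a candidate analytically, then verify the candidate and its grid
    neighbours by simulation.  ``cfg.pure_scan`` simulates every grid dose in
    [dose_min, dose_max] instead (oracle mode; keep the range narrow).
    """
    if target.kind != cfg.metric:
        raise ValueError(
            f"target metric kind {target.kind!r} inconsistent with config {cfg.metric!r}"
        )
    if not target.value > 0:
        raise ValueError("target metric value must be > 0")

    if cfg.pure_scan:
        n = int(round((cfg.dose_max - cfg.dose_min) / cfg.dose_step)) + 1
        candidates = cfg.dose_min + cfg.dose_step * np.arange(n)
    else:
        ref_dose = _snap(0.5 * (cfg.dose_min + cfg.dose_max), cfg)
        ref = _predict(params, cfg, ref_dose)
        if ref.value <= 0:
            raise RuntimeError("reference simulation produced a non-positive metric")
        slope = ref.value / ref_dose  # metric per mg, exact for a linear system
        center = _snap(target.value / slope, cfg)
        candidates = np.unique(
            [
                float(np.clip(center + k * cfg.dose_step, cfg.dose_min, cfg.dose_max))
                for k in (-1, 0, 1)
            ]
        )

    best: tuple[float, float, KineticMetric] | None = None
    for dose in candidates:
        m = _predict(params, cfg, float(dose))
        resid = abs(m.value - target.value)
        if best is None or resid < best[0] - 1e-15:
            best = (resid, float(dose), m)
    assert best is not None
    resid, dose, achieved = best

    eps = 0.5 * cfg.dose_step
    at_boundary = dose <= cfg.dose_min + eps or dose >= cfg.dose_max - eps
    if at_boundary:
        warnings.warn(
            f"selected dose {dose:g} mg lies on the scan boundary "
            f"[{cfg.dose_min:g}, {cfg.dose_max:g}] mg",
            BoundaryWarning,
            stacklevel=2,
        )
    return DoseEstimate(
        dose_mg=dose,
        dose_mg_per_kg=dose / params.body_weight,
        achieved_metric=achieved,
        target_metric=target,
        residual=resid,
        at_boundary=at_boundary,
    )


def translate_levels(
    levels: Sequence[tuple[float, KineticMetric]],
    params: PBPKParameters,
    cfg: ReverseDosimetryConfig,
) -> list[DoseEstimate]:
    """Translate in vitro exposure levels into in vivo doses, order preserved."""
    if len(levels) == 0:
        raise ValueError("at least one level is required")
    out = []
    for level, target in levels:
        est = find_dose(params, cfg, target)
        out.append(replace(est, level=level))
    return out
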