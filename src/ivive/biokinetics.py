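"""In vitro biokinetic datasets and the kinetic metrics derived from them.

The in vitro system is a cell-culture flask with three measured compartments
(exposure medium, cells, plastic device) sampled at a handful of time points
over 24 h on the first (day 0) and last (day 14) day of a repeated
every-other-day exposure.  Measured amounts per flask are converted to
concentrations in ug/mL; the day-14 cell-lysate AUC(0-24) (or the observed
Cmax) is the target metric handed to reverse dosimetry.

Datasets travel as tidy CSV (columns: level_uM, day, compartment, time_h,
value, value_kind, unit) plus a YAML sidecar holding the medium and lysate
volumes; units are checked strictly on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
import yaml

from .pbpk import ConcentrationTimeProfile, KineticMetric

__all__ = [
    "CompartmentSeries",
    "InVitroBiokineticDataset",
    "per_flask_to_concentration",
    "concentration_to_per_flask",
    "micromolar_to_ugml",
    "ugml_to_micromolar",
    "auc_trapezoid",
    "observed_cmax",
    "read_biokinetics_csv",
    "write_biokinetics_csv",
]

COMPARTMENTS = ("medium", "cells", "plastic")
_VALUE_KINDS = ("amount_per_flask", "concentration")
_UNITS = {"amount_per_flask": "ug", "concentration": "ug/mL"}


def per_flask_to_concentration(amount: float, volume: float) -> float:
    """Convert an amount per flask (ug) into a concentration (ug/mL)."""
    if volume <= 0:
        raise ValueError("volume must be > 0 mL")
    return amount / volume


def concentration_to_per_flask(concentration: float, volume: float) -> float:
    """Inverse of :func:`per_flask_to_concentration`."""
    if volume <= 0:
        raise ValueError("volume must be > 0 mL")
    return concentration * volume


def micromolar_to_ugml(conc_um: float, molecular_weight: float) -> float:
    """Convert a molar concentration (uM) to ug/mL for a given molar mass."""
    if conc_um < 0:
        raise ValueError("concentration must be >= 0")
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return conc_um * molecular_weight / 1000.0


def ugml_to_micromolar(conc_ugml: float, molecular_weight: float) -> float:
    """Inverse of :func:`micromolar_to_ugml`."""
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    return conc_ugml * 1000.0 / molecular_weight


@dataclass(frozen=True)
class CompartmentSeries:
    """Measurements for one compartment: times (h) and values.

    ``value_kind`` says whether values are amounts per flask (ug) or
    concentrations (ug/mL).  Replicate measurements at the same time are
    allowed; metric computation averages them first.
    """

    compartment: str
    time: np.ndarray
    value: np.ndarray
    value_kind: Literal["amount_per_flask", "concentration"]

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        v = np.asarray(self.value, dtype=float)
        if self.compartment not in COMPARTMENTS + ("metabolite",):
            raise ValueError(f"unknown compartment {self.compartment!r}")
        if self.value_kind not in _VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("time and value must be 1-D of equal length")
        if np.any(v < 0):
            raise ValueError("values must be >= 0")
        if np.any(np.diff(np.unique(t)) <= 0):  # pragma: no cover - unique sorts
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "value", v)

    def mean_profile(self, volume_ml: float | None = None) -> ConcentrationTimeProfile:
        """Replicate-averaged concentration profile (ug/mL).

        ``volume_ml`` is required when the stored values are per-flask
        amounts (the lysate volume is never defaulted).
        """
        times = np.unique(self.time)
        means = np.array([self.value[self.time == t].mean() for t in times])
        if self.value_kind == "amount_per_flask":
            if volume_ml is None:
                raise ValueError(
                    f"{self.compartment}: converting per-flask amounts requires a volume"
                )
            means = means / volume_ml if volume_ml > 0 else _raise_volume()
        return ConcentrationTimeProfile(
            name=self.compartment, time=times, concentration=means
        )


def _raise_volume():
    raise ValueError("volume must be > 0 mL")


@dataclass(frozen=True)
class InVitroBiokineticDataset:
    """One exposure level x observation day of the in vitro experiment."""

    nominal_concentration_um: float
    day: int
    series: tuple[CompartmentSeries, ...]
    medium_volume_ml: float
    lysate_volume_ml: float

    def __post_init__(self) -> None:
        if self.day not in (0, 14):
            raise ValueError("day must be 0 or 14")
        if self.nominal_concentration_um < 0:
            raise ValueError("nominal concentration must be >= 0")
        if self.medium_volume_ml <= 0 or self.lysate_volume_ml <= 0:
            raise ValueError("volumes must be > 0 mL")
        for s in self.series:
            if s.compartment in COMPARTMENTS and np.unique(s.time).size < 2:
                raise ValueError(
                    f"{s.compartment}: need >= 2 distinct time points in [0, 24] h"
                )

    def compartment(self, name: str) -> CompartmentSeries:
        for s in self.series:
            if s.compartment == name:
                return s
        raise KeyError(name)

    def _volume_for(self, name: str) -> float | None:
        return {"medium": self.medium_volume_ml, "cells": self.lysate_volume_ml}.get(name)

    def cell_metric(
        self, kind: Literal["AUC", "Cmax"], window: tuple[float, float] = (0.0, 24.0)
    ) -> KineticMetric:
        """Day-level cell-lysate metric: AUC of the replicate-mean profile, or Cmax."""
        prof = self.compartment("cells").mean_profile(self.lysate_volume_ml)
        if kind == "AUC":
            value = auc_trapezoid(prof, *window)
        else:
            value = observed_cmax(prof)
        return KineticMetric(
            kind=kind, value=value, window=window,
            source="measured_in_vitro", compartment="cells",
        )


def auc_trapezoid(profile: ConcentrationTimeProfile, t0: float, t1: float) -> float:
    """Linear-trapezoid AUC of a sparse profile over [t0, t1] (ug*h/mL).

    Window endpoints may be linearly interpolated from bracketing points, but
    never extrapolated beyond the first/last observation.
    """
    if not t1 > t0:
        raise ValueError("t1 must exceed t0")
    t, c = profile.time, profile.concentration
    if t.size < 2:
        raise ValueError("AUC needs at least two points")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(
            f"window [{t0}, {t1}] not covered by observations [{t[0]}, {t[-1]}]"
        )
    inner = (t > t0) & (t < t1)
    tw = np.concatenate([[t0], t[inner], [t1]])
    cw = np.concatenate([[np.interp(t0, t, c)], c[inner], [np.interp(t1, t, c)]])
    return float(np.trapezoid(cw, tw))


def observed_cmax(profile: ConcentrationTimeProfile) -> float:
    """Maximum measured concentration of a profile (ug/mL)."""
    if profile.time.size < 1:
        raise ValueError("empty profile")
    return float(np.max(profile.concentration))


# ---------------------------------------------------------------------------
# tidy CSV + YAML sidecar I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["level_uM", "day", "compartment", "time_h", "value", "value_kind", "unit"]


def write_biokinetics_csv(
    datasets: Iterable[InVitroBiokineticDataset], csv_path: str | Path,
    sidecar_path: str | Path | None = None,
) -> None:
    """Write datasets as tidy CSV plus a YAML sidecar with the volumes."""
    datasets = list(datasets)
    rows = []
    for ds in datasets:
        for s in ds.series:
            for t, v in zip(s.time, s.value):
                rows.append(
                    {
                        "level_uM": ds.nominal_concentration_um,
                        "day": ds.day,
                        "compartment": s.compartment,
                        "time_h": t,
                        "value": v,
                        "value_kind": s.value_kind,
                        "unit": _UNITS[s.value_kind],
                    }
                )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(csv_path, index=False)
    sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".yaml")
    vols = {
        "medium_volume_mL": float(datasets[0].medium_volume_ml),
        "lysate_volume_mL": float(datasets[0].lysate_volume_ml),
    }
    sidecar.write_text(yaml.safe_dump(vols, sort_keys=True))


def read_biokinetics_csv(
    csv_path: str | Path, sidecar_path: str | Path | None = None
) -> list[InVitroBiokineticDataset]:
    """Read tidy-CSV datasets; strict column, unit and kind checking."""
    df = pd.read_csv(csv_path)
    if list(df.columns) != _CSV_COLUMNS:
        raise ValueError(f"expected columns {_CSV_COLUMNS}, got {list(df.columns)}")
    bad_kind = set(df["value_kind"]) - set(_VALUE_KINDS)
    if bad_kind:
        raise ValueError(f"unknown value_kind(s) {sorted(bad_kind)}")
    mismatch = df[df.apply(lambda r: _UNITS[r["value_kind"]] != r["unit"], axis=1)]
    if len(mismatch):
        raise ValueError("unit column inconsistent with value_kind")
    sidecar = Path(sidecar_path) if sidecar_path else Path(csv_path).with_suffix(".yaml")
    vols = yaml.safe_load(sidecar.read_text())
    extra = set(vols) - {"medium_volume_mL", "lysate_volume_mL"}
    if extra:
        raise ValueError(f"unknown sidecar key(s) {sorted(extra)}")
    missing = {"medium_volume_mL", "lysate_volume_mL"} - set(vols)
    if missing:
        raise ValueError(f"sidecar missing {sorted(missing)}")

    out = []
    for (level, day), grp in df.groupby(["level_uM", "day"], sort=True):
        series = []
        for (comp, kind), g in grp.groupby(["compartment", "value_kind"], sort=True):
            g = g.sort_values("time_h")
            series.append(
                CompartmentSeries(
                    compartment=comp,
                    time=g["time_h"].to_numpy(),
                    value=g["value"].to_numpy(),
                    value_kind=kind,
                )
            )
        out.append(
            InVitroBiokineticDataset(
                nominal_concentration_um=float(level),
                day=int(day),
                series=tuple(series),
                medium_volume_ml=float(vols["medium_volume_mL"]),
                lysate_volume_ml=float(vols["lysate_volume_mL"]),
            )
        )
    return out
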