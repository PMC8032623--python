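"""Whole-body PBPK model: conservation, linearity, limits and metrics."""

import numpy as np
import pytest

from ivive.params import DosingRegimen, ParameterValidationError
from ivive.pbpk import (
    ConcentrationTimeProfile,
    mass_balance_error,
    simulate,
    tissue_metric,
)

from conftest import make_one_compartment_params, make_two_tissue_params


class TestSimulate:
    def test_zero_dose_gives_identically_zero_profiles(self, small_params):
        res = simulate(small_params, DosingRegimen(dose=0.0), duration=24.0)
        for prof in res.profiles.values():
            assert np.all(prof.concentration == 0.0)
        assert mass_balance_error(res) == 0.0

    def test_one_compartment_closed_form(self):
        """Collapsed body matches (D/V) exp(-CL/V t) to 1e-4 relative."""
        V, CL, D = 5.0, 0.5, 10.0
        params = make_one_compartment_params(blood_volume=V, clearance=CL)
        res = simulate(params, DosingRegimen(dose=D), duration=10.0)
        t_check = np.linspace(0.5, 10.0, 10)
        ven = res.profiles["venous_blood"]
        # total blood-side amount behaves as one pool; venous concentration
        # equals the pool concentration after the fast mixing transient
        sim = np.interp(t_check, ven.time, ven.concentration)
        expected = (D / V) * np.exp(-(CL / V) * t_check)
        assert np.max(np.abs(sim - expected) / expected) < 1e-4

    @pytest.mark.parametrize("n_doses,interval", [(1, 24.0), (3, 24.0)])
    def test_mass_conservation_bolus(self, small_params, n_doses, interval):
        reg = DosingRegimen(dose=50.0, n_doses=n_doses, interval=interval)
        res = simulate(small_params, reg, duration=n_doses * interval + 24.0)
        assert mass_balance_error(res) <= 1e-3

    def test_mass_conservation_infusion(self, small_params):
        reg = DosingRegimen(dose=50.0, infusion_duration=2.0)
        res = simulate(small_params, reg, duration=48.0)
        assert mass_balance_error(res) <= 1e-3

    def test_dose_linearity(self, small_params):
        r1 = simulate(small_params, DosingRegimen(dose=10.0), duration=48.0)
        r2 = simulate(small_params, DosingRegimen(dose=20.0), duration=48.0)
        for name in r1.profiles:
            c1, c2 = r1.profiles[name].concentration, r2.profiles[name].concentration
            mask = c1 > 1e-12 * c1.max() if c1.max() > 0 else np.zeros_like(c1, bool)
            if mask.any():
                assert np.max(np.abs(c2[mask] - 2 * c1[mask]) / (2 * c1[mask])) < 5e-3

    def test_superposition_of_repeated_doses(self, small_params):
        """Two doses equal the sum of two time-shifted single doses."""
        reg2 = DosingRegimen(dose=30.0, n_doses=2, interval=24.0)
        res2 = simulate(small_params, reg2, duration=72.0)
        res1 = simulate(small_params, DosingRegimen(dose=30.0), duration=72.0)
        t = res1.time
        for name in ("venous_blood", "brain:tissue", "liver:tissue"):
            single = res1.profiles[name].concentration
            shifted = np.interp(t - 24.0, t, single, left=0.0)
            combined = single + shifted
            direct = res2.profiles[name].concentration
            mask = combined > 1e-9 * combined.max()
            assert np.max(np.abs(direct[mask] - combined[mask]) / combined[mask]) < 5e-3

    def test_expm_and_ode_solver_agree(self, small_params):
        reg = DosingRegimen(dose=40.0, n_doses=2, interval=12.0)
        a = simulate(small_params, reg, duration=36.0, grid_step=0.5, method="expm")
        b = simulate(small_params, reg, duration=36.0, grid_step=0.5, method="ivp")
        for name in a.profiles:
            ca, cb = a.profiles[name].concentration, b.profiles[name].concentration
            scale = max(ca.max(), 1e-12)
            assert np.max(np.abs(ca - cb)) / scale < 1e-5

    def test_ps_ladder_perfusion_limit(self):
        """Brain exposure grows monotonically with PS and plateaus."""
        aucs = []
        for ps in [0.01, 0.1, 1.0, 10.0, 100.0, 1000.0, 10000.0]:
            params = make_two_tissue_params(brain_ps=ps)
            res = simulate(params, DosingRegimen(dose=100.0), duration=24.0, grid_step=0.1)
            aucs.append(tissue_metric(res, "brain:tissue", "AUC", (0.0, 24.0)).value)
        aucs = np.array(aucs)
        assert np.all(np.diff(aucs) > -1e-9 * aucs[1:])  # monotone up
        assert aucs[-1] / aucs[-2] < 1.05  # plateaued at high PS

    def test_validation_errors(self, small_params):
        with pytest.raises(ParameterValidationError):
            simulate(small_params, DosingRegimen(dose=10.0), duration=24.0, grid_step=0.0)
        with pytest.raises(ParameterValidationError):
            # duration shorter than the regimen span
            simulate(
                small_params,
                DosingRegimen(dose=10.0, n_doses=3, interval=24.0),
                duration=24.0,
            )
        with pytest.raises(ParameterValidationError):
            DosingRegimen(dose=-1.0)


class TestMassBalanceError:
    def test_detects_artificial_perturbation(self, small_params, bolus_100):
        res = simulate(small_params, bolus_100, duration=24.0)
        res.amounts[:, 2] *= 2.0  # double one compartment
        assert mass_balance_error(res) > 0.0


class TestTissueMetric:
    @staticmethod
    def _result_with(profile_values, time):
        # wrap a handmade profile into a result-like object for metric tests
        from ivive.params import DosingRegimen as DR
        from ivive.pbpk import SimulationResult

        prof = ConcentrationTimeProfile("x", time, profile_values)
        return SimulationResult(
            time=time, profiles={"x": prof},
            amounts=np.zeros((time.size, 1)), state_names=["x"],
            metabolized=np.zeros(time.size), params=None, regimen=DR(dose=0.0),
            solver="expm",
        )

    def test_constant_profile(self):
        t = np.linspace(0, 24, 49)
        res = self._result_with(np.full(t.size, 0.5), t)
        assert tissue_metric(res, "x", "AUC", (0.0, 24.0)).value == pytest.approx(12.0)
        assert tissue_metric(res, "x", "Cmax", (0.0, 24.0)).value == pytest.approx(0.5)

    def test_linear_ramp(self):
        t = np.linspace(0, 24, 49)
        res = self._result_with(t / 24.0 * 0.8, t)
        assert tissue_metric(res, "x", "AUC", (0.0, 24.0)).value == pytest.approx(9.6)

    def test_window_outside_span_raises(self, small_params, bolus_100):
        res = simulate(small_params, bolus_100, duration=24.0)
        with pytest.raises(ValueError, match="outside"):
            tissue_metric(res, "venous_blood", "AUC", (12.0, 48.0))

    def test_unknown_compartment_raises(self, small_params, bolus_100):
        res = simulate(small_params, bolus_100, duration=24.0)
        with pytest.raises(KeyError):
            tissue_metric(res, "pancreas:tissue", "AUC", (0.0, 24.0))

    def test_metric_scales_with_dose(self, small_params):
        r1 = simulate(small_params, DosingRegimen(dose=10.0), duration=48.0)
        r2 = simulate(small_params, DosingRegimen(dose=20.0), duration=48.0)
        for kind in ("AUC", "Cmax"):
            m1 = tissue_metric(r1, "brain:tissue", kind, (0.0, 48.0)).value
            m2 = tissue_metric(r2, "brain:tissue", kind, (0.0, 48.0)).value
            assert m2 == pytest.approx(2 * m1, rel=5e-3)


class TestExport:
    def test_tidy_frame_shape(self, small_params, bolus_100):
        res = simulate(small_params, bolus_100, duration=2.0, grid_step=0.5)
        df = res.to_tidy_frame()
        assert set(df.columns) == {"time_h", "compartment", "concentration_ug_per_ml"}
        assert len(df) == len(res.profiles) * res.time.size

    def test_csv_export_with_metadata_sidecar(self, small_params, bolus_100, tmp_path):
        import json
        import pandas as pd

        res = simulate(small_params, bolus_100, duration=2.0, grid_step=0.5)
        csv = tmp_path / "sim.csv"
        res.write_csv(csv)
        assert len(pd.read_csv(csv)) == len(res.profiles) * res.time.size
        meta = json.loads((tmp_path / "sim.json").read_text())
        assert meta["regimen"]["dose_mg"] == 100.0
        assert meta["solver"] == "expm"
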