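"""In vitro metrics: unit conversions, trapezoid AUC, Cmax, dataset I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ivive.biokinetics import (
    CompartmentSeries,
    InVitroBiokineticDataset,
    auc_trapezoid,
    concentration_to_per_flask,
    micromolar_to_ugml,
    observed_cmax,
    per_flask_to_concentration,
    read_biokinetics_csv,
    ugml_to_micromolar,
    write_biokinetics_csv,
)
from ivive.pbpk import ConcentrationTimeProfile


class TestUnitConversions:
    @pytest.mark.parametrize(
        "amount,volume,expected",
        [(0.0, 3.0, 0.0), (1.0, 2.0, 0.5), (4.2, 1.0, 4.2)],
    )
    def test_per_flask_to_concentration(self, amount, volume, expected):
        assert per_flask_to_concentration(amount, volume) == pytest.approx(expected)

    def test_per_flask_requires_positive_volume(self):
        with pytest.raises(ValueError):
            per_flask_to_concentration(1.0, 0.0)

    @pytest.mark.parametrize(
        "um,expected",
        [(0.0, 0.0), (1.25, 0.8066), (2.5, 1.6133)],
    )
    def test_micromolar_to_ugml_amiodarone(self, um, expected):
        assert micromolar_to_ugml(um, 645.31) == pytest.approx(expected, abs=5e-5)

    @settings(deadline=None, max_examples=50)
    @given(
        value=st.floats(1e-9, 1e6),
        factor=st.floats(1e-3, 1e3),
    )
    def test_round_trips_are_identities(self, value, factor):
        assert per_flask_to_concentration(
            concentration_to_per_flask(value, factor), factor
        ) == pytest.approx(value, rel=1e-12)
        assert ugml_to_micromolar(
            micromolar_to_ugml(value, 645.31), 645.31
        ) == pytest.approx(value, rel=1e-12)


def profile(times, concs):
    return ConcentrationTimeProfile("cells", np.asarray(times, float), np.asarray(concs, float))


class TestAucTrapezoid:
    def test_constant(self):
        assert auc_trapezoid(profile([0, 24], [0.05, 0.05]), 0, 24) == pytest.approx(1.2)

    def test_triangle(self):
        p = profile([0, 12, 24], [0.0, 0.1, 0.0])
        assert auc_trapezoid(p, 0, 24) == pytest.approx(1.2)

    def test_single_point_raises(self):
        with pytest.raises(ValueError):
            auc_trapezoid(profile([12.0], [0.1]), 0, 24)

    def test_window_not_covered_raises(self):
        with pytest.raises(ValueError, match="not covered"):
            auc_trapezoid(profile([2, 24], [0.1, 0.1]), 0, 24)

    def test_interpolated_endpoints(self):
        # endpoints at t=5 and t=15 interpolate to 0.5; the tent integrates to 7.5
        p = profile([0, 10, 20], [0.0, 1.0, 0.0])
        assert auc_trapezoid(p, 5, 15) == pytest.approx(7.5)

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=5, max_size=5),
    )
    def test_additive_over_adjacent_windows(self, concs):
        p = profile([0, 6, 12, 18, 24], concs)
        total = auc_trapezoid(p, 0, 24)
        assert auc_trapezoid(p, 0, 12) + auc_trapezoid(p, 12, 24) == pytest.approx(
            total, abs=1e-12 + 1e-9 * abs(total)
        )

    @settings(deadline=None, max_examples=50)
    @given(
        st.lists(st.floats(0.0, 10.0), min_size=4, max_size=4),
        st.lists(st.floats(0.0, 2.0), min_size=4, max_size=4),
    )
    def test_monotone_in_concentrations(self, concs, bump):
        t = [0, 8, 16, 24]
        lo = auc_trapezoid(profile(t, concs), 0, 24)
        hi = auc_trapezoid(profile(t, np.add(concs, bump)), 0, 24)
        assert hi >= lo - 1e-12


class TestObservedCmax:
    def test_examples(self):
        assert observed_cmax(profile([0, 2, 24], [0.01, 0.042, 0.03])) == pytest.approx(0.042)
        assert observed_cmax(profile([0, 24], [0.0, 0.0])) == 0.0
        assert observed_cmax(profile([0, 24], [0.3, 0.3])) == pytest.approx(0.3)


class TestDataset:
    def _dataset(self):
        series = (
            CompartmentSeries("medium", np.array([0.0, 6, 24]), np.array([0.8, 0.5, 0.2]), "concentration"),
            CompartmentSeries("cells", np.array([0.0, 6, 24]), np.array([0.0, 0.02, 0.04]), "amount_per_flask"),
            CompartmentSeries("plastic", np.array([0.0, 6, 24]), np.array([0.0, 0.5, 1.0]), "amount_per_flask"),
        )
        return InVitroBiokineticDataset(
            nominal_concentration_um=1.25, day=14, series=series,
            medium_volume_ml=2.0, lysate_volume_ml=0.5,
        )

    def test_cell_metric_uses_lysate_volume(self):
        ds = self._dataset()
        cmax = ds.cell_metric("Cmax")
        assert cmax.value == pytest.approx(0.04 / 0.5)
        assert cmax.source == "measured_in_vitro"

    def test_replicates_averaged_before_auc(self):
        s = CompartmentSeries(
            "cells",
            np.array([0.0, 0.0, 24.0, 24.0]),
            np.array([0.0, 0.02, 0.04, 0.06]),
            "amount_per_flask",
        )
        prof = s.mean_profile(1.0)
        assert prof.concentration == pytest.approx([0.01, 0.05])

    def test_per_flask_conversion_requires_volume(self):
        s = self._dataset().compartment("cells")
        with pytest.raises(ValueError, match="volume"):
            s.mean_profile(None)

    def test_csv_round_trip(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "bio.csv"
        write_biokinetics_csv([ds], path)
        back = read_biokinetics_csv(path)
        assert len(back) == 1
        b = back[0]
        assert b.nominal_concentration_um == 1.25 and b.day == 14
        assert b.lysate_volume_ml == 0.5
        np.testing.assert_allclose(
            b.compartment("cells").value, ds.compartment("cells").value
        )
        assert b.cell_metric("AUC").value == pytest.approx(ds.cell_metric("AUC").value)

    def test_strict_unit_checking(self, tmp_path):
        ds = self._dataset()
        path = tmp_path / "bio.csv"
        write_biokinetics_csv([ds], path)
        text = path.read_text().replace("ug/mL", "mg/mL")
        path.write_text(text)
        with pytest.raises(ValueError, match="unit"):
            read_biokinetics_csv(path)

    def test_day_validation(self):
        with pytest.raises(ValueError):
            InVitroBiokineticDataset(
                nominal_concentration_um=1.25, day=7, series=(),
                medium_volume_ml=2.0, lysate_volume_ml=1.0,
            )
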