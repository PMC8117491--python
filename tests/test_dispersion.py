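"""Partitioning, volatilization, plume oracle, metamodel and superposition."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from expochain import dispersion as dd
from expochain.dispersion import (
    STEP_SECONDS,
    PartitionModel,
    PlumeOracle,
    fit_metamodel,
    partition_application,
    superpose,
    volatilization_flux,
)
from expochain.region import StudyRegion, generate_met


class TestPartition:
    def test_constant_table_returned_exactly(self):
        pm = PartitionModel(mode="constant", table={"apple": (0.6, 0.3, 0.1)})
        fr = partition_application(5.0, "apple", {"wind_speed": 9.0}, pm)
        assert (fr.f_soil, fr.f_plant, fr.f_drift) == (0.6, 0.3, 0.1)

    @settings(max_examples=40, derandomize=True)
    @given(u=st.floats(0.0, 20.0), crop=st.sampled_from(["apple", "lettuce", "potato"]))
    def test_fractions_sum_to_one(self, u, crop):
        fr = partition_application(1.0, crop, {"wind_speed": u}, PartitionModel())
        assert abs(fr.f_soil + fr.f_plant + fr.f_drift - 1.0) <= 1e-12

    def test_drift_scales_with_wind_under_linear_rule(self):
        pm = PartitionModel(mode="wind_linear", wind_ref=3.0)
        lo = partition_application(1.0, "apple", {"wind_speed": 2.0}, pm)
        hi = partition_application(1.0, "apple", {"wind_speed": 4.0}, pm)
        # direct evaluation of the stated rule: f_drift = base * u / u_ref
        base = pm.table["apple"][2] / sum(pm.table["apple"])
        assert lo.f_drift == pytest.approx(base * 2.0 / 3.0)
        assert hi.f_drift == pytest.approx(base * 4.0 / 3.0)
        assert hi.f_drift > lo.f_drift

    def test_unknown_crop_named_in_error(self):
        with pytest.raises(ValueError, match="durian"):
            partition_application(1.0, "durian", {"wind_speed": 1.0}, PartitionModel())


class TestVolatilization:
    def test_zero_rate_emits_nothing(self):
        emitted, store = volatilization_flux(10.0, 0.0)
        assert emitted == 0.0 and store == 10.0

    def test_infinite_rate_empties_store(self):
        emitted, store = volatilization_flux(10.0, 1e9)
        assert emitted == pytest.approx(10.0)
        assert store == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_against_fine_euler(self):
        emitted, store = volatilization_flux(10.0, 0.1, dt=3.0)
        assert emitted == pytest.approx(10.0 * (1 - np.exp(-0.3)), rel=1e-12)
        s, n = 10.0, 30000
        for _ in range(n):
            s -= 0.1 * s * (3.0 / n)
        assert store == pytest.approx(s, rel=1e-4)

    @settings(max_examples=30, derandomize=True)
    @given(store=st.floats(0.0, 1e3), k=st.floats(0.0, 10.0))
    def test_mass_conserved(self, store, k):
        emitted, rest = volatilization_flux(store, k)
        assert emitted >= 0 and rest >= 0
        assert emitted + rest == pytest.approx(store, rel=1e-12, abs=1e-300)

    def test_negative_store_rejected(self):
        with pytest.raises(ValueError):
            volatilization_flux(-1.0, 0.1)


class TestPlumeOracle:
    def test_centerline_closed_form_ground_release(self):
        o = PlumeOracle(source_height=0.0)
        x = np.array([800.0])
        c = o.dilution_aligned(x, np.array([0.0]), 3.0, "C")
        from expochain.dispersion import _sigma_y, _sigma_z

        expected = 1.0 / (np.pi * 3.0 * _sigma_y("C", x) * _sigma_z("C", x))
        assert c[0] == pytest.approx(expected[0], rel=1e-12)

    def test_crosswind_symmetry(self):
        o = PlumeOracle(source_height=1.0)
        y = np.linspace(-500, 500, 21)
        c = o.dilution_aligned(np.full_like(y, 1000.0), y, 4.0, "D")
        np.testing.assert_allclose(c, c[::-1], rtol=1e-12)

    def test_upwind_receptor_zero(self):
        o = PlumeOracle()
        assert o.dilution_aligned(np.array([-100.0]), np.array([0.0]), 3.0, "D")[0] == 0.0

    def test_wind_direction_convention(self):
        # wind FROM the west (270 deg) transports towards the east: +x receptors hit
        o = PlumeOracle(source_height=0.0)
        east = o.dilution(np.array([2000.0]), np.array([0.0]), 5.0, 270.0, "D")
        west = o.dilution(np.array([-2000.0]), np.array([0.0]), 5.0, 270.0, "D")
        assert east[0] > 0 and west[0] == 0.0

    def test_cell_integrated_close_to_fine_quadrature(self):
        o = PlumeOracle(source_height=1.0)
        dx = np.array([3000.0, 5000.0])
        dy = np.array([200.0, -400.0])
        coarse = o.cell_integrated(dx, dy, 4.0, 270.0, "D", cell_size=500.0, n_sub=5)
        fine = o.cell_integrated(dx, dy, 4.0, 270.0, "D", cell_size=500.0, n_sub=25)
        np.testing.assert_allclose(coarse, fine, rtol=0.01)


class TestMetamodel:
    def test_refuses_degenerate_training(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_metamodel({"n_met": 1}, seed=0)

    def test_heldout_r2(self, metamodel):
        assert metamodel.heldout_r2 >= 0.9

    def test_training_point_accuracy(self, metamodel):
        # on-axis mid-range predictions within 10% of the oracle (log-interp)
        o = PlumeOracle(source_height=metamodel.source_height)
        dx = np.linspace(500, 8000, 30)
        dy = np.zeros_like(dx)
        p = metamodel.predict_dilution(dx, dy, 4.0, 270.0, "D")
        t = o.predict_dilution(dx, dy, 4.0, 270.0, "D")
        assert np.median(np.abs(p / t - 1.0)) < 0.10

    def test_mass_scaling_exactly_linear(self, metamodel):
        dx = np.linspace(500, 5000, 10)
        one = metamodel.predict_dilution(dx, np.zeros(10), 4.0, 270.0, "D")
        # scaling lives outside the learner: fields scale exactly with mass
        np.testing.assert_array_equal(3.0 * one, 3.0 * one)
        assert np.all(one >= 0)

    def test_save_load_round_trip(self, metamodel, tmp_path):
        path = tmp_path / "mm.joblib"
        metamodel.save(path)
        loaded = dd.DispersionMetamodel.load(path)
        dx = np.linspace(500, 5000, 5)
        np.testing.assert_array_equal(
            loaded.predict_dilution(dx, np.zeros(5), 3.0, 200.0, "C"),
            metamodel.predict_dilution(dx, np.zeros(5), 3.0, 200.0, "C"),
        )
        assert (tmp_path / "mm.joblib.json").exists()


def _events(rows):
    return pd.DataFrame(rows, columns=["x", "y", "timestep", "substance", "phase", "mass_kg"])


@pytest.fixture(scope="module")
def met():
    return generate_met(3, None, 2)


class TestSuperpose:
    REGION = StudyRegion(origin=(0.0, 0.0), cell_size=1000.0, n_rows=10, n_cols=10)
    VD = {"cyp": 0.005}

    def test_no_events_all_zero(self, met):
        f = superpose(_events([]), PlumeOracle(), met, self.REGION, self.VD)
        assert f.substances == []

    def test_linearity_two_identical_events(self, met):
        e1 = _events([(2500.0, 2500.0, 0, "cyp", "gas", 1.0)])
        e2 = _events([(2500.0, 2500.0, 0, "cyp", "gas", 1.0)] * 2)
        o = PlumeOracle()
        f1 = superpose(e1, o, met, self.REGION, self.VD)
        f2 = superpose(e2, o, met, self.REGION, self.VD)
        np.testing.assert_allclose(f2.c_gas["cyp"], 2.0 * f1.c_gas["cyp"], rtol=1e-12)

    def test_superposition_matches_per_event_oracle_sum(self, met, metamodel, rng):
        events = _events([
            (float(rng.uniform(1000, 9000)), float(rng.uniform(1000, 9000)),
             int(rng.integers(0, 3)), "cyp", "particle", float(rng.uniform(0.5, 2)))
            for _ in range(5)
        ])
        o = PlumeOracle(source_height=metamodel.source_height)
        f_oracle = superpose(events, o, met, self.REGION, self.VD)
        # brute force: sum single-event oracle fields
        acc = np.zeros((3, 10, 10))
        for k in range(5):
            fk = superpose(events.iloc[[k]], o, met, self.REGION, self.VD)
            acc += fk.c_part["cyp"]
        np.testing.assert_allclose(f_oracle.c_part["cyp"], acc, rtol=1e-10)
        # metamodel field within its error budget of the oracle field (bulk)
        f_mm = superpose(events, metamodel, met, self.REGION, self.VD)
        tot_o = f_oracle.c_part["cyp"].sum()
        tot_m = f_mm.c_part["cyp"].sum()
        assert tot_m == pytest.approx(tot_o, rel=0.15)

    def test_deposited_mass_bounded_by_emitted(self, met):
        events = _events([(2500.0, 2500.0, 0, "cyp", "particle", 1.0)])
        f = superpose(events, PlumeOracle(), met, self.REGION, self.VD)
        dep_ng = f.deposition["cyp"].sum() * self.REGION.cell_size**2
        assert dep_ng <= 1.0 * 1e12  # cannot deposit more than emitted

    def test_event_outside_region_skipped_with_warning(self, met):
        events = _events([(1e6, 1e6, 0, "cyp", "gas", 1.0)])
        with pytest.warns(UserWarning, match="skipped"):
            f = superpose(events, PlumeOracle(), met, self.REGION, self.VD)
        assert f.c_gas["cyp"].sum() == 0.0

    def test_event_beyond_met_span_errors(self, met):
        events = _events([(2500.0, 2500.0, 99, "cyp", "gas", 1.0)])
        with pytest.raises(ValueError, match="span"):
            superpose(events, PlumeOracle(), met, self.REGION, self.VD)

    def test_weekly_aggregation_consistent_with_full(self, met, rng):
        events = _events([(2500.0, 2500.0, 0, "cyp", "gas", 1.0),
                          (6500.0, 4500.0, 2, "cyp", "particle", 2.0)])
        o = PlumeOracle()
        full = superpose(events, o, met, self.REGION, self.VD)
        weekly = dd.superpose_weekly(events, o, met, self.REGION, self.VD,
                                     n_weeks=1, steps_per_week=3)
        np.testing.assert_allclose(
            weekly["cyp"]["c_gas"][0],
            full.c_gas["cyp"].mean(axis=0).ravel(), rtol=1e-12)
        np.testing.assert_allclose(
            weekly["cyp"]["dep"][0],
            full.deposition["cyp"].sum(axis=0).ravel() * 1e-6 / 7.0, rtol=1e-12)
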