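"""Synthetic region generators: determinism, conservation, censoring logic."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from expochain.region import (
    STATUS_BELOW_LOQ,
    STATUS_NON_DETECT,
    STATUS_QUANTIFIED,
    ConfigurationError,
    MetParams,
    Parcel,
    StudyRegion,
    generate_applications,
    generate_met,
    generate_region,
    pasquill_class,
    sample_monitoring,
)

CFG = {
    "n_rows": 50,
    "n_cols": 50,
    "n_parcels": 200,
    "crop_mix": {"apple": 0.2, "lettuce": 0.2, "potato": 0.2, "tomato": 0.2, "cereal": 0.2},
    "mean_annual_mass_kg": {"cypermethrin": 2.0},
}


class TestStudyRegion:
    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ConfigurationError):
            StudyRegion(n_rows=0, n_cols=5)
        with pytest.raises(ConfigurationError):
            StudyRegion(cell_size=-1.0)

    def test_half_open_cell_assignment(self, small_region):
        # the shared edge belongs to the next cell (half-open intervals)
        assert small_region.cell_index(0.0, 0.0) == (0, 0)
        assert small_region.cell_index(2000.0, 0.0) == (0, 1)
        assert small_region.cell_index(1999.999, 3999.0) == (1, 0)

    def test_cell_centers_row_major(self, small_region):
        c = small_region.cell_centers()
        assert c.shape == (100, 2)
        assert tuple(c[0]) == (1000.0, 1000.0)
        assert tuple(c[1]) == (3000.0, 1000.0)  # column-fastest


class TestGenerateRegion:
    def test_empty_parcel_config(self):
        _, parcels, _ = generate_region({"n_rows": 3, "n_cols": 3, "n_parcels": 0}, 1)
        assert parcels == []

    def test_determinism(self):
        a = generate_region(CFG, 7)
        b = generate_region(CFG, 7)
        assert all(pa.polygon.equals(pb.polygon) and pa.crop == pb.crop
                   and pa.annual_mass == pb.annual_mass
                   for pa, pb in zip(a[1], b[1]))
        np.testing.assert_array_equal(a[2].population, b[2].population)

    def test_parcels_inside_and_crop_mix(self):
        region, parcels, pop = generate_region(CFG, 7)
        x0, y0, x1, y1 = region.bounds
        hull = box(x0, y0, x1, y1)
        assert all(hull.contains(p.polygon) for p in parcels)
        # multinomial 3-sigma check on crop frequencies
        n = len(parcels)
        for crop, p in CFG["crop_mix"].items():
            k = sum(1 for q in parcels if q.crop == crop)
            sigma = np.sqrt(n * p * (1 - p))
            assert abs(k - n * p) <= 3 * sigma, crop
        assert np.all(pop.urban_unit_size >= 0)

    def test_negative_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            generate_region({"n_rows": -2, "n_cols": 3}, 0)


class TestApplications:
    CAL = {"events_per_parcel": 3,
           "windows": {"apple": (100, 140), "cereal": (50, 90)}}

    def _parcels(self):
        return [
            Parcel("P0", box(0, 0, 500, 500), "apple", {"cyp": 12.0}),
            Parcel("P1", box(1000, 0, 1500, 500), "cereal", {"cyp": 0.0, "del": 5.0}),
        ]

    def test_mass_conservation_and_windows(self):
        apps = generate_applications(self._parcels(), ["cyp", "del"], self.CAL, 3)
        agg = apps.groupby(["parcel_id", "substance"])["mass_kg"].sum()
        assert agg[("P0", "cyp")] == pytest.approx(12.0, rel=1e-9)
        assert agg[("P1", "del")] == pytest.approx(5.0, rel=1e-9)
        # zero-mass pairs yield no events
        assert ("P1", "cyp") not in agg.index
        apple = apps[apps.parcel_id == "P0"]
        assert apple.timestep.between(100, 140).all()

    def test_empty_window_with_mass_errors(self):
        cal = {"events_per_parcel": 2, "windows": {"apple": (10, 9), "cereal": (0, 5)}}
        with pytest.raises(ConfigurationError):
            generate_applications(self._parcels(), ["cyp"], cal, 0)

    def test_determinism(self):
        a = generate_applications(self._parcels(), ["cyp", "del"], self.CAL, 9)
        b = generate_applications(self._parcels(), ["cyp", "del"], self.CAL, 9)
        pd.testing.assert_frame_equal(a, b)


class TestMet:
    def test_single_record_valid(self):
        met = generate_met(1, None, 0)
        assert len(met) == 1
        r = met.iloc[0]
        assert r.wind_speed >= 0 and 0 <= r.wind_dir < 360
        assert r.stability_class in "ABCDEF"

    def test_calm_wind_floored(self):
        p = MetParams(weibull_scale=1e-6, min_wind=0.5)
        met = generate_met(200, p, 1)
        assert met.wind_speed.min() == pytest.approx(0.5)

    def test_prevailing_direction_circular_mean(self):
        p = MetParams(prevailing_dir=225.0, dir_kappa=3.0)
        met = generate_met(4000, p, 5)
        rad = np.radians(met.wind_dir)
        mean_dir = np.degrees(np.arctan2(np.sin(rad).mean(), np.cos(rad).mean())) % 360
        assert abs((mean_dir - 225.0 + 180) % 360 - 180) < 5.0

    def test_pasquill_lookup_spans_all_classes(self):
        got = {pasquill_class(u, d, c)
               for u in (1.0, 2.5, 4.0, 7.0) for d in (True, False) for c in (2, 6)}
        assert got == set("ABCDEF")


class TestMonitoring:
    def _stations(self, region, lod=0.01, loq=0.03):
        return pd.DataFrame(
            {"station_id": ["S1", "S2"], "x": [1000.0, 5000.0], "y": [1000.0, 5000.0],
             "substance": ["cyp", "cyp"], "LOD": lod, "LOQ": loq}
        )

    def test_status_rules(self, small_region):
        field = np.full(small_region.shape, 0.02)  # between LOD and LOQ
        s = sample_monitoring({"cyp": field}, self._stations(small_region),
                              {"sigma": 0.0}, small_region, 0)
        assert (s.status == STATUS_BELOW_LOQ).all()
        assert s.value.isna().all()
        field[:] = 0.001
        s = sample_monitoring({"cyp": field}, self._stations(small_region),
                              {"sigma": 0.0}, small_region, 0)
        assert (s.status == STATUS_NON_DETECT).all()

    def test_noiseless_limit_recovers_truth(self, small_region):
        field = np.full(small_region.shape, 5.0)
        s = sample_monitoring({"cyp": field}, self._stations(small_region),
                              {"sigma": 0.0}, small_region, 0)
        assert (s.status == STATUS_QUANTIFIED).all()
        np.testing.assert_allclose(s.value, 5.0)

    def test_station_outside_region_rejected(self, small_region):
        st = self._stations(small_region)
        st.loc[0, "x"] = 1e6
        with pytest.raises(ValueError, match="S1"):
            sample_monitoring({"cyp": np.ones(small_region.shape)}, st,
                              {"sigma": 0.1}, small_region, 0)

    def test_censoring_frequency_at_median_lod(self, small_region):
        # LOD at the median of the noisy lognormal draw: ~50% non-detects
        n = 400
        rng = np.random.default_rng(2)
        xy = rng.uniform(0, 20000, (n, 2))
        st = pd.DataFrame({"station_id": [f"S{i}" for i in range(n)],
                           "x": xy[:, 0], "y": xy[:, 1], "substance": "cyp",
                           "LOD": 1.0, "LOQ": 1.0})
        field = np.full(small_region.shape, 1.0)  # median of the draw = truth
        s = sample_monitoring({"cyp": field}, st, {"sigma": 0.5}, small_region, 3)
        frac = (s.status == STATUS_NON_DETECT).mean()
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / n)
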