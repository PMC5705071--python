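"""Generators: seascape geometry, current kinematics, climate, Tweedie."""

from itertools import combinations

import numpy as np
import pytest

from reefsources.synth.climate import ClimateConfig, ThermalEvent, build_sst
from reefsources.synth.currents import (CurrentsConfig, build_currents,
                                        discrete_divergence)
from reefsources.synth.seascape import (ConfigError, SeascapeConfig,
                                        PlantedConfig, build_reefs)
from reefsources.synth.surveys import SurveyConfig, build_surveys, sample_tweedie
from reefsources.thermal import degree_heating_weeks, significant_event_years


class TestBuildReefs:
    def test_minimal_single_reef(self):
        scape, truth = build_reefs(SeascapeConfig(n_reefs=1, n_regions=1),
                                   seed=0)
        assert truth is None
        assert len(scape.reefs) == 1
        r = scape.reefs[0]
        assert r.region == 0
        assert r.polygon.is_valid and r.area > 0

    def test_deterministic_for_fixed_seed(self):
        cfg = SeascapeConfig(n_reefs=50, n_regions=3)
        a, _ = build_reefs(cfg, seed=7)
        b, _ = build_reefs(cfg, seed=7)
        assert a.ids == b.ids
        for ra, rb in zip(a.reefs, b.reefs):
            assert ra.polygon.equals_exact(rb.polygon, 0)
            assert (ra.region, ra.no_take) == (rb.region, rb.no_take)

    def test_polygons_convex_and_disjoint(self, small_seascape):
        for reef in small_seascape.reefs:
            hull = reef.polygon.convex_hull
            assert reef.polygon.area == pytest.approx(hull.area, rel=1e-9)
            assert reef.polygon.contains(reef.polygon.centroid)
        # oracle: pairwise geometric intersection test
        for a, b in combinations(small_seascape.polygons, 2):
            assert not a.intersects(b)

    def test_every_reef_inside_domain_with_one_region_each(self, small_seascape):
        xmin, ymin, xmax, ymax = small_seascape.domain
        for reef in small_seascape.reefs:
            bx0, by0, bx1, by1 = reef.polygon.bounds
            assert bx0 >= xmin and by0 >= ymin and bx1 <= xmax and by1 <= ymax
            assert 0 <= reef.region < 3

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigError):
            build_reefs(SeascapeConfig(n_reefs=0), seed=0)
        with pytest.raises(ConfigError):
            build_reefs(SeascapeConfig(domain=(0, 0, -10, 10)), seed=0)

    def test_planted_mode_records_truth(self):
        cfg = SeascapeConfig(n_reefs=40, n_regions=2,
                             planted=PlantedConfig(n_planted=6))
        scape, truth = build_reefs(cfg, seed=3)
        assert truth is not None and len(truth.robust_ids) == 6
        assert truth.robust_ids <= set(scape.ids)
        planted = [r for r in scape.reefs if r.id in truth.robust_ids]
        assert all(r.band == "outer" for r in planted)


class TestBuildCurrents:
    def test_pure_jet_has_no_cross_shelf_flow(self, small_seascape):
        cfg = CurrentsConfig(eddy_amplitude=0.0, inflow_speed=0.0,
                             coastal_jet_speed=0.0)
        fld = build_currents(small_seascape, cfg, seed=0)
        assert np.abs(fld.v).max() < 1e-12
        assert fld.u.max() > 0.9 * cfg.jet_speed

    def test_discrete_divergence_free(self, small_seascape):
        fld = build_currents(small_seascape, CurrentsConfig(), seed=5)
        scale = max(np.abs(fld.u).max(), np.abs(fld.v).max())
        for it in (0, len(fld.times) // 2, len(fld.times) - 1):
            div = discrete_divergence(fld, it)
            assert np.abs(div).max() < 1e-6 * scale

    def test_deterministic_rebuild(self, small_seascape):
        a = build_currents(small_seascape, CurrentsConfig(), seed=9)
        b = build_currents(small_seascape, CurrentsConfig(), seed=9)
        assert np.array_equal(a.u, b.u) and np.array_equal(a.v, b.v)

    def test_too_short_record_rejected(self, small_seascape):
        with pytest.raises(ConfigError):
            build_currents(small_seascape,
                           CurrentsConfig(time_span_hours=24.0), seed=0,
                           min_span_hours=30 * 24.0)


class TestBuildSST:
    def test_null_climate_gives_zero_dhw(self, small_seascape):
        cfg = ClimateConfig(n_years=3, events=())
        sst = build_sst(small_seascape, cfg, seed=1)
        dhw = degree_heating_weeks(sst)
        assert dhw.annual_max.max() == 0.0
        assert significant_event_years(dhw) == []

    def test_planted_events_detected_exactly(self, small_seascape):
        years = (2, 5, 11, 17, 20, 23, 28, 30, 33, 35)
        cfg = ClimateConfig(n_years=36,
                            events=tuple(ThermalEvent(year=y) for y in years))
        sst = build_sst(small_seascape, cfg, seed=4)
        found = significant_event_years(degree_heating_weeks(sst))
        assert found == list(years)

    def test_uniform_hotspot_closed_form(self, small_seascape):
        # +3 degC for 4 weeks with zero noise -> annual-max DHW = 12
        cfg = ClimateConfig(n_years=2, noise_amplitude=0.0,
                            events=(ThermalEvent(year=1, intensity=3.0,
                                                 n_weeks=4),))
        sst = build_sst(small_seascape, cfg, seed=0)
        dhw = degree_heating_weeks(sst)
        assert dhw.annual_max[0].max() == pytest.approx(0.0)
        assert dhw.annual_max[1].max() == pytest.approx(12.0)
        px = dhw.reef_pixel_indices()
        assert np.allclose(dhw.annual_max[1][px], 12.0)

    def test_event_year_outside_record_rejected(self, small_seascape):
        cfg = ClimateConfig(n_years=5, events=(ThermalEvent(year=7),))
        with pytest.raises(ConfigError):
            build_sst(small_seascape, cfg, seed=0)

    def test_every_reef_has_pixels(self, small_seascape):
        sst = build_sst(small_seascape, ClimateConfig(n_years=1), seed=2)
        assert set(sst.reef_pixels) == set(small_seascape.ids)
        assert all(len(v) >= 1 for v in sst.reef_pixels.values())


class TestTweedieSampler:
    def test_zero_mean_gives_exact_zero(self):
        out = sample_tweedie(np.zeros(100), p=1.6, phi=3.58, seed=0)
        assert np.all(out == 0.0)

    def test_moment_identities(self):
        # oracle: compound Poisson-gamma mean mu, variance phi * mu**p
        mu, p, phi, n = 100.0, 1.6, 3.58, 100_000
        x = sample_tweedie(np.full(n, mu), p=p, phi=phi, seed=42)
        assert x.mean() == pytest.approx(mu, rel=0.02)
        assert x.var() == pytest.approx(phi * mu**p, rel=0.05)

    def test_zero_inflation_probability(self):
        mu, p, phi, n = 5.0, 1.6, 3.58, 100_000
        lam = mu ** (2 - p) / (phi * (2 - p))
        x = sample_tweedie(np.full(n, mu), p=p, phi=phi, seed=7)
        assert (x == 0).mean() == pytest.approx(np.exp(-lam), abs=0.01)

    def test_determinism_and_domain_errors(self):
        a = sample_tweedie(np.full(10, 3.0), 1.5, 2.0, seed=1)
        b = sample_tweedie(np.full(10, 3.0), 1.5, 2.0, seed=1)
        assert np.array_equal(a, b)
        with pytest.raises(ValueError):
            sample_tweedie(np.ones(3), p=2.5, phi=1.0, seed=0)
        with pytest.raises(ValueError):
            sample_tweedie(np.ones(3), p=1.5, phi=-1.0, seed=0)


class TestBuildSurveys:
    def _supply(self, n=500, seed=0):
        import pandas as pd
        rng = np.random.default_rng(seed)
        return pd.Series(rng.lognormal(0, 1, n),
                         index=[f"R{i:03d}" for i in range(n)])

    def test_survey_count_mirrors_campaign_scale(self):
        surveys = build_surveys(self._supply(), SurveyConfig(n_surveyed=137),
                                seed=1)
        assert len(surveys) == 137
        assert (surveys["max_cots_per_km2"] >= 0).all()
        assert surveys["coral_cover"].between(0, 1).all()

    def test_null_link_no_association(self):
        # b = 0: outbreak status independent of supply (chi-square oracle)
        from scipy.stats import chi2_contingency
        supply = self._supply(500, seed=3)
        cfg = SurveyConfig(n_surveyed=500, link_slope=0.0,
                           link_intercept=np.log(800.0))
        pvals = []
        for seed in range(5):
            sv = build_surveys(supply, cfg, seed=seed)
            high = supply.loc[sv["reef_id"]] > supply.median()
            ob = sv["max_cots_per_km2"].to_numpy() >= 1500
            tab = np.array([[(high.to_numpy() & ob).sum(),
                             (high.to_numpy() & ~ob).sum()],
                            [(~high.to_numpy() & ob).sum(),
                             (~high.to_numpy() & ~ob).sum()]])
            pvals.append(chi2_contingency(tab)[1])
        assert max(pvals) > 0.01  # not systematically associated

    def test_empty_selection_rejected(self):
        import pandas as pd
        with pytest.raises(ConfigError):
            build_surveys(pd.Series(dtype=float), SurveyConfig(), seed=0)
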