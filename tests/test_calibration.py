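import numpy as np
import pytest

from cambium import (
    FixtureConfig,
    StudyRecord,
    SupplyRegression,
    calibrate_average_season,
    filter_seasons,
    gen_growth_series,
    infer_supply_for_production,
    load_observed_production,
    run_multi_year,
    simulate_season,
    split_goodness,
)


@pytest.fixture(scope="module")
def short_season():
    cfg = FixtureConfig(
        n_years=1, seed=21, doy_start=150, doy_end=200, ar_sigma=0.0,
        dips_range=(0, 0), peak_sd=0.0, bounds_jitter_sd=0.0,
        drought_depth_range=(0.0, 0.0),
    )
    return gen_growth_series(cfg)[1963]


class TestInferSupply:
    def test_zero_target_needs_no_supply(self, bell_season, params):
        inf = infer_supply_for_production(bell_season, params, 0)
        assert inf.supply == 0.0
        assert inf.attained

    def test_round_trip_through_simulator(self, bell_season, params):
        target = simulate_season(bell_season, params, 2.0).production
        inf = infer_supply_for_production(bell_season, params, target)
        assert inf.attained
        assert simulate_season(bell_season, params, inf.supply).production == target
        assert inf.supply <= 2.0 + 1e-3   # smallest sufficient supply

    def test_random_round_trips(self, params):
        rng = np.random.default_rng(9)
        seasons = gen_growth_series(FixtureConfig(n_years=5, seed=33))
        pairs = [
            (seasons[year], float(rng.uniform(0.8, 3.5)))
            for year in sorted(seasons)
            for _ in range(4)
        ]
        for season, s in pairs:
            target = simulate_season(season, params, s).production
            inf = infer_supply_for_production(season, params, target)
            assert inf.attained, (season.year, s)
            assert (
                simulate_season(season, params, inf.supply).production
                == target
            )

    def test_unattainable_target_flagged(self, short_season, params):
        inf = infer_supply_for_production(short_season, params, 1e6)
        assert not inf.attained
        assert inf.production < 1e6

    def test_non_finite_target_rejected(self, bell_season, params):
        with pytest.raises(ValueError, match="finite"):
            infer_supply_for_production(bell_season, params, float("inf"))


class TestRunMultiYear:
    def test_one_row_per_year_reproducible(self, params):
        series = gen_growth_series(FixtureConfig(n_years=3, seed=4))
        with pytest.warns(UserWarning, match="no previous season"):
            a = run_multi_year(series, params)
        with pytest.warns(UserWarning, match="no previous season"):
            b = run_multi_year(series, params)
        assert len(a) == 3
        assert a.equals(b)

    def test_negative_predicted_supply_warns_and_zeroes(self, params):
        series = gen_growth_series(FixtureConfig(n_years=2, seed=4))
        broke = SupplyRegression(intercept=-5.0, beta_sd=0, beta_median=0,
                                 beta_mad=0, beta_min=0, beta_max=0,
                                 beta_skew_prev=0)
        with pytest.warns(UserWarning, match="nonpositive"):
            out = run_multi_year(series, params, broke)
        assert (out.production == 0).all()
        assert out.nonpositive_supply.all()

    def test_fixture_truth_reproduced_with_known_supplies(self, params):
        from cambium import gen_study_fixture

        fx = gen_study_fixture(FixtureConfig(n_years=5, seed=13))
        out = run_multi_year(
            fx.series_by_year, fx.config.params, supplies=fx.noisy_supplies
        )
        expected = [fx.true_production[y] for y in sorted(fx.series_by_year)]
        assert list(out.production) == expected


class TestSplitGoodness:
    def test_perfect_agreement(self):
        obs = {y: float(10 + (y % 7)) for y in range(1990, 2002)}
        stats = split_goodness(
            obs, obs, (range(1990, 1996), range(1996, 2002))
        )
        assert stats["R2_calibration"] == pytest.approx(1.0)
        assert stats["R2_verification"] == pytest.approx(1.0)
        assert stats["r_overall"] == pytest.approx(1.0)

    def test_shuffled_simulation_near_zero(self):
        rng = np.random.default_rng(8)
        years = list(range(1980, 2020))
        obs = {y: float(v) for y, v in zip(years, rng.normal(20, 4, 40))}
        shuffled = rng.permutation(list(obs.values()))
        sim = {y: float(v) for y, v in zip(years, shuffled)}
        stats = split_goodness(obs, sim, (years[:20], years[20:]))
        assert stats["R2_calibration"] < 0.3
        assert stats["R2_verification"] < 0.3

    def test_toy_vectors_match_hand_computed_r2(self):
        years = [1, 2, 3, 4, 5, 6]
        obs = {y: v for y, v in zip(years, [10.0, 12, 9, 14, 11, 13])}
        sim = {y: v for y, v in zip(years, [11.0, 13, 10, 13, 12, 15])}
        stats = split_goodness(obs, sim, (years[:3], years[3:]))
        for side_years, key in ((years[:3], "R2_calibration"),
                                (years[3:], "R2_verification")):
            o = np.array([obs[y] for y in side_years])
            s = np.array([sim[y] for y in side_years])
            r = np.corrcoef(o, s)[0, 1]
            assert stats[key] == pytest.approx(r * r, rel=1e-12)

    def test_constant_side_names_the_side(self):
        years = list(range(10))
        obs = {y: 5.0 for y in years}
        sim = {y: float(y) for y in years}
        with pytest.raises(ValueError, match="calibration"):
            split_goodness(obs, sim, (years[:5], years[5:]))

    def test_too_few_years_rejected(self):
        obs = {1: 1.0, 2: 2.0, 3: 3.0}
        with pytest.raises(ValueError, match="at least 3"):
            split_goodness(obs, obs, ([1, 2], [3]))


class TestCalibrateAverageSeason:
    def test_targets_already_met_returns_initial(self, bell_season, params,
                                                 bell_supply):
        res = simulate_season(bell_season, params, bell_supply)
        out = calibrate_average_season(
            bell_season, params,
            {"production": res.production,
             "first_division_day": res.first_division_time},
            ["supply"], {"supply": (0.0, 10.0)}, supply=bell_supply,
        )
        assert out.objective == 0.0
        assert out.supply == bell_supply
        assert out.params == params

    def test_free_supply_consistent_with_inference(self, bell_season, params):
        # attainable by construction: a production the simulator itself emits
        target = simulate_season(bell_season, params, 2.0).production
        out = calibrate_average_season(
            bell_season, params, {"production": target},
            ["supply"], {"supply": (0.0, 6.0)}, supply=None, n_grid=61,
        )
        inf = infer_supply_for_production(bell_season, params, target)
        assert out.objective == 0.0
        assert (
            simulate_season(bell_season, params, out.supply).production
            == simulate_season(bell_season, params, inf.supply).production
            == target
        )

    def test_alpha_recovered_from_its_own_target(self, bell_season, params):
        true_alpha = 0.78
        truth = simulate_season(
            bell_season, params.replace(alpha=true_alpha), 3.0
        )
        out = calibrate_average_season(
            bell_season, params, {"production": truth.production},
            ["alpha"], {"alpha": (0.6, 0.95)}, supply=3.0, n_grid=33,
        )
        assert out.objective == 0.0
        assert abs(out.params.alpha - true_alpha) <= 0.05

    def test_missing_bounds_rejected(self, bell_season, params):
        with pytest.raises(ValueError, match="bounds"):
            calibrate_average_season(
                bell_season, params, {"production": 20}, ["alpha"], {},
                supply=3.0,
            )

    def test_fixed_supply_required_when_not_free(self, bell_season, params):
        with pytest.raises(ValueError, match="supply"):
            calibrate_average_season(
                bell_season, params, {"production": 20},
                ["alpha"], {"alpha": (0.6, 0.95)},
            )


class TestFilterSeasons:
    @staticmethod
    def _record():
        years = tuple(range(1963, 2012))
        return StudyRecord(
            years=years,
            observed_production={y: 20.0 for y in years},
            calibration_years=tuple(range(1989, 2012)),
            verification_years=tuple(range(1963, 1988)),
        )

    def test_empty_mask_is_identity(self):
        rec = self._record()
        out = filter_seasons(rec, {})
        assert out.observed_production == rec.observed_production
        assert out.calibration_years == rec.calibration_years

    def test_masked_year_absent_downstream(self):
        out = filter_seasons(self._record(), {1978: "missing data"})
        assert 1978 not in out.observed_production
        assert 1978 not in out.verification_years
        assert out.excluded_years[1978] == "missing data"

    def test_six_removals_leave_43_usable_years(self):
        mask = {
            1978: "cell production not prepared",
            2003: "cell production not prepared",
            1977: "growth discrepancy",
            1988: "growth discrepancy",
            2001: "growth discrepancy",
            2008: "growth discrepancy",
        }
        out = filter_seasons(self._record(), mask)
        assert len(out.observed_production) == 43
        usable = set(out.calibration_years) | set(out.verification_years)
        assert usable.isdisjoint(mask)

    def test_unknown_year_rejected(self):
        with pytest.raises(ValueError, match="1871"):
            filter_seasons(self._record(), {1871: "?"})


class TestLoadExclusionMask:
    def test_yaml_and_json_masks(self, tmp_path):
        from cambium import load_exclusion_mask

        ypath = tmp_path / "mask.yaml"
        ypath.write_text("1978: missing data\n2003: missing data\n")
        assert load_exclusion_mask(ypath) == {
            1978: "missing data", 2003: "missing data"
        }
        jpath = tmp_path / "mask.json"
        jpath.write_text('{"1977": "growth discrepancy"}')
        assert load_exclusion_mask(jpath) == {1977: "growth discrepancy"}

    def test_non_mapping_rejected(self, tmp_path):
        from cambium import load_exclusion_mask

        path = tmp_path / "mask.yaml"
        path.write_text("- 1978\n- 2003\n")
        with pytest.raises(ValueError, match="mapping"):
            load_exclusion_mask(path)


class TestLoadObservedProduction:
    def test_round_trip(self, tmp_path):
        path = tmp_path / "prod.csv"
        path.write_text("year,cells\n1990,21\n1991,18\n")
        assert load_observed_production(path) == {1990: 21.0, 1991: 18.0}

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "prod.csv"
        path.write_text("year,count\n1990,21\n")
        with pytest.raises(ValueError, match="cells"):
            load_observed_production(path)
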