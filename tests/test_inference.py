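"""Outlier filtering, log transforms and the seasonal mixed-model suite."""

import numpy as np
import pandas as pd
import pytest

from sociospatial import inference
from sociospatial.inference import (
    assemble_records,
    filter_outliers,
    fit_lmm,
    half_min_positive,
    log_transform,
    run_model_suite,
)


def record(animal, season, kind, value, herd="h1", year="2019"):
    return {
        "animal_id": animal,
        "herd": herd,
        "season": season,
        "year": year,
        "kind": kind,
        "value": value,
    }


class TestFilterOutliers:
    def _records(self, summer_area, winter_area=100.0):
        return pd.DataFrame(
            [
                record("a", "summer", "hr_area_km2", summer_area),
                record("a", "winter", "hr_area_km2", winter_area),
                record("a", "winter", "spatial_strength", 1.0),
                record("b", "summer", "hr_area_km2", 50.0),
            ]
        )

    def test_large_summer_range_drops_animal_everywhere(self):
        out = filter_outliers(self._records(5000.0))
        assert set(out["animal_id"]) == {"b"}

    def test_all_below_threshold_identity(self):
        recs = self._records(300.0)
        pd.testing.assert_frame_equal(filter_outliers(recs), recs)

    def test_winter_only_exceedance_retained(self):
        out = filter_outliers(self._records(300.0, winter_area=9000.0))
        assert set(out["animal_id"]) == {"a", "b"}


class TestLogTransform:
    def test_unit_value_zero_offset(self):
        assert log_transform(1.0) == 0.0

    def test_zero_safe_with_offset(self):
        assert np.isfinite(log_transform(0.0, offset=0.01))

    def test_monotone(self, rng):
        v = rng.uniform(0, 5, 50)
        out = log_transform(np.sort(v), offset=0.1)
        assert (np.diff(out) >= 0).all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform(-1.0)

    def test_half_min_positive_offset(self):
        assert half_min_positive([0.0, 0.4, 2.0]) == 0.2
        assert half_min_positive([0.0, 0.0]) == 0.0


def balanced_two_season(delta, n=24, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        for season, base in (("summer", 0.0), ("winter", delta)):
            rows.append(
                {
                    "animal_id": f"a{i}",
                    "herd": f"h{i % 2}",
                    "season": season,
                    "year": str(2019 + i % 2),
                    "value": base + rng.normal(0, noise) if noise else base + 0.01 * i,
                }
            )
    return pd.DataFrame(rows)


class TestFitLmm:
    def test_matches_ols_when_no_grouping_variance(self):
        """With balanced seasons and no animal/herd/year structure the REML
        fit collapses to OLS: season beta = difference of season means."""
        data = balanced_two_season(delta=1.5)
        fit = fit_lmm(data, "value ~ season")
        diff = (
            data[data.season == "winter"]["value"].mean()
            - data[data.season == "summer"]["value"].mean()
        )
        assert fit.coef("season[T.winter]") == pytest.approx(diff, abs=1e-4)

    def test_intercept_equivariance_under_shift(self):
        data = balanced_two_season(delta=1.0, noise=0.3, seed=5)
        fit0 = fit_lmm(data, "value ~ season")
        shifted = data.assign(value=data["value"] + 10.0)
        fit1 = fit_lmm(shifted, "value ~ season")
        assert fit1.coef("Intercept") == pytest.approx(fit0.coef("Intercept") + 10.0, abs=1e-3)
        assert fit1.coef("season[T.winter]") == pytest.approx(
            fit0.coef("season[T.winter]"), abs=1e-3
        )

    def test_null_season_effect_rarely_flagged(self):
        """Zero true season effect: |beta| < 2 SE in >= 90 % of seeded runs."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            data = balanced_two_season(delta=0.0, n=24, noise=1.0, seed=seed)
            fit = fit_lmm(data, "value ~ season")
            beta = fit.coefficients.loc["season[T.winter]"]
            hits += abs(beta["estimate"]) < 2 * beta["se"]
        assert hits >= 0.9 * n_runs

    def test_reports_variance_components(self):
        data = balanced_two_season(delta=1.0, noise=0.3, seed=2)
        fit = fit_lmm(data, "value ~ season")
        assert "residual" in fit.variance_components
        assert fit.variance_components["residual"] > 0


def synthetic_records(seed=0, winter_effect=True):
    """Record table with a known seasonal structure for suite-level checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for h in ("h1", "h2"):
        for i in range(8):
            animal = f"{h}-{i}"
            for year in ("2019", "2020"):
                for season in ("summer", "winter"):
                    w = season == "winter" and winter_effect
                    soc = rng.lognormal(0 if w else -3, 0.3)
                    rows += [
                        record(animal, season, "social_strength_observed", soc, h, year),
                        record(
                            animal,
                            season,
                            "social_strength_null_mean",
                            soc * (0.3 if w else 1.0) * rng.lognormal(0, 0.1),
                            h,
                            year,
                        ),
                        record(
                            animal, season, "spatial_strength",
                            rng.lognormal(1 if w else -1, 0.3), h, year,
                        ),
                        record(
                            animal, season, "hr_area_km2",
                            rng.lognormal(5 if w else 4, 0.4), h, year,
                        ),
                    ]
            rows.append(
                record(
                    animal,
                    "winter" if False else "summer",
                    "fidelity_udoi",
                    rng.lognormal(0 if winter_effect else -1, 0.2),
                    h,
                    "2019-2020",
                )
            )
            rows.append(
                record(
                    animal, "winter", "fidelity_udoi",
                    rng.lognormal(-2 if winter_effect else -1, 0.2), h, "2019-2020",
                )
            )
    return pd.DataFrame(rows)


class TestRunModelSuite:
    def test_recovers_seasonal_directions(self):
        fits = run_model_suite(synthetic_records(seed=3))
        assert fits["fidelity"].coef("season[T.winter]") < 0
        assert fits["spatial_strength"].coef("season[T.winter]") > 0
        assert fits["social_strength"].coef("season[T.winter]") > 0
        # null-mean strengths fall short of observed only in winter
        assert fits["social_strength"].coef("season[T.winter]:source[T.random]") < 0
        assert set(fits) == {"fidelity", "spatial_strength", "social_strength", "hr_area"}

    def test_interaction_near_zero_without_effect(self):
        fits = run_model_suite(synthetic_records(seed=4, winter_effect=False))
        term = fits["social_strength"].coefficients.loc["season[T.winter]:source[T.random]"]
        assert abs(term["estimate"]) < 2 * term["se"]

    def test_missing_response_named_error(self):
        records = synthetic_records(seed=1)
        no_fid = records[records["kind"] != "fidelity_udoi"]
        with pytest.raises(ValueError, match="fidelity_udoi"):
            run_model_suite(no_fid)

    def test_social_model_pairing_is_one_to_one(self):
        records = synthetic_records(seed=2)
        obs = records[records["kind"] == "social_strength_observed"]
        nul = records[records["kind"] == "social_strength_null_mean"]
        key = ["animal_id", "herd", "season", "year"]
        assert len(obs) == len(nul)
        assert obs[key].sort_values(key).reset_index(drop=True).equals(
            nul[key].sort_values(key).reset_index(drop=True)
        )


class TestAssembleRecords:
    def test_stacks_all_kinds(self):
        social_summary = pd.DataFrame(
            [
                {
                    "animal_id": "a", "herd": "h", "season": "winter", "year": 2019,
                    "strength": 0.5, "null_mean": 0.1, "null_lo": 0.0, "null_hi": 0.2,
                }
            ]
        )
        spatial = pd.DataFrame(
            [{"animal_id": "a", "herd": "h", "season": "winter", "year": 2019, "strength": 1.2}]
        )
        hr = pd.DataFrame(
            [{"animal_id": "a", "herd": "h", "season": "winter", "year": 2019, "hr_area_km2": 40.0}]
        )
        fid = pd.DataFrame(
            [{"animal_id": "a", "herd": "h", "season": "winter", "year_pair": "2019-2020", "udoi": 0.3}]
        )
        recs = assemble_records(social_summary, spatial, hr, fid)
        assert sorted(recs["kind"].unique()) == sorted(inference.RESPONSE_KINDS)
        assert len(recs) == 5
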