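import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import epiperf as ep
from epiperf.qc_conversions import (
    DEFAULT_SPECS,
    PredictorSpec,
    build_analysis_set,
    spec_by_name,
    validate_spec_set,
)

from conftest import make_clean_config


class TestPredictorSpecs:
    def test_default_set_valid(self):
        validate_spec_set(DEFAULT_SPECS)
        assert len(DEFAULT_SPECS) == 15

    def test_uses_age_exactly_for_clocks(self):
        clocks = [s for s in DEFAULT_SPECS if s.uses_age]
        assert sorted(s.name for s in clocks) == sorted(
            ["horvath", "hannum", "skin_blood", "lin", "weidner", "vidal_bralo", "zhang"]
        )

    def test_exponentiate_restricted(self):
        with pytest.raises(ValueError):
            PredictorSpec(
                name="b2m",
                prediction_column="dnam_b2m",
                phenotype_column="b2m_mg_l",
                prediction_transform="exponentiate",
                family="protein",
            )

    def test_ts_to_kbp_restricted(self):
        with pytest.raises(ValueError):
            PredictorSpec(
                name="b2m",
                prediction_column="x",
                phenotype_column="y",
                phenotype_transform="ts_to_kbp",
                family="protein",
            )


class TestSexMismatch:
    def test_synthetic_default_count(self, default_population):
        kept, report = ep.exclude_sex_mismatch(default_population)
        assert report.counts["sex_mismatch"] == 60
        assert len(kept) == len(default_population) - 60
        assert (kept["sex"] == kept["dnam_predicted_sex"]).all()

    def test_all_concordant(self):
        df = pd.DataFrame({"sex": ["male", "female"], "dnam_predicted_sex": ["male", "female"]})
        kept, report = ep.exclude_sex_mismatch(df)
        assert report.counts["sex_mismatch"] == 0
        assert len(kept) == 2

    def test_all_mismatched_warns(self):
        df = pd.DataFrame({"sex": ["male"] * 3, "dnam_predicted_sex": ["female"] * 3})
        with pytest.warns(UserWarning, match="all rows removed"):
            kept, _ = ep.exclude_sex_mismatch(df)
        assert len(kept) == 0

    def test_missing_column_errors(self):
        with pytest.raises(ValueError, match="dnam_predicted_sex"):
            ep.exclude_sex_mismatch(pd.DataFrame({"sex": ["male"]}))


class TestTopcodedAge:
    def test_synthetic_default_count(self, clean_population):
        kept, report = ep.exclude_topcoded_age(clean_population)
        # defect sites are disjoint, so all 126 top-coded rows survive sex QC
        assert report.counts["topcoded_age"] == 126
        assert (kept["age_years"] < 85).all()

    def test_no_topcoding(self):
        df = pd.DataFrame({"age_years": [50.0, 60.0], "age_topcoded": [False, False]})
        kept, report = ep.exclude_topcoded_age(df)
        assert report.counts["topcoded_age"] == 0
        assert len(kept) == 2

    def test_rule_not_applied_for_dnamtl(self, clean_population):
        aset = build_analysis_set(clean_population, spec_by_name("dnamtl"))
        assert "topcoded_age" not in aset.report.counts


class TestTsToKbp:
    def test_intercept(self):
        assert ep.ts_to_kbp(0.0) == pytest.approx(3.274)

    def test_unit_ratio(self):
        # (3274 + 2413 * 1) / 1000
        assert ep.ts_to_kbp(1.0) == pytest.approx(5.687)

    def test_two(self):
        assert ep.ts_to_kbp(2.0) == pytest.approx(8.100)

    def test_missing_propagates(self):
        out = ep.ts_to_kbp(np.array([1.0, np.nan]))
        assert math.isnan(out[1]) and out[0] == pytest.approx(5.687)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ep.ts_to_kbp(-0.1)

    @given(
        st.floats(0, 10, allow_nan=False),
        st.floats(0, 10, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_affine_identity(self, a, b):
        lhs = ep.ts_to_kbp(a) - ep.ts_to_kbp(b)
        assert lhs == pytest.approx(2.413 * (a - b), abs=1e-12)


class TestAggregateLymphocytes:
    def test_zeros(self):
        assert ep.aggregate_lymphocytes(0.0, 0.0, 0.0) == 0.0

    def test_sum(self):
        assert ep.aggregate_lymphocytes(0.1, 0.2, 0.15) == pytest.approx(0.45)

    def test_over_one_warns(self):
        with pytest.warns(UserWarning, match="exceeds 1"):
            total = ep.aggregate_lymphocytes(0.5, 0.5, 0.5)
        assert total == pytest.approx(1.5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ep.aggregate_lymphocytes(1.2, 0.1, 0.1)

    def test_missing_propagates(self):
        out = ep.aggregate_lymphocytes(np.array([0.1, np.nan]), np.array([0.1, 0.1]), np.array([0.1, 0.1]))
        assert math.isnan(out[1])


def brute_log_outliers(values, k=3.0):
    """Explicit-loop oracle recomputing the log mean/SD and the >= k rule."""
    logs = [math.log(v) for v in values if not math.isnan(v) and v > 0]
    n = len(logs)
    mu = sum(logs) / n
    sd = math.sqrt(sum((l - mu) ** 2 for l in logs) / (n - 1))
    flagged = []
    for i, v in enumerate(values):
        if not math.isnan(v) and v > 0 and sd > 0 and abs(math.log(v) - mu) / sd >= k:
            flagged.append(i)
    return flagged


class TestFilterLogOutliers:
    def test_all_equal_removes_nothing(self):
        res = ep.filter_log_outliers(np.full(10, 3.5))
        assert res.n_outlier == 0
        assert res.keep.all()

    def test_injected_five_sd_points(self):
        rng = np.random.default_rng(0)
        base = np.exp(rng.standard_normal(1000) * 0.3)
        spiked = np.concatenate([base, np.exp([5 * 0.3 * 6] * 5)])  # far out on log scale
        res = ep.filter_log_outliers(spiked)
        assert res.n_outlier == 5
        assert set(np.flatnonzero(res.outlier_mask)) == set(brute_log_outliers(spiked))

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.exp(rng.standard_normal(10_000) * rng.uniform(0.1, 1.0))
        v[rng.integers(0, v.size, 20)] = np.nan
        res = ep.filter_log_outliers(v, nonpositive="exclude")
        assert sorted(np.flatnonzero(res.outlier_mask)) == brute_log_outliers(v)
        assert res.n_missing == int(np.isnan(v).sum())

    def test_missing_counted_separately(self):
        v = np.array([1.0, 2.0, np.nan, 3.0])
        res = ep.filter_log_outliers(v)
        assert res.n_missing == 1
        assert not res.keep[2]

    def test_nonpositive_error_default(self):
        with pytest.raises(ValueError, match="non-positive"):
            ep.filter_log_outliers(np.array([1.0, 0.0, 2.0]))

    def test_nonpositive_exclude_policy(self):
        res = ep.filter_log_outliers(np.array([1.0, 0.0, 2.0]), nonpositive="exclude")
        assert res.n_nonpositive == 1
        assert not res.keep[1]

    def test_inclusive_boundary(self):
        # construct a vector whose extreme value sits exactly at k sample SDs
        v = np.array([math.exp(-1), math.exp(0), math.exp(1)])
        logs = np.log(v)
        k = abs(logs[2] - logs.mean()) / logs.std(ddof=1)
        res = ep.filter_log_outliers(v, k=k)
        assert res.n_outlier >= 1  # >= comparison is inclusive


class TestExponentiatePredictions:
    def test_zero_maps_to_one(self):
        spec = spec_by_name("crp")
        df = pd.DataFrame({"dnam_log_crp": [0.0]})
        out = ep.exponentiate_predictions(df, spec)
        assert out["dnam_log_crp"].iloc[0] == pytest.approx(1.0)

    def test_roundtrip(self):
        spec = spec_by_name("hba1c")
        df = pd.DataFrame({"dnam_log_hba1c": [np.log(3.2)]})
        out = ep.exponentiate_predictions(df, spec)
        assert out["dnam_log_hba1c"].iloc[0] == pytest.approx(3.2, rel=1e-12)

    def test_identity_spec_unchanged(self):
        spec = spec_by_name("b2m")
        df = pd.DataFrame({"dnam_b2m": [1.5]})
        out = ep.exponentiate_predictions(df, spec)
        assert out is df


class TestBuildAnalysisSet:
    def test_cystatin_counts(self, clean_population):
        aset = build_analysis_set(clean_population, spec_by_name("cystatin_c"))
        assert aset.report.counts["missing_phenotype"] == 28
        assert aset.report.counts["outlier"] == 39

    def test_clock_excludes_topcoded(self, clean_population):
        aset = build_analysis_set(clean_population, spec_by_name("zhang"))
        assert aset.report.counts["topcoded_age"] == 126
        assert "outlier" not in aset.report.counts  # age is not a lab measure

    def test_clean_table_all_zero(self):
        cfg = make_clean_config(seed=8, predictors=("hannum",))
        df = ep.simulate_population(cfg)
        clean, _ = ep.apply_global_qc(df)
        aset = build_analysis_set(clean, spec_by_name("hannum"))
        assert sum(aset.report.counts.values()) == 0
        assert aset.report.n_out == len(clean)

    def test_composition_audit(self, clean_population):
        for name in ("hannum", "dnamtl", "cystatin_c", "lymphocytes"):
            aset = build_analysis_set(clean_population, spec_by_name(name))
            assert aset.report.n_in == aset.report.n_out + aset.report.n_removed_distinct

    def test_order_invariance(self, clean_population):
        shuffled = clean_population.sample(frac=1.0, random_state=5)
        a = build_analysis_set(clean_population, spec_by_name("cystatin_c"))
        b = build_analysis_set(shuffled, spec_by_name("cystatin_c"))
        assert a.report.counts == b.report.counts
        assert sorted(a.frame["id"]) == sorted(b.frame["id"])

    def test_ts_conversion_applied(self, clean_population):
        aset = build_analysis_set(clean_population, spec_by_name("dnamtl"))
        kept_ids = aset.frame["id"]
        raw = clean_population.set_index("id").loc[kept_ids, "telomere_ts_ratio"]
        np.testing.assert_allclose(aset.phenotype, (3274 + 2413 * raw.to_numpy()) / 1000)

    def test_lymphocyte_prediction_is_component_sum(self, clean_population):
        aset = build_analysis_set(clean_population, spec_by_name("lymphocytes"))
        kept = clean_population.set_index("id").loc[aset.frame["id"]]
        expected = (kept["dnam_b"] + kept["dnam_cd4t"] + kept["dnam_cd8t"]).to_numpy()
        np.testing.assert_allclose(aset.prediction, expected)

    def test_crp_prediction_exponentiated(self, clean_population):
        aset = build_analysis_set(clean_population, spec_by_name("crp"))
        kept = clean_population.set_index("id").loc[aset.frame["id"]]
        np.testing.assert_allclose(
            aset.prediction, np.exp(kept["dnam_log_crp"].to_numpy()), rtol=1e-12
        )

    def test_tiny_stratum_flagged(self):
        cfg = make_clean_config(
            seed=2, group_sizes={"NH White": 50, "NH Black": 2}, predictors=("hannum",)
        )
        df = ep.simulate_population(cfg)
        clean, _ = ep.apply_global_qc(df)
        with pytest.warns(UserWarning, match="fewer than"):
            aset = build_analysis_set(clean, spec_by_name("hannum"))
        assert "NH Black" in aset.report.unanalysable_strata
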