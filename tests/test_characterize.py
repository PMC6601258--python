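"""County labelling, covariate pruning, stepwise logistic regression,
provider extraction and profiling."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from graphscan import (
    Cluster,
    label_counties,
    prune_correlated,
    provider_profile,
    stepwise_aic_logistic,
    top_decile_providers,
)
from graphscan.characterize import (
    COVARIATE_COLUMNS,
    PROVIDER_COLUMNS,
    CharacterizationError,
    SeparationError,
    validate_covariates,
    validate_providers,
)
from graphscan.statistics import ScoreValue


def _cluster(members, score=5.0, p=0.01):
    return Cluster(
        members=tuple(sorted(members)),
        score=ScoreValue(score, score > 0),
        statistic="kulldorff_poisson",
        count_kind="claims",
        year=2015,
        p_value=p,
        significant=True,
    )


class TestLabels:
    def test_no_clusters_all_zero(self):
        labels = label_counties(["A", "B", "C"], [])
        assert labels.sum() == 0

    def test_cluster_members_labelled_one(self):
        roster = [f"n{i}" for i in range(20)]
        labels = label_counties(roster, [_cluster(roster[3:8])])
        assert labels.sum() == 5
        assert labels.loc[roster[3:8]].all()

    def test_disjoint_clusters_union_size(self):
        roster = [f"n{i}" for i in range(20)]
        labels = label_counties(roster, [_cluster(roster[:4]), _cluster(roster[10:13])])
        assert labels.sum() == 7

    def test_member_outside_roster_is_error(self):
        with pytest.raises(CharacterizationError, match="roster"):
            label_counties(["A"], [_cluster(["A", "Z"])])


class TestPrune:
    @staticmethod
    def _frame(columns):
        return pd.DataFrame(columns, index=[f"c{i}" for i in range(len(next(iter(columns.values()))))])

    def test_identical_column_dropped(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        df = self._frame({"a": x, "b": x.copy(), "c": rng.normal(size=100)})
        out = prune_correlated(df, 0.6)
        assert list(out.columns) == ["a", "c"]

    def test_orthogonal_columns_all_kept(self):
        rng = np.random.default_rng(1)
        df = self._frame({k: rng.normal(size=200) for k in "abcd"})
        assert list(prune_correlated(df, 0.6).columns) == list("abcd")

    def test_constructed_correlations_straddling_threshold(self):
        rng = np.random.default_rng(2)
        n = 2000
        z = rng.normal(size=n)
        # corr(a,b) ~ 0.9 (>=0.6, b dropped); corr(a,c) ~ 0.3 (kept);
        # d constructed from c with corr ~ 0.75 (dropped against c)
        a = z
        b = 0.9 * z + np.sqrt(1 - 0.81) * rng.normal(size=n)
        c = 0.3 * z + np.sqrt(1 - 0.09) * rng.normal(size=n)
        d = 0.75 * c + np.sqrt(1 - 0.5625) * rng.normal(size=n)
        df = self._frame({"a": a, "b": b, "c": c, "d": d})
        out = prune_correlated(df, 0.6)
        corr = out.corr().to_numpy()
        off_diag = corr[~np.eye(len(out.columns), dtype=bool)]
        assert np.all(np.abs(off_diag) < 0.6)
        assert "a" in out.columns and "b" not in out.columns

    def test_zero_variance_dropped_with_warning(self, caplog):
        rng = np.random.default_rng(3)
        df = self._frame({"a": np.ones(50), "b": rng.normal(size=50)})
        with caplog.at_level("WARNING"):
            out = prune_correlated(df, 0.6)
        assert list(out.columns) == ["b"]
        assert "zero variance" in caplog.text


class TestStepwise:
    def test_single_class_labels_rejected(self):
        rng = np.random.default_rng(4)
        cov = pd.DataFrame({"x": rng.normal(size=50)}, index=[f"c{i}" for i in range(50)])
        labels = pd.Series(0, index=cov.index)
        with pytest.raises(CharacterizationError, match="single-class"):
            stepwise_aic_logistic(labels, cov)

    def test_separating_covariate_raises(self):
        idx = [f"c{i}" for i in range(60)]
        x = np.r_[np.zeros(30), np.ones(30)]
        cov = pd.DataFrame({"x": x}, index=idx)
        labels = pd.Series((x > 0).astype(int), index=idx)
        with pytest.raises(SeparationError):
            stepwise_aic_logistic(labels, cov)

    def test_noise_inclusion_rate_matches_aic_penalty(self):
        """With AIC's 2-per-parameter penalty, a pure-noise covariate enters
        the selected model with probability ~ P(chi2_1 > 2) ~ 0.157."""
        rng = np.random.default_rng(5)
        k, n, sims = 4, 200, 40
        included = total = 0
        for _ in range(sims):
            cov = pd.DataFrame(
                rng.normal(size=(n, k)),
                columns=[f"v{i}" for i in range(k)],
                index=[f"c{i}" for i in range(n)],
            )
            labels = pd.Series(rng.integers(0, 2, n), index=cov.index)
            res = stepwise_aic_logistic(labels, cov)
            included += len(res.selected_variables)
            total += k
        rate = included / total
        # binomial 99% band around 0.157 with 160 trials
        assert 0.07 < rate < 0.25

    def test_strong_effect_recovered_and_matches_exhaustive_aic(self):
        rng = np.random.default_rng(6)
        n, k = 400, 4
        X = rng.normal(size=(n, k))
        beta = np.array([0.9, 0.0, 0.0, 0.0])
        p = 1 / (1 + np.exp(-(X @ beta - 0.5)))
        y = (rng.uniform(size=n) < p).astype(int)
        cov = pd.DataFrame(X, columns=[f"v{i}" for i in range(k)],
                           index=[f"c{i}" for i in range(n)])
        labels = pd.Series(y, index=cov.index)
        res = stepwise_aic_logistic(labels, cov)
        assert "v0" in res.selected_variables
        assert res.p_values["v0"] < 0.1
        # exhaustive AIC over all subsets
        best_aic = np.inf
        for r in range(k + 1):
            for subset in itertools.combinations(cov.columns, r):
                Xs = sm.add_constant(cov[list(subset)], has_constant="add")
                aic = sm.Logit(labels.to_numpy(float), Xs).fit(disp=0).aic
                best_aic = min(best_aic, aic)
        assert res.aic == pytest.approx(best_aic, abs=1e-6)

    def test_result_aic_not_worse_than_full_or_null(self):
        rng = np.random.default_rng(7)
        n, k = 300, 5
        cov = pd.DataFrame(rng.normal(size=(n, k)),
                           columns=[f"v{i}" for i in range(k)],
                           index=[f"c{i}" for i in range(n)])
        labels = pd.Series(rng.integers(0, 2, n), index=cov.index)
        res = stepwise_aic_logistic(labels, cov)
        full = sm.Logit(labels.to_numpy(float),
                        sm.add_constant(cov, has_constant="add")).fit(disp=0).aic
        null = sm.Logit(labels.to_numpy(float),
                        np.ones((n, 1))).fit(disp=0).aic
        assert res.aic <= full + 1e-9
        assert res.aic <= null + 1e-9


class TestProviders:
    @staticmethod
    def _providers(ob, op, county="A", specialty="Family Practice"):
        n = len(ob)
        return pd.DataFrame(
            {
                "provider_id": [f"P{i}" for i in range(n)],
                "county": county,
                "specialty": specialty,
                "total_beneficiaries": [max(o * 5, 10) for o in ob],
                "opioid_beneficiaries": ob,
                "total_claims": [max(o * 5, 10) for o in op],
                "opioid_claims": op,
            }
        )

    def test_strictly_increasing_counts_select_top_provider(self):
        df = self._providers(list(range(1, 11)), list(range(1, 11)))
        out = top_decile_providers(df, _cluster(["A"]))
        assert list(out["provider_id"]) == ["P9"]

    def test_top_in_one_axis_only_excluded(self):
        ob = [1, 2, 3, 4, 5, 6, 7, 8, 9, 100]
        op = [100, 2, 3, 4, 5, 6, 7, 8, 9, 1]
        df = self._providers(ob, op)
        out = top_decile_providers(df, _cluster(["A"]))
        assert out.empty

    def test_all_tied_all_retained(self):
        df = self._providers([5] * 8, [7] * 8)
        out = top_decile_providers(df, _cluster(["A"]))
        assert len(out) == 8

    def test_idempotent(self):
        rng = np.random.default_rng(8)
        df = self._providers(list(rng.integers(0, 50, 30)), list(rng.integers(0, 50, 30)))
        once = top_decile_providers(df, _cluster(["A"]))
        twice = top_decile_providers(once, _cluster(["A"]))
        pd.testing.assert_frame_equal(once, twice)

    def test_providers_outside_cluster_excluded(self, caplog):
        df = self._providers([10, 20], [10, 20], county="Z")
        with caplog.at_level("WARNING"):
            out = top_decile_providers(df, _cluster(["A"]))
        assert out.empty

    def test_profile_single_provider(self):
        df = pd.DataFrame(
            {
                "provider_id": ["P0"], "county": ["A"], "specialty": ["Dentist"],
                "total_beneficiaries": [100], "opioid_beneficiaries": [20],
                "total_claims": [200], "opioid_claims": [50],
            }
        )
        prof = provider_profile(df)
        assert prof.loc[0, "mean_pct_opioid_beneficiaries"] == pytest.approx(20.0)
        assert prof.loc[0, "mean_pct_opioid_claims"] == pytest.approx(25.0)

    def test_profile_mean_over_same_specialty(self):
        df = pd.DataFrame(
            {
                "provider_id": ["P0", "P1"], "county": "A", "specialty": "Dentist",
                "total_beneficiaries": [100, 100], "opioid_beneficiaries": [10, 30],
                "total_claims": [100, 100], "opioid_claims": [10, 30],
            }
        )
        prof = provider_profile(df)
        assert prof.loc[0, "mean_pct_opioid_beneficiaries"] == pytest.approx(20.0)

    def test_profile_empty_input_error(self):
        with pytest.raises(CharacterizationError):
            provider_profile(pd.DataFrame(columns=list(PROVIDER_COLUMNS)))

    def test_zero_total_provider_excluded_with_warning(self, caplog):
        df = pd.DataFrame(
            {
                "provider_id": ["P0", "P1"], "county": "A", "specialty": "Dentist",
                "total_beneficiaries": [0, 100], "opioid_beneficiaries": [0, 30],
                "total_claims": [0, 100], "opioid_claims": [0, 30],
            }
        )
        with caplog.at_level("WARNING"):
            prof = provider_profile(df)
        assert prof.loc[0, "n_providers"] == 1
        assert "zero totals" in caplog.text

    def test_sorted_by_provider_count(self):
        df = pd.DataFrame(
            {
                "provider_id": [f"P{i}" for i in range(5)],
                "county": "A",
                "specialty": ["X", "Y", "Y", "Y", "X"],
                "total_beneficiaries": 100, "opioid_beneficiaries": 10,
                "total_claims": 100, "opioid_claims": 10,
            }
        )
        prof = provider_profile(df)
        assert list(prof["specialty"]) == ["Y", "X"]
        assert list(prof["n_providers"]) == [3, 2]


class TestValidators:
    def test_covariate_percentages_bounded(self):
        df = pd.DataFrame(
            {c: [50.0, 60.0] for c in COVARIATE_COLUMNS},
            index=pd.Index(["A", "B"], name="county"),
        )
        df.loc["A", "pct_male"] = 101.0
        with pytest.raises(CharacterizationError, match="percentage"):
            validate_covariates(df)

    def test_provider_opioid_exceeding_total_rejected(self):
        df = pd.DataFrame(
            {
                "provider_id": ["P0"], "county": ["A"], "specialty": ["X"],
                "total_beneficiaries": [10], "opioid_beneficiaries": [20],
                "total_claims": [10], "opioid_claims": [1],
            }
        )
        with pytest.raises(CharacterizationError, match="exceed"):
            validate_providers(df)
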