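import math

import numpy as np
import pandas as pd
import pytest

from icudce.config import column_names
from icudce.design import PatientProfile, profile_vector
from icudce.errors import (
    ConvergenceError,
    DataError,
    EstimationError,
    SeparationError,
)
from icudce.estimation import (
    CodedData,
    code_dataset,
    decode_rows,
    fit_from_json,
    fit_logit,
    fit_to_json,
    level_contrasts,
    odds_ratios,
    predict_admission,
)
from icudce.synthetic import (
    intercept_only_theta,
    responses_frame,
    simulate_respondents,
    simulate_responses,
)


@pytest.fixture(scope="module")
def sim_frame(study_design, single_class_population):
    resp = simulate_respondents(
        60,
        single_class_population,
        intercept_only_theta(single_class_population),
        seed=31,
    )
    records = simulate_responses(
        resp, study_design, single_class_population, seed=31
    )
    return responses_frame(records, study_design)


class TestCoding:
    def test_admit_column_count(self, sim_frame, attributes):
        coded = code_dataset(sim_frame, attributes, model="admit")
        # 1 + sum over attributes of (levels - 1) for the default configuration
        assert coded.X.shape[1] == 15
        assert coded.columns == column_names(attributes, intercept=True)

    def test_quality_tasks_excluded_by_default(self, sim_frame, attributes):
        coded = code_dataset(sim_frame, attributes, model="admit")
        n_std_rows = (sim_frame["task_type"] == "standard").sum()
        assert coded.X.shape[0] == n_std_rows

    def test_priority_difference_coding(self, sim_frame, attributes, study_design):
        coded = code_dataset(sim_frame, attributes, model="priority")
        assert coded.columns == column_names(attributes, intercept=False)
        # spot-check one row against hand-computed difference
        rid = coded.cluster_ids[0]
        rows = sim_frame[
            (sim_frame["respondent_id"] == rid) & (sim_frame["task_type"] == "standard")
        ]
        tid = sorted(rows["task_id"].unique())[0]
        task = study_design.task(tid)
        expected = profile_vector(task.profile_a, attributes) - profile_vector(
            task.profile_b, attributes
        )
        np.testing.assert_allclose(coded.X[0], expected)

    def test_identical_profiles_give_zero_priority_row(self, attributes):
        base = {a.name: a.reference for a in attributes}
        rows = []
        for alt in ("A", "B"):
            row = dict(base)
            row.update(
                respondent_id=1, task_id=1, block_id=1, alternative=alt,
                task_type="standard", repeat_of="", admit=1,
                priority_chosen=int(alt == "A"), response_time_ms=5000,
            )
            rows.append(row)
        frame = pd.DataFrame(rows)
        coded = code_dataset(frame, attributes, model="priority")
        assert (coded.X == 0).all()

    def test_reference_profile_is_intercept_only(self, attributes):
        base = {a.name: a.reference for a in attributes}
        row = dict(base)
        row.update(
            respondent_id=1, task_id=1, block_id=1, alternative="A",
            task_type="standard", repeat_of="", admit=1,
            priority_chosen=1, response_time_ms=5000,
        )
        coded = code_dataset(pd.DataFrame([row]), attributes, model="admit")
        assert coded.X[0, 0] == 1.0
        assert (coded.X[0, 1:] == 0).all()

    def test_unknown_level_errors(self, sim_frame, attributes):
        broken = sim_frame.copy()
        std_idx = broken.index[broken["task_type"] == "standard"][0]
        broken.loc[std_idx, "age"] = "unheard-of"
        with pytest.raises(DataError, match="age"):
            code_dataset(broken, attributes, model="admit")

    def test_decode_roundtrip(self, sim_frame, attributes):
        coded = code_dataset(sim_frame, attributes, model="admit")
        decoded = decode_rows(coded.X, coded.columns, attributes)
        original = sim_frame[sim_frame["task_type"] == "standard"].reset_index()
        for a in attributes:
            assert (decoded[a.name] == original[a.name]).all()


def _toy_coded(y, x):
    y = np.asarray(y, dtype=float)
    X = np.asarray(x, dtype=float).reshape(len(y), -1)
    return CodedData(
        y=y, X=X, cluster_ids=np.arange(len(y)), columns=[f"a:{j}" for j in range(X.shape[1])],
        model="admit",
    )


class TestFitLogit:
    def test_intercept_only_fifty_fifty_is_exact_zero(self):
        coded = CodedData(
            y=np.array([1.0, 0.0] * 5),
            X=np.ones((10, 1)),
            cluster_ids=np.arange(10),
            columns=["intercept"],
            model="admit",
        )
        fit = fit_logit(coded)
        assert fit.beta[0] == 0.0
        assert fit.converged

    def test_one_parameter_matches_grid_search_oracle(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=10)
        y = (rng.random(10) < 1 / (1 + np.exp(-1.3 * x))).astype(float)
        coded = _toy_coded(y, x)
        fit = fit_logit(coded, cluster_robust=False)
        # oracle: exhaustive grid over [-10, 10] at step 1e-4
        grid = np.arange(-10.0, 10.0, 1e-4)
        eta = np.outer(grid, x)
        ll = (y * eta - np.logaddexp(0.0, eta)).sum(axis=1)
        best = grid[np.argmax(ll)]
        assert fit.beta[0] == pytest.approx(best, abs=1e-3)

    def test_intercept_only_matches_p_hat_enumeration(self):
        # brute-force: enumerate candidate success probabilities on a tiny sample
        y = np.array([1.0, 0.0, 1.0, 1.0])
        coded = CodedData(
            y=y, X=np.ones((4, 1)), cluster_ids=np.arange(4),
            columns=["intercept"], model="admit",
        )
        fit = fit_logit(coded)
        p_grid = np.arange(0.001, 1.0, 0.001)
        ll = y.sum() * np.log(p_grid) + (len(y) - y.sum()) * np.log(1 - p_grid)
        p_best = p_grid[np.argmax(ll)]
        p_fit = 1 / (1 + math.exp(-fit.beta[0]))
        assert p_fit == pytest.approx(p_best, abs=1e-3)

    def test_parameter_recovery_within_3se(self, attributes, sim_frame, pooled):
        coded = code_dataset(sim_frame, attributes, model="admit")
        fit = fit_logit(coded)
        for j, col in enumerate(fit.columns):
            if col == "intercept":
                continue
            true = pooled.get(col, 0.0)
            se = math.sqrt(fit.vcov[j, j])
            assert abs(fit.beta[j] - true) < 3.5 * se

    def test_loglik_beats_null(self, attributes, sim_frame):
        coded = code_dataset(sim_frame, attributes, model="admit")
        fit = fit_logit(coded, compute_null=True)
        assert fit.loglik >= fit.loglik_null
        assert 2 * (fit.loglik - fit.loglik_null) >= 0

    def test_row_order_invariance(self, attributes, sim_frame):
        coded = code_dataset(sim_frame, attributes, model="admit")
        fit1 = fit_logit(coded)
        rng = np.random.default_rng(0)
        perm = rng.permutation(coded.X.shape[0])
        coded2 = CodedData(
            y=coded.y[perm], X=coded.X[perm], cluster_ids=coded.cluster_ids[perm],
            columns=coded.columns, model="admit",
        )
        fit2 = fit_logit(coded2)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)
        np.testing.assert_allclose(fit1.vcov, fit2.vcov, atol=1e-8)

    def test_alternative_relabel_invariances(self, attributes, sim_frame):
        coded = code_dataset(sim_frame, attributes, model="priority")
        fit = fit_logit(coded)
        # full flip (labels and answers together): substantively invariant
        flipped = sim_frame.copy()
        flipped["alternative"] = flipped["alternative"].map({"A": "B", "B": "A"})
        coded_f = code_dataset(flipped, attributes, model="priority")
        fit_f = fit_logit(coded_f)
        np.testing.assert_allclose(fit.beta, fit_f.beta, atol=1e-6)
        # negating the difference coding alone flips the sign of beta
        coded_neg = CodedData(
            y=coded.y, X=-coded.X, cluster_ids=coded.cluster_ids,
            columns=coded.columns, model="priority",
        )
        fit_neg = fit_logit(coded_neg)
        np.testing.assert_allclose(fit.beta, -fit_neg.beta, atol=1e-6)
        # admit model is unchanged by the relabelling
        fit_a = fit_logit(code_dataset(sim_frame, attributes, model="admit"))
        fit_af = fit_logit(code_dataset(flipped, attributes, model="admit"))
        np.testing.assert_allclose(fit_a.beta, fit_af.beta, atol=1e-8)

    def test_vcov_symmetric_psd(self, attributes, sim_frame):
        fit = fit_logit(code_dataset(sim_frame, attributes, model="admit"))
        np.testing.assert_allclose(fit.vcov, fit.vcov.T)
        assert np.linalg.eigvalsh(fit.vcov).min() > -1e-10

    def test_collinear_columns_error(self):
        X = np.column_stack([np.ones(8), np.ones(8)])
        coded = CodedData(
            y=np.array([0, 1] * 4, dtype=float), X=X,
            cluster_ids=np.arange(8), columns=["intercept", "a:dup"], model="admit",
        )
        with pytest.raises(EstimationError):
            fit_logit(coded)

    def test_perfect_separation_detected(self):
        x = np.array([-2.0, -1.0, -0.5, 0.5, 1.0, 2.0])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logit(_toy_coded(y, x), cluster_robust=False)

    def test_nonconvergence_carries_last_iterate(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(float)
        with pytest.raises(ConvergenceError) as err:
            fit_logit(_toy_coded(y, x), max_iter=1, tol=1e-14)
        assert err.value.last_beta is not None


@pytest.fixture(scope="module")
def admit_fit(attributes, sim_frame):
    return fit_logit(code_dataset(sim_frame, attributes, model="admit"))


class TestOddsRatios:
    @pytest.fixture()
    def fit(self, admit_fit):
        return admit_fit

    def test_zero_contrast(self, fit):
        table = odds_ratios(fit, {"null": np.zeros(len(fit.columns))})
        row = table.iloc[0]
        assert row["or"] == 1.0
        assert row["ci_low"] == 1.0 and row["ci_high"] == 1.0

    def test_known_contrast_arithmetic(self, fit):
        c = np.zeros(len(fit.columns))
        fit2 = fit
        # force a deterministic check: c'beta = ln 6.4 with zero variance
        import copy

        fit2 = copy.deepcopy(fit)
        fit2.beta = np.zeros(len(fit.columns))
        fit2.beta[1] = math.log(6.4)
        fit2.vcov = np.zeros_like(fit2.vcov)
        c[1] = 1.0
        row = odds_ratios(fit2, {"x": c}).iloc[0]
        assert row["or"] == pytest.approx(6.4, rel=1e-12)

    def test_reciprocal_property(self, fit):
        rng = np.random.default_rng(3)
        c = rng.normal(size=len(fit.columns))
        table = odds_ratios(fit, {"c": c, "negc": -c})
        assert table.iloc[0]["or"] * table.iloc[1]["or"] == pytest.approx(1.0, rel=1e-10)

    def test_ci_contains_point(self, fit):
        table = odds_ratios(fit)
        assert ((table["ci_low"] <= table["or"]) & (table["or"] <= table["ci_high"])).all()

    def test_dimension_mismatch(self, fit):
        with pytest.raises(DataError):
            odds_ratios(fit, {"bad": np.zeros(3)})


class TestPredict:
    def test_all_reference_alpha_zero_is_half(self, attributes, sim_frame):
        fit = fit_logit(code_dataset(sim_frame, attributes, model="admit"))
        fit.attributes = attributes
        fit.beta = np.zeros_like(fit.beta)
        profile = PatientProfile.from_dict(
            {a.name: a.reference for a in attributes}, attributes
        )
        assert predict_admission(fit, profile) == 0.5

    def test_age_contrast_or_12(self, attributes, sim_frame):
        fit = fit_logit(code_dataset(sim_frame, attributes, model="admit"))
        fit.attributes = attributes
        fit.beta = np.zeros_like(fit.beta)
        fit.beta[fit.columns.index("age:39 yr")] = math.log(12.0)
        ref = {a.name: a.reference for a in attributes}
        young = dict(ref, age="39 yr")
        p_old = predict_admission(fit, PatientProfile.from_dict(ref, attributes))
        p_young = predict_admission(fit, PatientProfile.from_dict(young, attributes))
        odds_ratio = (p_young / (1 - p_young)) / (p_old / (1 - p_old))
        assert odds_ratio == pytest.approx(12.0, rel=1e-10)

    def test_monotone_in_coefficient(self, attributes, sim_frame):
        fit = fit_logit(code_dataset(sim_frame, attributes, model="admit"))
        fit.attributes = attributes
        prof = PatientProfile.from_dict(
            dict({a.name: a.reference for a in attributes}, age="39 yr"), attributes
        )
        p1 = predict_admission(fit, prof)
        fit.beta[fit.columns.index("age:39 yr")] += 0.5
        assert predict_admission(fit, prof) > p1


class TestSerialization:
    def test_json_roundtrip(self, attributes, sim_frame, tmp_path):
        fit = fit_logit(code_dataset(sim_frame, attributes, model="admit"))
        path = tmp_path / "fit.json"
        fit_to_json(fit, path)
        loaded = fit_from_json(path, attributes)
        np.testing.assert_allclose(loaded.beta, fit.beta)
        np.testing.assert_allclose(loaded.vcov, fit.vcov)
        assert loaded.columns == fit.columns
        assert loaded.loglik == pytest.approx(fit.loglik)
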