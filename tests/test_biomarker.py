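import numpy as np
import pandas as pd
import pytest

from ewaspipe import biomarker
from ewaspipe.biomarker import BiomarkerModel

from _oracles import (
    elastic_net_fista,
    elastic_net_kkt_violation,
    elastic_net_objective,
)


def _cohort(n=80, p=40, seed=0, n_signal=5):
    rng = np.random.default_rng(seed)
    m = pd.DataFrame(rng.uniform(0.05, 0.95, (n, p)),
                     columns=[f"cg{j:05d}" for j in range(p)])
    w = np.zeros(p)
    w[:n_signal] = rng.standard_normal(n_signal)
    y = m.to_numpy() @ w + rng.standard_normal(n) * 0.3
    return m, y


class TestPrefilter:
    def test_identity_when_all_allowed(self):
        m, _ = _cohort()
        out = biomarker.prefilter_sites(m, list(m.columns))
        pd.testing.assert_frame_equal(out, m)

    def test_disjoint_errors(self):
        m, _ = _cohort()
        with pytest.raises(ValueError, match="overlap"):
            biomarker.prefilter_sites(m, ["cgX"])

    def test_partial_overlap(self):
        m, _ = _cohort(p=10)
        allowed = ["cg00001", "cg00003", "cg00007", "cgZZ"]
        out = biomarker.prefilter_sites(m, allowed)
        assert list(out.columns) == ["cg00001", "cg00003", "cg00007"]

    def test_empty_list_errors(self):
        m, _ = _cohort()
        with pytest.raises(ValueError, match="empty"):
            biomarker.prefilter_sites(m, [])


class TestTrainElasticNet:
    def test_huge_lambda_all_zero(self):
        m, y = _cohort()
        model = biomarker.train_elastic_net(m, y, lambda_override=1e6)
        assert len(model.weights) == 0
        assert model.intercept == pytest.approx(np.mean(y))

    def test_zero_penalty_matches_ols_orthonormal(self):
        rng = np.random.default_rng(3)
        n, p = 64, 8
        q, _ = np.linalg.qr(rng.standard_normal((n, n)))
        x = q[:, :p]  # orthonormal columns
        w = rng.standard_normal(p)
        y = x @ w + rng.standard_normal(n) * 0.1
        m = pd.DataFrame(x, columns=[f"cg{j}" for j in range(p)])
        model = biomarker.train_elastic_net(m, y, lambda_override=1e-12,
                                            standardize=False)
        ols, *_ = np.linalg.lstsq(np.column_stack([np.ones(n), x]), y, rcond=None)
        dense = pd.Series(0.0, index=m.columns)
        dense[model.weights.index] = model.weights
        np.testing.assert_allclose(dense.to_numpy(), ols[1:], atol=1e-6)

    def test_kkt_and_objective_vs_fista_oracle(self):
        rng = np.random.default_rng(4)
        n, p = 80, 200
        x = rng.standard_normal((n, p))
        w = np.zeros(p)
        w[:10] = rng.standard_normal(10)
        y = x @ w + rng.standard_normal(n)
        m = pd.DataFrame(x, columns=[f"cg{j}" for j in range(p)])
        lam, alpha = 0.1, 0.5
        model = biomarker.train_elastic_net(m, y, alpha=alpha,
                                            lambda_override=lam,
                                            standardize=False)
        # reconstruct the centered-problem solution the solver worked on
        dense = pd.Series(0.0, index=m.columns)
        dense[model.weights.index] = model.weights
        beta = dense.to_numpy()
        xc = x - x.mean(axis=0)
        yc = y - y.mean()
        assert elastic_net_kkt_violation(xc, yc, beta, lam, alpha) < 1e-6
        oracle = elastic_net_fista(xc, yc, lam, alpha)
        obj_model = elastic_net_objective(xc, yc, beta, lam, alpha)
        obj_oracle = elastic_net_objective(xc, yc, oracle, lam, alpha)
        assert obj_model <= obj_oracle + 1e-8

    def test_cv_reproducibility(self):
        m, y = _cohort(n=60, p=30, seed=5)
        m1 = biomarker.train_elastic_net(m, y, seed=42, n_lambda=25)
        m2 = biomarker.train_elastic_net(m, y, seed=42, n_lambda=25)
        assert m1.lambda_selected == m2.lambda_selected
        pd.testing.assert_series_equal(m1.weights, m2.weights)

    def test_sparsity_monotone_along_path(self):
        m, y = _cohort(n=70, p=50, seed=6, n_signal=8)
        lams = np.geomspace(1e-4, 1.0, 12)
        counts = [
            len(biomarker.train_elastic_net(m, y, lambda_override=lam).weights)
            for lam in lams
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_degenerate_response_rejected(self):
        m, _ = _cohort()
        with pytest.raises(ValueError, match="constant"):
            biomarker.train_elastic_net(m, np.ones(len(m)))

    def test_too_few_samples_for_folds(self):
        m, y = _cohort(n=8)
        with pytest.raises(ValueError, match="folds"):
            biomarker.train_elastic_net(m.iloc[:8], y[:8], n_folds=10)

    def test_weights_file_roundtrip(self, tmp_path):
        m, y = _cohort(n=60, p=30, seed=7)
        model = biomarker.train_elastic_net(m, y, seed=1, n_lambda=25)
        path = tmp_path / "weights.tsv"
        model.to_tsv(path)
        back = BiomarkerModel.from_tsv(path)
        assert back.intercept == model.intercept
        np.testing.assert_array_equal(back.weights.to_numpy(),
                                      model.weights.to_numpy())


class TestScore:
    def _model(self, intercept=1.0, weights=None, means=None):
        weights = weights if weights is not None else {"cg1": 2.0}
        means = means if means is not None else {"cg1": 0.25}
        return BiomarkerModel(
            intercept=intercept, weights=pd.Series(weights),
            training_means=pd.Series(means), alpha=0.5,
            lambda_selected=0.1, n_train=10, n_features_prefilter=1,
        )

    def test_simple_projection(self):
        m = pd.DataFrame({"cg1": [0.5]}, index=["s1"])
        assert biomarker.score(self._model(), m).iloc[0] == pytest.approx(2.0)

    def test_missing_site_uses_training_mean(self):
        m = pd.DataFrame({"other": [0.9]}, index=["s1"])
        assert biomarker.score(self._model(), m).iloc[0] == pytest.approx(1.5)

    def test_all_zero_weights_gives_intercept(self):
        model = self._model(weights={}, means={})
        m = pd.DataFrame({"cg1": [0.5, 0.7]}, index=["s1", "s2"])
        out = biomarker.score(model, m)
        assert (out == 1.0).all()

    def test_strict_mode_escalates(self):
        model = BiomarkerModel(
            intercept=0.0,
            weights=pd.Series({"cg1": 1.0, "cg2": 1.0, "cg3": 1.0}),
            training_means=pd.Series({"cg1": 0.1, "cg2": 0.2, "cg3": 0.3}),
            alpha=0.5, lambda_selected=0.1, n_train=10, n_features_prefilter=3,
        )
        m = pd.DataFrame({"cg1": [0.5]}, index=["s1"])
        with pytest.raises(ValueError, match="absent"):
            biomarker.score(model, m, strict=True)
        # non-strict: imputes and warns
        out = biomarker.score(model, m)
        assert out.iloc[0] == pytest.approx(0.5 + 0.2 + 0.3)

    def test_nan_entries_imputed(self):
        m = pd.DataFrame({"cg1": [np.nan]}, index=["s1"])
        assert biomarker.score(self._model(), m).iloc[0] == pytest.approx(1.5)

    def test_model_requires_means_for_weights(self):
        with pytest.raises(ValueError, match="training mean"):
            BiomarkerModel(
                intercept=0.0, weights=pd.Series({"cg1": 1.0}),
                training_means=pd.Series(dtype=float), alpha=0.5,
                lambda_selected=0.1, n_train=5, n_features_prefilter=1,
            )


class TestScoreTransfer:
    def test_multisite_beats_single_site_on_new_cohort(self):
        from ewaspipe import synthetic

        cfg = synthetic.SimulationConfig(
            n_individuals=500, n_cpgs=300, target_h2=0.6, seed=33, n_causal=10,
            covariate_effects={},
        )
        m_train, ph_train, truth = synthetic.simulate_methylation_cohort(cfg)
        y = ph_train["trait"].to_numpy()
        model = biomarker.train_elastic_net(m_train, y, seed=1, n_lambda=30,
                                            path_decades=3.0)
        best_site = m_train.columns[np.argmax(np.abs(truth.effects))]
        single = biomarker.train_single_site(m_train[best_site], y,
                                             site_id=best_site)

        test_cfg = synthetic.SimulationConfig(
            n_individuals=500, n_cpgs=300, target_h2=0.6, seed=33, n_causal=10,
            covariate_effects={}, population_seed=77,
        )
        m_test, _, truth_test = synthetic.simulate_methylation_cohort(test_cfg)
        multi = biomarker.score(model, m_test)
        one = biomarker.score(single, m_test)
        r_multi = np.corrcoef(multi, truth_test.score)[0, 1]
        r_one = np.corrcoef(one, truth_test.score)[0, 1]
        assert r_multi > r_one


class TestSingleSite:
    def test_exact_linear(self):
        m = np.array([0.1, 0.2, 0.3, 0.4])
        model = biomarker.train_single_site(m, 3 * m)
        assert model.weights.iloc[0] == pytest.approx(3.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-12)

    def test_five_point_hand_slope(self):
        m = np.array([0.1, 0.3, 0.4, 0.6, 0.9])
        y = np.array([2.0, 1.0, 3.0, 4.0, 3.5])
        model = biomarker.train_single_site(m, y)
        mx, my = m.mean(), y.mean()
        slope = ((m - mx) * (y - my)).sum() / ((m - mx) ** 2).sum()
        assert model.weights.iloc[0] == pytest.approx(slope, abs=1e-12)
        assert model.intercept == pytest.approx(my - slope * mx, abs=1e-12)

    def test_orthogonal_response_small_weight(self):
        rng = np.random.default_rng(8)
        m = rng.uniform(0, 1, 500)
        y = rng.standard_normal(500)
        model = biomarker.train_single_site(m, y)
        # slope SE ~ sd(y)/ (sd(m) sqrt(n)); allow 3 SE
        se = y.std() / (m.std() * np.sqrt(500))
        assert abs(model.weights.iloc[0]) < 3 * se

    def test_constant_site_rejected(self):
        with pytest.raises(ValueError, match="vary"):
            biomarker.train_single_site(np.full(10, 0.5), np.arange(10.0))
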