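"""The cyclic boosting loop: selection, monotone loss, MLE limits,
prediction and serialization."""

import numpy as np
import pandas as pd
import pytest

import betaboost as bb
from conftest import make_linear_learners


def _intercept_pair(n):
    return [bb.build_intercept(n)], [bb.build_intercept(n)]


class TestFitContract:
    def test_mstop_zero_returns_offsets(self, linear_fixture):
        sample, df, X = linear_fixture
        lmu, lphi = _intercept_pair(sample.n)
        model = bb.boost_fit(sample, lmu, lphi, bb.BoostConfig(m_stop=0))
        assert model.history == []
        mu = model.predict(df, "mu")
        assert np.allclose(mu, mu[0])

    def test_history_bookkeeping(self, linear_fixture):
        sample, df, X = linear_fixture
        lmu = make_linear_learners(X)
        lphi = make_linear_learners(X)
        model = bb.boost_fit(sample, lmu, lphi, bb.BoostConfig(m_stop=25))
        assert len(model.history) == 50  # one mu pick + one phi pick per iteration
        assert [h[1] for h in model.history[:2]] == ["mu", "phi"]

    def test_training_loss_monotone(self, linear_fixture):
        """Each half-step fits a shrunken increment of the current score, so
        the negative log-likelihood never increases along the path."""
        sample, df, X = linear_fixture
        model = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                             bb.BoostConfig(m_stop=150))
        losses = np.array([h[3] for h in model.history])
        assert np.all(np.diff(losses) <= 1e-8)

    def test_empty_learner_set_rejected(self, linear_fixture):
        sample, _, X = linear_fixture
        with pytest.raises(ValueError):
            bb.boost_fit(sample, [], make_linear_learners(X), bb.BoostConfig(m_stop=1))

    def test_determinism(self, linear_fixture):
        sample, df, X = linear_fixture
        runs = []
        for _ in range(2):
            model = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                                 bb.BoostConfig(m_stop=40))
            runs.append(model.history)
        assert runs[0] == runs[1]


class TestMLEConvergence:
    def test_intercept_only_matches_bivariate_mle(self):
        """With only intercept learners the boosting path converges to the
        direct two-parameter maximum-likelihood estimate."""
        n = 500
        state = bb.make_state(np.full(n, bb.betadist.logit(0.3)), np.full(n, np.log(5.0)))
        sample = bb.sample_beta(state, seed=11)
        lmu, lphi = _intercept_pair(n)
        model = bb.boost_fit(sample, lmu, lphi,
                             bb.BoostConfig(m_stop=2000, step_length=0.1, init="zero"))
        d = pd.DataFrame(index=range(1))
        eta0, eta1 = bb.fit_null_beta(sample.values)
        mu_mle = float(bb.betadist.inv_logit(eta0))
        phi_mle = float(np.exp(eta1))
        assert model.predict(d, "mu")[0] == pytest.approx(mu_mle, abs=0.02)
        assert model.predict(d, "phi")[0] == pytest.approx(phi_mle, abs=0.5)

    def test_linear_model_approaches_variable_dispersion_mle(self):
        """Unpenalized linear learners, large m: coefficients approach the
        variable-dispersion beta-regression MLE (direct optimization)."""
        from scipy.optimize import minimize

        rng = np.random.default_rng(3)
        n = 500
        X = rng.normal(0, 1, (n, 3))
        eta_mu = 0.4 + 0.7 * X[:, 0] - 0.5 * X[:, 1]
        eta_phi = 1.0 + 0.4 * X[:, 2]
        sample = bb.sample_beta(bb.make_state(eta_mu, eta_phi), seed=4)

        def nll(theta):
            em = theta[0] + X @ theta[1:4]
            ep = theta[4] + X @ theta[5:8]
            st = bb.make_state(em, ep)
            return -bb.beta_loglik(sample.values, st)

        res = minimize(nll, np.zeros(8), method="BFGS")
        lmu = make_linear_learners(X, df_target=2.0)
        lphi = make_linear_learners(X, df_target=2.0)
        model = bb.boost_fit(sample, lmu, lphi, bb.BoostConfig(m_stop=3000))

        def slopes(learners):
            return np.array([bl.coef[1] / bl.predict_info["scale"]
                             for bl in learners if bl.kind == "linear"])

        np.testing.assert_allclose(slopes(model.learners_mu), res.x[1:4], atol=1e-2)
        np.testing.assert_allclose(slopes(model.learners_phi), res.x[5:8], atol=1e-2)

    def test_step_length_robustness(self, linear_fixture):
        """Halving the step length while doubling the iteration count leaves
        predictions nearly unchanged."""
        sample, df, X = linear_fixture
        m1 = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                          bb.BoostConfig(m_stop=200, step_length=0.1))
        m2 = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                          bb.BoostConfig(m_stop=400, step_length=0.05))
        p1 = m1.predict(df, "eta_mu")
        p2 = m2.predict(df, "eta_mu")
        assert np.linalg.norm(p1 - p2) / np.linalg.norm(p1) < 0.01


class TestSelection:
    def test_informative_predictors_win(self):
        """2 informative + 8 noise linear learners: the informative ones are
        selected in nearly every replicate, each noise one in under half."""
        sel_counts = {f"x{j + 1}": 0 for j in range(10)}
        n_rep = 20
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            n = 400
            X = rng.normal(0, 1, (n, 10))
            eta_mu = 0.2 + 0.9 * X[:, 0] - 0.9 * X[:, 1]
            sample = bb.sample_beta(bb.make_state(eta_mu, np.full(n, 1.5)), seed=rep)
            lmu = make_linear_learners(X)
            lphi = [bb.build_intercept(n)]
            grid = np.arange(10, 301, 10)
            cv = bb.cv_mstop(sample, lmu, lphi, bb.BoostConfig(m_stop=300),
                             n_folds=10, grid=grid, seed=rep)
            model = bb.boost_fit(sample, make_linear_learners(X), [bb.build_intercept(n)],
                                 bb.BoostConfig(m_stop=cv.m_opt))
            for bl in model.learners_mu:
                if bl.kind == "linear" and bl.selected:
                    sel_counts[bl.predict_info["column"]] += 1
        assert sel_counts["x1"] >= 0.8 * n_rep
        assert sel_counts["x2"] >= 0.8 * n_rep
        # boosting overselects mildly; noise terms are picked in well under
        # half the replicates on average (per-learner counts at 20
        # replicates are too noisy for a sharp per-learner bound)
        noise_mean = np.mean([sel_counts[f"x{j + 1}"] for j in range(2, 10)])
        assert noise_mean < 0.5 * n_rep
        assert max(sel_counts[f"x{j + 1}"] for j in range(2, 10)) < n_rep * 0.8

    def test_fixed_precision_freezes_phi_submodel(self, linear_fixture):
        sample, df, X = linear_fixture
        model = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                             bb.BoostConfig(m_stop=100, fixed_precision=True))
        phi_selected = [bl.label for bl in model.learners_phi if bl.selected]
        assert phi_selected in ([], ["intercept"])
        phi = model.predict(df, "phi")
        assert np.allclose(phi, phi[0])

    def test_selection_frequencies_table(self, linear_fixture):
        sample, df, X = linear_fixture
        models = []
        for m in (0, 60):
            models.append(bb.boost_fit(sample, make_linear_learners(X),
                                       make_linear_learners(X), bb.BoostConfig(m_stop=m)))
        tab = bb.selection_frequencies(models[:1])
        assert (tab["frequency"] == 0).all()
        tab2 = bb.selection_frequencies(models)
        # recount directly from the accumulated coefficients
        for _, row in tab2.iterrows():
            learners = models[1].learners_mu if row.submodel == "mu" else models[1].learners_phi
            manual = sum(bl.selected for bl in learners if bl.label == row.label) / 2
            assert row.frequency == pytest.approx(manual)

    def test_vocabulary_mismatch_rejected(self, linear_fixture):
        sample, df, X = linear_fixture
        a = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                         bb.BoostConfig(m_stop=1))
        b = bb.boost_fit(sample, make_linear_learners(X[:, :3]), make_linear_learners(X[:, :3]),
                         bb.BoostConfig(m_stop=1))
        with pytest.raises(ValueError):
            bb.selection_frequencies([a, b])


class TestPredictAndSerialize:
    def test_link_identity(self, linear_fixture):
        sample, df, X = linear_fixture
        model = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                             bb.BoostConfig(m_stop=50))
        np.testing.assert_allclose(
            model.predict(df, "mu"),
            bb.betadist.inv_logit(model.predict(df, "eta_mu")),
            atol=1e-12,
        )
        np.testing.assert_allclose(
            model.predict(df, "variance"),
            bb.beta_variance(model.predict(df, "mu"), model.predict(df, "phi")),
            atol=1e-12,
        )

    def test_missing_column_raises(self, linear_fixture):
        sample, df, X = linear_fixture
        model = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                             bb.BoostConfig(m_stop=30))
        with pytest.raises(KeyError):
            model.predict(df.drop(columns=["x1"]), "mu")

    def test_round_trip_serialization(self, tmp_path, linear_fixture):
        sample, df, X = linear_fixture
        model = bb.boost_fit(sample, make_linear_learners(X), make_linear_learners(X),
                             bb.BoostConfig(m_stop=50))
        path = tmp_path / "model.json"
        model.save(path)
        clone = bb.BoostedModel.load(path)
        for what in ("eta_mu", "eta_phi", "mu", "phi", "variance"):
            np.testing.assert_allclose(clone.predict(df, what), model.predict(df, what),
                                       atol=1e-12)


class TestOddsFactor:
    @pytest.mark.parametrize("coef, expected", [(0.0, 1.0), (0.20, 1.2214), (-0.23, 0.7945)])
    def test_values(self, coef, expected):
        assert bb.odds_factor(coef) == pytest.approx(expected, abs=1e-4)

    def test_rejects_nonfinite(self):
        with pytest.raises(ValueError):
            bb.odds_factor(float("nan"))
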