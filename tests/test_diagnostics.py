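import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dcmfmri import (ConditionTiming, Dataset, FitResult, GaussianDensity,
                     Prediction, build_input_matrix, build_priors, default_spec,
                     effective_self_connection, explained_variance,
                     posterior_probability, self_connection_time_constant,
                     summarise)


def make_dataset(Y, X0=None):
    U = build_input_matrix([ConditionTiming("c", (), ())], Y.shape[0] * 1.0, 1 / 16)
    return Dataset(U=U, Y=Y, TR=1.0, slice_times=np.full(Y.shape[1], 0.5), X0=X0)


def fake_result(spec, mean, sd=None):
    """A FitResult carrying just a posterior, for the interpretation helpers."""
    prior = build_priors(spec)
    mean = np.asarray(mean, dtype=float)
    cov = np.diag(sd ** 2) if sd is not None else np.eye(mean.size) * 1e-4
    post = GaussianDensity(mean, cov, prior.index)
    V, R = 4, spec.n_regions
    return FitResult(posterior=post, lambdas=np.full(R, 6.0),
                     lambda_var=np.full(R, 1 / 128), F=0.0,
                     F_trajectory=np.array([0.0]), accuracy=0.0, complexity=0.0,
                     prediction=Prediction(y_hat=np.zeros((V, R))),
                     residuals=np.zeros((V, R)), converged=True, n_iterations=1)


class TestExplainedVariance:
    def test_perfect_prediction(self):
        rng = np.random.default_rng(0)
        Y = rng.standard_normal((50, 2))
        data = make_dataset(Y)
        assert explained_variance(Prediction(y_hat=Y.copy()), data) == pytest.approx(100.0)

    def test_zero_prediction(self):
        rng = np.random.default_rng(1)
        Y = rng.standard_normal((50, 2))
        Y -= Y.mean(axis=0)  # orthogonal to the constant confound
        data = make_dataset(Y)
        assert explained_variance(Prediction(y_hat=np.zeros_like(Y)), data) \
            == pytest.approx(0.0, abs=1e-9)

    def test_constructed_signal_fraction(self):
        # signal and residual orthogonal with SS(signal)/SS(total) = 1/4
        t = np.arange(200)
        signal = np.sin(2 * np.pi * t / 20)[:, None]
        resid = np.sqrt(3.0) * np.cos(2 * np.pi * t / 20)[:, None]
        data = make_dataset(signal + resid)
        ev = explained_variance(Prediction(y_hat=signal), data)
        assert ev == pytest.approx(25.0, abs=0.5)

    def test_invariant_to_confound_component(self):
        rng = np.random.default_rng(2)
        Y = rng.standard_normal((60, 2))
        y_hat = rng.standard_normal((60, 2)) * 0.3
        base = explained_variance(Prediction(y_hat=y_hat), make_dataset(Y))
        shifted = explained_variance(Prediction(y_hat=y_hat + 7.0),
                                     make_dataset(Y - 3.0))
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_zero_variance_data_rejected(self):
        data = make_dataset(np.ones((10, 1)))   # fully explained by the constant
        with pytest.raises(ValueError, match="variance"):
            explained_variance(Prediction(y_hat=np.zeros((10, 1))), data)


class TestPosteriorProbability:
    def test_symmetric_posterior_is_coin_flip(self):
        assert posterior_probability(0.0, 2.0) == pytest.approx(0.5)

    @given(st.floats(0.01, 3.0), st.floats(0.01, 3.0))
    @settings(max_examples=40)
    def test_monotone_in_mean_and_precision(self, mean, var):
        p = posterior_probability(mean, var)
        assert posterior_probability(mean * 1.5, var) >= p
        assert posterior_probability(mean, var / 1.5) >= p
        assert posterior_probability(-mean, var) == p

    def test_invalid_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            posterior_probability(1.0, 0.0)


class TestEffectiveSelfConnection:
    def test_default_rate_at_zero_posterior(self):
        spec = default_spec()
        res = fake_result(spec, np.zeros(len(build_priors(spec).index)))
        assert effective_self_connection(res, spec, 0, [0.6, 0.8, -0.2]) \
            == pytest.approx(-0.5)

    def test_worked_example_contexts(self):
        spec = default_spec()
        prior = build_priors(spec)
        mean = np.zeros(prior.n)
        mean[prior.position("lvF (self)")] = -0.16
        mean[prior.position("Pictures on lvF (self)")] = -0.47
        mean[prior.position("Words on lvF (self)")] = 2.80
        res = fake_result(spec, mean)
        pics = effective_self_connection(res, spec, 0, [0.6, 0.8, -0.2])
        words = effective_self_connection(res, spec, 0, [0.6, -0.2, 0.8])
        assert round(pics, 2) == -0.17
        assert round(words, 2) == -4.40
        tau, hl = self_connection_time_constant(res, spec, 0, [0.6, 0.8, -0.2])
        assert tau == pytest.approx(1 / abs(pics))
        assert hl == pytest.approx(tau * np.log(2))

    def test_bad_region_rejected(self):
        spec = default_spec()
        res = fake_result(spec, np.zeros(37))
        with pytest.raises(ValueError, match="region"):
            effective_self_connection(res, spec, 9, [0, 0, 0])


class TestSummarise:
    def test_table_layout_matches_free_parameters(self):
        spec = default_spec()
        prior = build_priors(spec)
        rng = np.random.default_rng(3)
        res = fake_result(spec, rng.normal(0, 0.1, prior.n),
                          sd=np.full(prior.n, 0.05))
        rep = summarise(res, spec)
        assert len(rep.table) == prior.n
        assert (rep.table["family"].isin(["a", "b", "c"])).sum() == 24
        extrinsic = rep.table[(rep.table["family"] == "a")
                              & rep.table["units"].eq("Hz")]
        assert extrinsic["parameter"].str.contains("→").all()
        selfs = rep.table[rep.table["parameter"].str.contains("(self)", regex=False)]
        assert (selfs["units"] == "None").all()
        assert ((rep.table["probability"] >= 0.5)
                & (rep.table["probability"] <= 1.0)).all()

    def test_tsv_round_trip(self, tmp_path):
        spec = default_spec()
        prior = build_priors(spec)
        res = fake_result(spec, np.linspace(-1, 1, prior.n),
                          sd=np.full(prior.n, 0.1))
        rep = summarise(res, spec)
        path = tmp_path / "report.tsv"
        rep.to_tsv(path)
        # keep_default_na: the unitless rows are labelled with the literal
        # string "None", which must survive the round trip
        back = pd.read_csv(path, sep="\t", keep_default_na=False)
        assert list(back.columns) == list(rep.table.columns)
        pd.testing.assert_frame_equal(back, rep.table, check_exact=False, atol=1e-12)

    def test_explained_variance_included_with_data(self, two_region_fit):
        spec, data, _, result = two_region_fit
        rep = summarise(result, spec, data=data)
        assert rep.explained_variance is not None
        assert 0 <= rep.explained_variance <= 100
        assert rep.F == result.F
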