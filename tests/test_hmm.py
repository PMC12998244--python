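import math
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from roarbout.hmm import (
    FitConfig,
    GaussianHMM,
    HMMParams,
    HMMResults,
    fit_hmm,
    log_likelihood,
    params_from_text,
)


def enumerate_loglik(params: HMMParams, x: np.ndarray) -> float:
    """Independent oracle: sum p(path, obs) over every hidden state path."""
    total = -np.inf
    k, n = params.n_states, len(x)
    for path in product(range(k), repeat=n):
        lp = math.log(params.startprob[path[0]])
        for t in range(1, n):
            lp += math.log(params.transmat[path[t - 1], path[t]])
        for t in range(n):
            lp += float(params.log_emission(x[t])[path[t]])
        total = np.logaddexp(total, lp)
    return float(total)


def random_params(rng, k=2):
    return HMMParams(
        startprob=rng.dirichlet(np.ones(k)),
        transmat=rng.dirichlet(np.ones(k), size=k),
        means=rng.uniform(50, 350, size=k),
        variances=rng.uniform(10, 500, size=k),
    )


class TestForwardAlgorithm:
    def test_single_frame_closed_form(self, rng):
        p = random_params(rng)
        x = np.array([200.0])
        expected = np.logaddexp.reduce(np.log(p.startprob) + p.log_emission(200.0))
        assert log_likelihood(p, x) == pytest.approx(float(expected), abs=1e-12)

    def test_length3_matches_path_enumeration(self, rng):
        p = HMMParams(np.array([0.6, 0.4]), np.array([[0.7, 0.3], [0.2, 0.8]]),
                      np.array([100.0, 300.0]), np.array([50.0, 80.0]))
        x = rng.normal(150, 80, size=3)
        assert log_likelihood(p, x) == pytest.approx(enumerate_loglik(p, x), abs=1e-10)

    def test_identical_states_reduce_to_iid_gaussian(self, rng):
        p = HMMParams(np.array([0.5, 0.5]), np.full((2, 2), 0.5),
                      np.array([150.0, 150.0]), np.array([40.0, 40.0]))
        x = rng.normal(150, 6, size=20)
        iid = float(np.sum(p.log_emission(x)[:, 0]))
        assert log_likelihood(p, x) == pytest.approx(iid, abs=1e-9)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10**6), n=st.integers(1, 8))
    def test_property_matches_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        p = random_params(rng)
        x = rng.uniform(30, 380, size=n)
        assert log_likelihood(p, x) == pytest.approx(enumerate_loglik(p, x), abs=1e-10)

    def test_long_contour_no_underflow(self, rng):
        p = random_params(rng)
        x = rng.normal(200, 50, size=100_000)
        ll = log_likelihood(p, x)
        assert np.isfinite(ll)

    def test_empty_contour_rejected(self, rng):
        with pytest.raises(ValueError):
            log_likelihood(random_params(rng), np.array([]))

    def test_matches_hmmlearn(self, rng):
        """Independent library cross-check of the forward algorithm."""
        from hmmlearn.hmm import GaussianHMM as RefHMM

        p = random_params(rng)
        x = rng.normal(180, 60, size=40)
        ref = RefHMM(n_components=2, covariance_type="diag", init_params="")
        ref.startprob_ = p.startprob
        ref.transmat_ = p.transmat
        ref.means_ = p.means[:, None]
        ref.covars_ = p.variances[:, None]
        assert log_likelihood(p, x) == pytest.approx(ref.score(x[:, None]), abs=1e-8)


class TestFit:
    def test_parameter_recovery(self, rng):
        truth = HMMParams(np.array([0.5, 0.5]), np.array([[0.9, 0.1], [0.15, 0.85]]),
                          np.array([120.0, 300.0]), np.array([100.0, 100.0]))
        seqs = [truth.sample(50, rng) for _ in range(200)]
        res = fit_hmm(seqs, FitConfig(n_restarts=3, seed=7))
        np.testing.assert_allclose(res.sorted_by_mean().means, [120.0, 300.0], atol=10.0)

    def test_em_monotone_within_restart(self, rng):
        truth = random_params(rng)
        seqs = [truth.sample(30, rng) for _ in range(5)]
        res = fit_hmm(seqs, FitConfig(n_restarts=1, seed=1))
        diffs = np.diff(res.history)
        assert np.all(diffs >= -1e-8)

    def test_best_restart_wins(self, rng):
        seqs = [rng.normal(100, 5, 20), rng.normal(250, 5, 20)]
        res = fit_hmm(seqs, FitConfig(n_restarts=6, seed=2))
        assert res.loglik == pytest.approx(np.max(res.restart_logliks), abs=1e-9)

    def test_constant_contour_hits_variance_floor(self):
        res = fit_hmm([np.full(30, 200.0)], FitConfig(n_restarts=2, seed=0))
        np.testing.assert_allclose(res.params.means, 200.0, atol=1e-6)
        np.testing.assert_allclose(res.params.variances, 1.0)

    def test_same_seed_identical_model(self, rng):
        seqs = [rng.normal(150, 30, 25) for _ in range(4)]
        a = fit_hmm(seqs, FitConfig(n_restarts=3, seed=11))
        b = fit_hmm(seqs, FitConfig(n_restarts=3, seed=11))
        np.testing.assert_array_equal(a.params.means, b.params.means)
        np.testing.assert_array_equal(a.params.transmat, b.params.transmat)

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            GaussianHMM([np.array([])])

    def test_summary_mentions_fit(self, rng):
        res = fit_hmm([rng.normal(100, 10, 30)], FitConfig(n_restarts=2, seed=0))
        text = res.summary()
        assert "log-likelihood" in text and "transition matrix" in text

    def test_text_round_trip(self, rng):
        res = fit_hmm([rng.normal(100, 10, 30)], FitConfig(n_restarts=2, seed=0))
        back = params_from_text(res.to_text())
        np.testing.assert_array_equal(back.means, res.params.means)
        np.testing.assert_array_equal(back.transmat, res.params.transmat)


class TestInvariantsOnParams:
    def test_bad_simplex_rejected(self):
        with pytest.raises(ValueError):
            HMMParams(np.array([0.7, 0.7]), np.eye(2), np.array([1.0, 2.0]),
                      np.array([1.0, 1.0]))

    def test_non_stochastic_rows_rejected(self):
        with pytest.raises(ValueError):
            HMMParams(np.array([0.5, 0.5]), np.array([[0.5, 0.6], [0.5, 0.5]]),
                      np.array([1.0, 2.0]), np.array([1.0, 1.0]))
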