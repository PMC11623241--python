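"""wAIC, PSIS-LOO and model ranking against independent oracles."""

import warnings

import numpy as np
import pytest
from scipy.special import logsumexp

import mdnrm as m
from mdnrm.selection import FitScore, smooth_log_weights


def brute_force_waic(loglik):
    """Direct-formula wAIC, written loop-wise and independently of the
    package implementation."""
    S, N = loglik.shape
    lppd, p_waic, pointwise = 0.0, 0.0, []
    for n in range(N):
        col = loglik[:, n]
        lppd_n = np.log(np.mean(np.exp(col - col.max()))) + col.max()
        p_n = float(np.var(col, ddof=1))
        lppd += lppd_n
        p_waic += p_n
        pointwise.append(lppd_n - p_n)
    score = -2.0 * (lppd - p_waic)
    se = 2.0 * np.sqrt(N * np.var(pointwise, ddof=1))
    return lppd, p_waic, score, se


@pytest.fixture()
def loglik(rng):
    return rng.normal(-1.2, 0.5, size=(50, 20)) + rng.normal(0, 0.4, (1, 20))


class TestWaic:
    def test_matches_brute_force(self, loglik):
        w = m.waic(loglik)
        lppd, p_waic, score, se = brute_force_waic(loglik)
        assert abs(w.lppd - lppd) < 1e-10
        assert abs(w.p_eff - p_waic) < 1e-10
        assert abs(w.score - score) < 1e-10
        assert abs(w.se - se) < 1e-10

    def test_identical_rows_have_zero_penalty(self):
        row = np.linspace(-3, -1, 7)
        ll = np.tile(row, (5, 1))
        w = m.waic(ll)
        assert w.p_eff == pytest.approx(0.0, abs=1e-12)
        assert w.score == pytest.approx(-2 * row.sum())

    def test_duplicated_observation_adds_contribution(self, loglik):
        w = m.waic(loglik)
        w2 = m.waic(np.hstack([loglik, loglik[:, :1]]))
        assert w2.lppd == pytest.approx(
            w.lppd + (w.pointwise[0] + np.var(loglik[:, 0], ddof=1))
        )
        assert w2.p_eff == pytest.approx(w.p_eff + np.var(loglik[:, 0], ddof=1))

    def test_single_draw_rejected(self):
        with pytest.raises(ValueError):
            m.waic(np.zeros((1, 4)))

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            m.waic(np.array([[0.0, -np.inf], [0.0, 0.0]]))

    def test_row_permutation_invariant(self, loglik, rng):
        perm = rng.permutation(loglik.shape[0])
        assert m.waic(loglik[perm]).score == pytest.approx(
            m.waic(loglik).score, abs=1e-12
        )


class TestPsisLoo:
    def test_identical_rows_equal_lppd(self):
        row = np.linspace(-2, -1, 6)
        ll = np.tile(row, (200, 1))
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            l = m.psis_loo(ll)
        assert l.elpd == pytest.approx(l.lppd)
        assert l.score == pytest.approx(-2 * row.sum())
        assert np.all(np.isnan(l.pareto_k))

    def test_matches_reference_psis(self, rng):
        """Against the established PSIS implementation, elpd to 1e-6."""
        import arviz as az

        ll = rng.normal(-1.0, 0.8, size=(1000, 10))
        mine = m.psis_loo(ll)
        lw, khat = az.psislw(-ll.T, reff=1.0)
        elpd_ref = logsumexp(np.asarray(lw).T + ll, axis=0)
        assert np.abs(mine.pointwise - elpd_ref).max() < 1e-6
        np.testing.assert_allclose(mine.pareto_k, np.asarray(khat), atol=1e-8)

    def test_loo_never_beats_in_sample(self, rng):
        ll = rng.normal(-1.0, 1.0, size=(500, 25))
        l = m.psis_loo(ll)
        lppd_i = logsumexp(ll, axis=0) - np.log(ll.shape[0])
        assert np.all(l.pointwise <= lppd_i + 1e-10)

    def test_column_permutation_equivariant(self, rng):
        ll = rng.normal(-1.0, 0.7, size=(400, 12))
        perm = rng.permutation(12)
        a = m.psis_loo(ll)
        b = m.psis_loo(ll[:, perm])
        np.testing.assert_allclose(b.pointwise, a.pointwise[perm], atol=1e-12)


class TestGpdTail:
    def test_recovers_heavy_tail_shape(self, rng):
        u = rng.uniform(size=10_000)
        x = np.sort((np.power(1 - u, -0.5) - 1.0) / 0.5)  # GPD(k=0.5, sigma=1)
        k, sigma = m.fit_gpd_tail(x)
        assert abs(k - 0.5) < 0.05
        assert abs(sigma - 1.0) < 0.1

    def test_exponential_gives_zero_shape(self, rng):
        x = np.sort(rng.exponential(1.0, 10_000))
        k, _ = m.fit_gpd_tail(x)
        assert abs(k) < 0.05

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            m.fit_gpd_tail(np.array([0.1, 0.2, 0.3]))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            m.fit_gpd_tail(np.full(10, 2.0))


def _score(criterion, score, n=5):
    pw = np.full(n, -score / 2 / n)
    return FitScore(criterion=criterion, lppd=-score / 2, elpd=-score / 2,
                    p_eff=0.0, score=score, se=1.0, pointwise=pw)


class TestCompareModels:
    def test_orders_ascending_and_reports_best(self):
        scores = {
            "b": (_score("waic", 120.0), _score("loo", 100.0)),
            "a": (_score("waic", 100.0), _score("loo", 130.0)),
        }
        res = m.compare_models(scores)
        assert res.best_waic == "a"
        assert res.best_loo == "b"
        assert list(res.table["model"]) == ["a", "b"]

    def test_tie_breaks_by_label(self):
        scores = {
            "z": (_score("waic", 100.0), _score("loo", 100.0)),
            "a": (_score("waic", 100.0), _score("loo", 100.0)),
        }
        res = m.compare_models(scores)
        assert res.best_waic == "a" and res.best_loo == "a"

    def test_minus_infinity_ranks_first(self):
        scores = {
            "normal": (_score("waic", 100.0), _score("loo", 100.0)),
            "perfect": (_score("waic", -np.inf), _score("loo", -np.inf)),
        }
        assert m.compare_models(scores).best_waic == "perfect"

    def test_mismatched_n_rejected(self):
        scores = {
            "a": (_score("waic", 1.0, n=5), _score("loo", 1.0, n=5)),
            "b": (_score("waic", 1.0, n=6), _score("loo", 1.0, n=6)),
        }
        with pytest.raises(ValueError, match="different N"):
            m.compare_models(scores)

    def test_fewer_than_two_rejected(self):
        with pytest.raises(ValueError):
            m.compare_models({"a": (_score("waic", 1.0), _score("loo", 1.0))})


def test_smoothing_preserves_normalization(rng):
    lw, k = smooth_log_weights(rng.normal(0, 2, 500))
    assert logsumexp(lw) == pytest.approx(0.0, abs=1e-10)
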