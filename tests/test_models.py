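"""Logits, softmax probabilities, pointwise likelihood and priors."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mdnrm as m
from mdnrm.models import row_logits

C = 3
MDNRM_VARIANTS = ["mdnrm_orig", "mdnrm_a", "mdnrm_b", "mdnrm_r"]


def _spec(variant, prior=None, **kw):
    if prior is None:
        prior = "none" if variant in ("mdnrm_orig", "nrm_1pl") else "gamma"
    return m.ModelSpec(variant=variant, n_classes=C, alpha_prior=prior, **kw)


def _params(spec, I, J, rng, diag_boost=0.0):
    shapes = m.parameter_shapes(spec, I, J)
    theta = rng.normal(0, 1, shapes["theta"])
    if theta.ndim == 3 and diag_boost:
        for t in range(C):
            theta[:, t, t] += diag_boost
    alpha = None
    if "alpha" in shapes:
        alpha = rng.gamma(2.0, 0.5, shapes["alpha"])
    beta = rng.normal(0, 1, shapes["beta"])
    return m.ParameterSet(theta=theta, beta=beta, alpha=alpha)


class TestLogits:
    def test_original_mdnrm_is_theta_plus_beta(self):
        spec = _spec("mdnrm_orig")
        theta = np.zeros((1, C, C))
        theta[0, 0] = [0.0, 1.0, 2.0]
        beta = np.full((1, C), 5.0)
        p = m.ParameterSet(theta=theta, beta=beta)
        np.testing.assert_allclose(m.logits(spec, p, 0, 0, 0), [5.0, 6.0, 7.0])

    def test_subtype_a_scales_theta(self):
        spec = _spec("mdnrm_a")
        theta = np.zeros((1, C, C))
        theta[0, 0] = [1.0, 0.0, -1.0]
        p = m.ParameterSet(
            theta=theta, beta=np.zeros(C), alpha=np.full((1, C), 2.0)
        )
        np.testing.assert_allclose(m.logits(spec, p, 0, 0, 0), [2.0, 0.0, -2.0])

    def test_zero_ability_gives_constant_logits(self):
        spec = _spec("mdnrm_r")
        p = m.ParameterSet(
            theta=np.zeros((2, C, C)),
            beta=np.arange(2 * C, dtype=float).reshape(2, C),
            alpha=np.ones((2, C)),
        )
        z = m.logits(spec, p, 1, 0, 2)
        np.testing.assert_allclose(z, np.full(C, p.beta[1, 2]))

    def test_shape_mismatch_names_offender(self):
        spec = _spec("mdnrm_r")
        p = m.ParameterSet(
            theta=np.zeros((2, C, C)), beta=np.zeros((2, C)),
            alpha=np.zeros((3, C)),
        )
        with pytest.raises(m.ShapeError, match="alpha"):
            m.logits(spec, p, 0, 0, 0)


class TestClassProbabilities:
    def test_uniform_for_equal_logits(self):
        np.testing.assert_allclose(
            m.class_probabilities(np.zeros(3)), np.full(3, 1 / 3)
        )

    def test_closed_form(self):
        np.testing.assert_allclose(
            m.class_probabilities(np.array([np.log(2), 0.0, 0.0])),
            [0.5, 0.25, 0.25],
        )

    @settings(max_examples=60, derandomize=True)
    @given(
        z=st.lists(st.floats(-30, 30), min_size=2, max_size=5),
        c=st.floats(-50, 50),
    )
    def test_shift_invariance_and_simplex(self, z, c):
        z = np.asarray(z)
        p = m.class_probabilities(z)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)
        np.testing.assert_allclose(m.class_probabilities(z + c), p, atol=1e-12)

    def test_non_finite_rejected(self):
        with pytest.raises(FloatingPointError):
            m.class_probabilities(np.array([np.nan, 0.0]))


class TestPointwiseLoglik:
    def _table(self, I=4, J=2):
        spec = _spec("mdnrm_orig")
        table, _ = m.generate_dataset(
            m.SimulationConfig(spec=spec, n_raters=J, n_cases=I, seed=3)
        )
        return table

    @pytest.mark.parametrize("variant", MDNRM_VARIANTS + ["nrm_2pl", "nrm_1pl"])
    def test_zero_parameters_give_uniform(self, variant):
        spec = _spec(variant)
        table = self._table()
        shapes = m.parameter_shapes(spec, table.n_cases, table.n_raters)
        p = m.ParameterSet(
            theta=np.zeros(shapes["theta"]),
            beta=np.zeros(shapes["beta"]),
            alpha=np.zeros(shapes["alpha"]) if "alpha" in shapes else None,
        )
        ll = m.pointwise_loglik(spec, p, table)
        np.testing.assert_allclose(ll, np.log(1 / C))

    @pytest.mark.parametrize("variant", MDNRM_VARIANTS)
    def test_beta_perturbation_is_bit_exact_noop(self, variant, rng):
        spec = _spec(variant)
        table = self._table()
        p = _params(spec, table.n_cases, table.n_raters, rng)
        ll = m.pointwise_loglik(spec, p, table)
        p2 = m.ParameterSet(
            theta=p.theta, alpha=p.alpha,
            beta=p.beta + rng.normal(0, 10, p.beta.shape),
        )
        ll2 = m.pointwise_loglik(spec, p2, table)
        assert np.array_equal(ll, ll2)  # zero difference, not just close

    def test_response_indexed_beta_does_not_cancel(self, rng):
        spec = _spec("mdnrm_r", beta_response_indexed=True)
        table = self._table()
        p = _params(spec, table.n_cases, table.n_raters, rng)
        p2 = m.ParameterSet(
            theta=p.theta, alpha=p.alpha,
            beta=p.beta + rng.normal(0, 1, p.beta.shape),
        )
        assert not np.allclose(
            m.pointwise_loglik(spec, p, table),
            m.pointwise_loglik(spec, p2, table),
        )

    def test_matches_manual_enumeration(self):
        """3-row toy table against softmax probabilities written out by hand."""
        spec = _spec("mdnrm_orig")
        table = m.ResponseTable(
            case_id=[0, 0, 1], rater_id=[0, 1, 0],
            ground_truth=[1, 1, 2], response=[0, 1, 2],
            n_cases=2, n_raters=2, n_classes=3,
        )
        theta = np.zeros((2, 3, 3))
        theta[0, 1] = [0.3, -0.2, 1.1]
        theta[1, 1] = [0.0, 0.5, -0.5]
        theta[0, 2] = [-1.0, 0.0, 2.0]
        p = m.ParameterSet(theta=theta, beta=np.ones((2, 3)))
        ll = m.pointwise_loglik(spec, p, table)
        for k, (j, s, t) in enumerate([(0, 1, 0), (1, 1, 1), (0, 2, 2)]):
            z = theta[j, s]
            expected = np.log(np.exp(z[t]) / np.exp(z).sum())
            assert abs(ll[k] - expected) < 1e-12

    def test_unit_discrimination_2pl_equals_1pl(self, rng):
        table = self._table()
        spec2, spec1 = _spec("nrm_2pl"), _spec("nrm_1pl")
        shapes = m.parameter_shapes(spec1, table.n_cases, table.n_raters)
        theta = rng.normal(0, 1, shapes["theta"])
        beta = rng.normal(0, 1, shapes["beta"])
        p1 = m.ParameterSet(theta=theta, beta=beta)
        p2 = m.ParameterSet(theta=theta, beta=beta,
                            alpha=np.ones((table.n_cases, C)))
        np.testing.assert_allclose(
            m.pointwise_loglik(spec2, p2, table),
            m.pointwise_loglik(spec1, p1, table),
            atol=1e-12,
        )

    def test_raising_theta_raises_own_class_probability(self, rng):
        spec = _spec("mdnrm_a", prior="halfnormal")
        table = self._table()
        p = _params(spec, table.n_cases, table.n_raters, rng)
        i, j, s = 1, 0, int(table.case_truths()[1])
        z0 = m.logits(spec, p, i, j, s)
        probs0 = m.class_probabilities(z0)
        p.theta[j, s, 1] += 0.7
        probs1 = m.class_probabilities(m.logits(spec, p, i, j, s))
        assert probs1[1] > probs0[1]
        others = [t for t in range(C) if t != 1]
        assert np.all(probs1[others] < probs0[others])


class TestLogPrior:
    def test_density_at_mode(self):
        spec = _spec("mdnrm_orig")
        p = m.ParameterSet(theta=np.zeros((1, C, C)), beta=np.zeros((1, C)))
        expected = (C * C + C) * np.log(1.0 / (2.0 * np.sqrt(2.0 * np.pi)))
        assert abs(m.log_prior(spec, p) - expected) < 1e-12

    def test_negative_alpha_outside_support(self, rng):
        spec = _spec("mdnrm_r", prior="gamma")
        p = _params(spec, 2, 2, rng)
        p.alpha[0, 0] = -1.0
        assert m.log_prior(spec, p) == -np.inf

    @pytest.mark.parametrize("prior", ["gamma", "halfnormal"])
    def test_matches_per_entry_scalar_densities(self, prior, rng):
        spec = _spec("mdnrm_r", prior=prior)
        p = _params(spec, 3, 2, rng)
        expected = 0.0
        for v in p.theta.ravel():
            expected += stats.norm.logpdf(v, scale=2.0)
        for v in p.beta.ravel():
            expected += stats.norm.logpdf(v, scale=2.0)
        for v in p.alpha.ravel():
            if prior == "gamma":
                expected += stats.gamma.logpdf(v, 2.0, scale=0.5)
            else:
                expected += stats.halfnorm.logpdf(v, scale=10.0)
        assert abs(m.log_prior(spec, p) - expected) < 1e-9


class TestModelSpec:
    def test_alpha_prior_required_for_two_parameter_variants(self):
        with pytest.raises(ValueError, match="alpha_prior"):
            m.ModelSpec(variant="mdnrm_r", n_classes=3, alpha_prior="none")

    def test_no_alpha_variants_normalize_prior_to_none(self):
        spec = m.ModelSpec(variant="mdnrm_orig", n_classes=3, alpha_prior="gamma")
        assert spec.alpha_prior == m.AlphaPrior.NONE

    def test_positive_hyperparameters_enforced(self):
        with pytest.raises(ValueError):
            m.ModelSpec(variant="mdnrm_r", n_classes=3, alpha_prior="gamma",
                        gamma_rate=0.0)

    @pytest.mark.parametrize(
        "variant,expected",
        [
            ("mdnrm_orig", {"theta": (2, 3, 3), "beta": (5, 3)}),
            ("mdnrm_a", {"theta": (2, 3, 3), "alpha": (5, 3), "beta": (3,)}),
            ("mdnrm_b", {"theta": (2, 3, 3), "alpha": (3,), "beta": (5, 3)}),
            ("mdnrm_r", {"theta": (2, 3, 3), "alpha": (5, 3), "beta": (5, 3)}),
            ("nrm_2pl", {"theta": (2,), "alpha": (5, 3), "beta": (5, 3)}),
            ("nrm_1pl", {"theta": (2,), "beta": (5, 3)}),
        ],
    )
    def test_parameter_shapes_per_variant(self, variant, expected):
        spec = _spec(variant)
        assert m.parameter_shapes(spec, n_cases=5, n_raters=2) == expected
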