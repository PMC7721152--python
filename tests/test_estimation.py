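import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize_scalar

from ecwm.designs import GroupObservation, QuestionDesign, StudyDataset, ValidationError
from ecwm.estimation import (
    ConvergenceError,
    EMSettings,
    estimate_group,
    estimate_pooled,
    group_information,
    log_likelihood,
    response_prob,
)

P1, P2 = 0.158, 0.842


def cw(label, p, n, c):
    return GroupObservation(label, QuestionDesign.crosswise(p), n, c)


class TestResponseProb:
    @pytest.mark.parametrize(
        "pi, design, expected",
        [
            (0.0, QuestionDesign.crosswise(P1), P1),
            (0.5, QuestionDesign.crosswise(P1), 0.5),
            (0.5, QuestionDesign.crosswise(0.3), 0.5),
            (0.2189, QuestionDesign.crosswise(P1), 0.158 + 0.2189 * 0.684),
            (0.37, QuestionDesign.direct(), 0.37),
        ],
    )
    def test_tree_probabilities(self, pi, design, expected):
        assert response_prob(pi, design).lam == pytest.approx(expected, abs=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValidationError):
            response_prob(1.2, QuestionDesign.direct())

    @given(pi=st.floats(0, 1), p=st.floats(0.01, 0.99).filter(lambda v: abs(v - 0.5) > 1e-3))
    @settings(max_examples=200, deadline=None)
    def test_lambda_stays_in_design_band(self, pi, p):
        lam = response_prob(pi, QuestionDesign.crosswise(p)).lam
        assert min(p, 1 - p) - 1e-12 <= lam <= max(p, 1 - p) + 1e-12


class TestEstimateGroup:
    @pytest.mark.parametrize(
        "obs, pi_pct, se_pct",
        [
            (cw("a", P1, 455, 140), 21.88, 3.16),
            (cw("b", P2, 456, 320), 20.50, 3.13),
            (GroupObservation("dq", QuestionDesign.direct(), 450, 49), 10.89, 1.47),
        ],
    )
    def test_published_group_estimates(self, obs, pi_pct, se_pct):
        est = estimate_group(obs)
        assert 100 * est.pi_hat == pytest.approx(pi_pct, abs=0.005)
        assert 100 * est.se == pytest.approx(se_pct, abs=0.005)
        assert est.ci_low <= est.pi_hat <= est.ci_high
        assert not est.truncated

    def test_out_of_range_estimate_reported_raw_and_flagged(self):
        est = estimate_group(cw("empty", P1, 100, 0))
        assert est.pi_hat == pytest.approx((0 - P1) / (1 - 2 * P1))
        assert est.pi_hat < 0 and est.truncated
        assert est.pi_hat_clipped == 0.0

    @given(n=st.integers(2, 1000), c=st.data(), p=st.floats(0.05, 0.45))
    @settings(max_examples=150, deadline=None)
    def test_estimator_inverts_response_prob(self, n, c, p):
        """estimate_group recovers exactly the lambda-hat fed through the tree."""
        count = c.draw(st.integers(0, n))
        obs = cw("g", p, n, count)
        est = estimate_group(obs)
        assert response_prob(min(1, max(0, est.pi_hat)), obs.design).lam * n == pytest.approx(
            count, abs=1e-6
        ) or est.truncated

    def test_bootstrap_se_matches_delta_method(self, rng):
        """Delta-method SE agrees with the parametric-bootstrap sd at n = 455."""
        n, p, pi = 455, P1, 0.21
        lam = p + pi * (1 - 2 * p)
        counts = rng.binomial(n, lam, size=2000)
        pis = (counts / n - p) / (1 - 2 * p)
        analytic = math.sqrt(lam * (1 - lam) / (n * (1 - 2 * p) ** 2))
        assert np.std(pis, ddof=1) == pytest.approx(analytic, rel=0.03)


class TestLogLikelihood:
    def test_direct_group_maximized_at_sample_proportion(self, dq_group):
        grid = np.linspace(0, 1, 1001)
        values = [log_likelihood(dq_group, v) for v in grid]
        assert log_likelihood(dq_group, 49 / 450) >= max(values)

    def test_contradicting_boundary_gives_minus_inf(self, dq_group):
        assert log_likelihood(dq_group, 0.0) == -math.inf

    def test_additivity_over_groups(self, ecwm_pair):
        joint = log_likelihood(ecwm_pair, [0.2, 0.3])
        singles = log_likelihood(StudyDataset([ecwm_pair[0]]), 0.2) + log_likelihood(
            StudyDataset([ecwm_pair[1]]), 0.3
        )
        assert joint == pytest.approx(singles, abs=1e-10)


class TestEstimatePooled:
    def test_published_pooled_estimate(self, ecwm_pair):
        est = estimate_pooled(ecwm_pair)
        assert 100 * est.pi_hat == pytest.approx(21.19, abs=0.005)
        assert 100 * est.se == pytest.approx(2.23, abs=0.005)
        assert est.method == "maximum_likelihood"

    def test_complementary_pair_closed_form(self, ecwm_pair):
        g1, g2 = ecwm_pair
        closed = ((g1.count_a + g2.n - g2.count_a) / (g1.n + g2.n) - P1) / (1 - 2 * P1)
        assert estimate_pooled(ecwm_pair).pi_hat == pytest.approx(closed, abs=1e-9)

    def test_single_group_reduces_to_closed_form(self):
        obs = cw("g", P1, 455, 140)
        pooled = estimate_pooled(StudyDataset([obs]))
        single = estimate_group(obs)
        assert pooled.pi_hat == pytest.approx(single.pi_hat, abs=1e-8)
        assert pooled.se == pytest.approx(single.se, rel=1e-6)

    def test_em_equals_numerical_mle_on_random_datasets(self, rng):
        """EM fixed point agrees with direct likelihood maximization to 1e-6."""
        for _ in range(25):
            p = rng.uniform(0.05, 0.45)
            pi = rng.uniform(0.05, 0.95)
            groups = []
            for j, pg in enumerate((p, 1 - p, rng.uniform(0.55, 0.95))):
                n = int(rng.integers(50, 800))
                lam = pg + pi * (1 - 2 * pg)
                groups.append(cw(f"g{j}", pg, n, int(rng.binomial(n, lam))))
            ds = StudyDataset(groups)
            em = estimate_pooled(ds).pi_hat
            res = minimize_scalar(
                lambda v: -log_likelihood(ds, v),
                bounds=(0, 1), method="bounded", options={"xatol": 1e-12},
            )
            assert em == pytest.approx(res.x, abs=1e-6)

    def test_rejects_direct_groups(self, full_study):
        with pytest.raises(ValidationError):
            estimate_pooled(full_study)

    def test_nonconvergence_carries_trace(self, ecwm_pair):
        with pytest.raises(ConvergenceError) as exc:
            estimate_pooled(ecwm_pair, EMSettings(tol=1e-14, max_iter=2))
        assert len(exc.value.trace) >= 3

    def test_ecwm_matches_single_cwm_efficiency(self):
        """Complementary-p pair at equal split carries the same information as one CWM group."""
        pi, p, n = 0.21, P1, 911
        pair_info = group_information(pi, QuestionDesign.crosswise(p), n / 2) + group_information(
            pi, QuestionDesign.crosswise(1 - p), n / 2
        )
        single_info = group_information(pi, QuestionDesign.crosswise(p), n)
        assert 1 / pair_info == pytest.approx(1 / single_info, abs=1e-12)


def test_em_settings_validation():
    for kwargs in ({"tol": 0.0}, {"max_iter": 0}, {"pi_init": 0.0}, {"pi_init": 1.0}):
        with pytest.raises(ValidationError):
            EMSettings(**kwargs)
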