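import numpy as np
import pytest

from rlpcascade.bayes_ensemble import (
    EnsembleError,
    beta_binomial_posterior,
    decide,
    dirichlet_multinomial_posterior,
    mcmc_beta_posterior_mean,
    mcmc_dirichlet_posterior_mean,
    stage_vote,
    subfamily_vote,
)
from rlpcascade.dataset_builder import ClassScheme
from rlpcascade.models import MemberModel


class TestBetaBinomial:
    def test_unanimous_positive(self):
        post = beta_binomial_posterior([1, 1, 1, 1, 1])
        assert post.mean == pytest.approx(6 / 7)
        assert (post.alpha, post.beta) == (6.0, 1.0)

    def test_unanimous_negative(self):
        post = beta_binomial_posterior([0] * 10)
        assert post.mean == pytest.approx(1 / 12)

    def test_empty_votes_rejected(self):
        with pytest.raises(EnsembleError):
            beta_binomial_posterior([])

    def test_non_binary_votes_rejected(self):
        with pytest.raises(EnsembleError):
            beta_binomial_posterior([0, 2])

    def test_mean_strictly_increasing_in_successes(self):
        means = [beta_binomial_posterior([1] * x + [0] * (12 - x)).mean
                 for x in range(13)]
        assert np.all(np.diff(means) > 0)

    def test_mean_converges_to_frequency(self):
        n = 10_000
        x = 3_777
        post = beta_binomial_posterior([1] * x + [0] * (n - x))
        assert abs(post.mean - x / n) < 0.01


class TestDirichletMultinomial:
    def test_concentrated_counts(self):
        post = dirichlet_multinomial_posterior([3, 0, 0])
        assert np.allclose(post.mean, [4 / 6, 1 / 6, 1 / 6])

    def test_zero_counts_give_uniform_prior_mean(self):
        post = dirichlet_multinomial_posterior([0] * 5)
        assert np.allclose(post.mean, 0.2)

    def test_negative_count_rejected(self):
        with pytest.raises(EnsembleError):
            dirichlet_multinomial_posterior([3, -1])

    def test_map_label(self):
        post = dirichlet_multinomial_posterior(
            [1, 8, 1], classes=("a", "b", "c")
        )
        assert post.map_label == "b"
        assert post.mean.sum() == pytest.approx(1.0)


class _StubEstimator:
    def __init__(self, label):
        self.label = label

    def predict(self, X):
        return np.array([self.label] * len(X))


def _member(label, feature_type="AAComposition"):
    return MemberModel(
        algorithm_id="lda",
        feature_type=feature_type,
        dataset_id="stub",
        stage="rlp_vs_nrlp",
        estimator=_StubEstimator(label),
        classes=["NRLP", "RLP"],
    )


VECTORS = {"AAComposition": np.full(20, 0.05), "CPAASC": np.zeros(9)}


class TestVoting:
    def test_unanimous_stage_vote(self):
        members = [_member("RLP") for _ in range(6)]
        assert stage_vote(members, VECTORS, "RLP").tolist() == [1] * 6

    def test_mixed_stage_vote_order_preserved(self):
        members = [_member("RLP"), _member("NRLP"), _member("RLP")]
        assert stage_vote(members, VECTORS, "RLP").tolist() == [1, 0, 1]

    def test_missing_feature_vector_rejected(self):
        members = [_member("RLP", feature_type="Tripeptide")]
        with pytest.raises(EnsembleError, match="Tripeptide"):
            stage_vote(members, VECTORS, "RLP")

    def test_subfamily_counts_conserve_members(self):
        scheme = ClassScheme(labels=("LRR-RLP", "WAK-RLP", "Other-RLP"))
        members = [_member("LRR-RLP")] * 4 + [_member("WAK-RLP")] * 2
        counts = subfamily_vote(members, VECTORS, scheme)
        assert counts.tolist() == [4, 2, 0]
        assert counts.sum() == len(members)

    def test_prediction_outside_scheme_rejected(self):
        scheme = ClassScheme(labels=("LRR-RLP", "Other-RLP"))
        with pytest.raises(EnsembleError):
            subfamily_vote([_member("mystery")], VECTORS, scheme)


def _subfam_posterior(max_prob, k=16, n=100):
    """Posterior whose largest mean is approximately max_prob."""
    # choose counts so (1 + x) / (k + n) hits the target, the remaining
    # votes spread thinly over the other classes
    x = min(int(round(max_prob * (k + n) - 1)), n)
    rest = n - x
    others = [rest // (k - 1) + (1 if i < rest % (k - 1) else 0)
              for i in range(k - 1)]
    return dirichlet_multinomial_posterior(
        [x] + others, classes=tuple(f"fam{i}-RLP" for i in range(k))
    )


class TestDecide:
    def test_tm_absence_forces_nrlp(self):
        decision = decide(True, False, 0.99, 0.99, _subfam_posterior(0.8))
        assert decision.classification == "NRLP"

    def test_high_probability_receptor_call(self):
        post = _subfam_posterior(0.83)
        decision = decide(True, True, 0.996, 0.991, post)
        assert decision.classification == post.map_label

    def test_low_subfamily_probability_is_undefined(self):
        decision = decide(True, True, 0.95, 0.95, _subfam_posterior(0.42))
        assert decision.classification == "Undefined"

    def test_stage1_failure_forces_nrlp(self):
        decision = decide(True, True, 0.4, 0.99, _subfam_posterior(0.8))
        assert decision.classification == "NRLP"

    def test_sp_absence_does_not_veto(self):
        decision = decide(False, True, 0.99, 0.99, _subfam_posterior(0.8))
        assert decision.classification != "NRLP"

    def test_decision_probability_monotone_in_evidence(self):
        post_hi, post_lo = _subfam_posterior(0.8), _subfam_posterior(0.4)
        base = decide(False, True, 0.65, 0.65, post_lo).decision_probability
        for better in (
            decide(True, True, 0.65, 0.65, post_lo),
            decide(False, True, 0.99, 0.65, post_lo),
            decide(False, True, 0.65, 0.99, post_lo),
            decide(False, True, 0.65, 0.65, post_hi),
        ):
            assert better.decision_probability >= base

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(EnsembleError):
            decide(True, True, 1.0, 0.5, _subfam_posterior(0.8))


class TestMCMCOracle:
    """Conjugate closed forms vs the independent Metropolis sampler."""

    def test_beta_agreement(self):
        for i, (x, n) in enumerate([(0, 10), (5, 5), (13, 20), (40, 60)]):
            exact = beta_binomial_posterior([1] * x + [0] * (n - x)).mean
            estimate = mcmc_beta_posterior_mean(x, n, seed=100 + i)
            assert abs(estimate - exact) < 0.01

    def test_dirichlet_agreement(self):
        rng = np.random.default_rng(0)
        for i in range(4):
            counts = rng.integers(0, 40, size=int(rng.integers(2, 10)))
            exact = dirichlet_multinomial_posterior(counts).mean
            estimate = mcmc_dirichlet_posterior_mean(counts, seed=200 + i)
            assert np.abs(estimate - exact).max() < 0.01
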