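"""Conjugate Bayesian combination of member-classifier votes.

Each binary stage treats its member votes as n independent Bernoulli
trials with success probability pi; with a Beta(alpha0, beta0) prior the
posterior is Beta(alpha0 + x, beta0 + n - x) in closed form, and its mean
is the stage probability reported per sequence.  The subfamily stage
treats the per-class vote counts as one Multinomial draw; with a
Dirichlet prior the posterior is Dirichlet(alpha0 + x).

Posteriors are exact conjugate updates.  A vectorised random-walk
Metropolis sampler is included purely as an independent numerical
cross-check of the closed forms (it samples the same likelihood-times-
prior target without using conjugacy).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .dataset_builder import ClassScheme
from .models import MemberModel


class EnsembleError(ValueError):
    pass


@dataclass(frozen=True)
class StagePosterior:
    """Beta posterior over a binary stage's success probability."""

    x: int
    n: int
    alpha0: float = 1.0
    beta0: float = 1.0
    alpha: float = field(init=False)
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise EnsembleError("need at least one vote")
        if not 0 <= self.x <= self.n:
            raise EnsembleError("success count outside [0, n]")
        if self.alpha0 <= 0 or self.beta0 <= 0:
            raise EnsembleError("prior parameters must be positive")
        object.__setattr__(self, "alpha", self.alpha0 + self.x)
        object.__setattr__(self, "beta", self.beta0 + self.n - self.x)

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class SubfamilyPosterior:
    """Dirichlet posterior over subfamily probabilities."""

    counts: tuple[int, ...]
    classes: tuple[str, ...]
    alpha0: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.counts) < 2:
            raise EnsembleError("need at least two classes")
        if len(self.counts) != len(self.classes) or len(self.counts) != len(
            self.alpha0
        ):
            raise EnsembleError("counts/classes/prior length mismatch")
        if any(c < 0 for c in self.counts):
            raise EnsembleError("negative vote count")
        if any(a <= 0 for a in self.alpha0):
            raise EnsembleError("prior parameters must be positive")

    @property
    def N(self) -> int:
        return int(sum(self.counts))

    @property
    def alpha(self) -> np.ndarray:
        return np.asarray(self.alpha0) + np.asarray(self.counts)

    @property
    def mean(self) -> np.ndarray:
        alpha = self.alpha
        return alpha / alpha.sum()

    @property
    def map_label(self) -> str:
        return self.classes[int(np.argmax(self.mean))]

    @property
    def map_probability(self) -> float:
        return float(self.mean.max())


def beta_binomial_posterior(
    votes: Sequence[int], alpha0: float = 1.0, beta0: float = 1.0
) -> StagePosterior:
    """Closed-form Beta-Binomial update from a binary vote vector."""
    votes = np.asarray(votes)
    if votes.size == 0:
        raise EnsembleError("empty vote vector")
    if not np.isin(votes, (0, 1)).all():
        raise EnsembleError("votes must be 0/1")
    return StagePosterior(
        x=int(votes.sum()), n=int(votes.size), alpha0=alpha0, beta0=beta0
    )


def dirichlet_multinomial_posterior(
    counts: Sequence[int],
    classes: Optional[Sequence[str]] = None,
    alpha0: Optional[Sequence[float]] = None,
) -> SubfamilyPosterior:
    """Closed-form Dirichlet-Multinomial update from per-class vote counts."""
    counts = tuple(int(c) for c in counts)
    if classes is None:
        classes = tuple(f"class_{i}" for i in range(len(counts)))
    if alpha0 is None:
        alpha0 = tuple(1.0 for _ in counts)
    return SubfamilyPosterior(
        counts=counts, classes=tuple(classes), alpha0=tuple(alpha0)
    )


# ---------------------------------------------------------------------------
# voting


def _vector_for(member: MemberModel, feature_vectors_by_type: Mapping) -> np.ndarray:
    try:
        vec = feature_vectors_by_type[member.feature_type]
    except KeyError as exc:
        raise EnsembleError(
            f"no {member.feature_type!r} feature vector for member "
            f"{member.dataset_id}"
        ) from exc
    return np.asarray(vec, dtype=float).reshape(1, -1)


def stage_vote(
    members: Sequence[MemberModel],
    feature_vectors_by_type: Mapping,
    target_label: str,
) -> np.ndarray:
    """Binary vote vector: 1 where a member predicts ``target_label``.

    Member order follows the supplied roster (the bundle manifest order).
    """
    votes = np.empty(len(members), dtype=int)
    for i, member in enumerate(members):
        pred = member.predict(_vector_for(member, feature_vectors_by_type))[0]
        votes[i] = 1 if str(pred) == target_label else 0
    return votes


def subfamily_vote(
    members: Sequence[MemberModel],
    feature_vectors_by_type: Mapping,
    scheme: ClassScheme,
) -> np.ndarray:
    """Per-class vote counts in scheme order; sums to the member count."""
    counts = np.zeros(len(scheme.labels), dtype=int)
    position = {label: i for i, label in enumerate(scheme.labels)}
    for member in members:
        pred = str(member.predict(_vector_for(member, feature_vectors_by_type))[0])
        if pred not in position:
            raise EnsembleError(f"member predicted {pred!r}, not in scheme")
        counts[position[pred]] += 1
    return counts


# ---------------------------------------------------------------------------
# decision


@dataclass(frozen=True)
class Decision:
    """Final call for one sequence plus the evidence behind it."""

    classification: str  # subfamily label, "Undefined", or "NRLP"
    decision_probability: float
    evidence: dict


DEFAULT_CUTOFFS = {"c1": 0.6, "c2": 0.6, "c3": 0.7}
DEFAULT_WEIGHTS = (1.0, 1.0, 1.0, 1.0, 1.0)
DEFAULT_DECISION_PRIOR = (0.5, 0.5)


def decide(
    sp: bool,
    tm: bool,
    p1: float,
    p2: float,
    subfam_posterior: SubfamilyPosterior,
    cutoffs: Mapping[str, float] = DEFAULT_CUTOFFS,
    weights: Sequence[float] = DEFAULT_WEIGHTS,
    prior: Sequence[float] = DEFAULT_DECISION_PRIOR,
) -> Decision:
    """Apply the categorical decision rule and score the evidence.

    A sequence is NRLP when it lacks a TM segment or fails either binary
    stage's probability cutoff; Undefined when the stages pass but no
    subfamily reaches its cutoff; otherwise the maximum-posterior
    subfamily.  Signal-peptide absence does not veto (known receptor-like
    proteins lack predicted signal peptides); only TM absence does.

    The decision probability is the mean of a Beta posterior over the
    weighted 5-bit evidence vector (sp, tm, stage-1 pass, stage-2 pass,
    subfamily pass) — a single confidence summary, monotone in every
    piece of evidence.
    """
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise EnsembleError("stage probabilities must lie in (0, 1)")
    c1, c2, c3 = cutoffs["c1"], cutoffs["c2"], cutoffs["c3"]
    pass1 = p1 >= c1
    pass2 = p2 >= c2
    pass3 = subfam_posterior.map_probability >= c3
    if not tm or not pass1 or not pass2:
        classification = "NRLP"
    elif not pass3:
        classification = "Undefined"
    else:
        classification = subfam_posterior.map_label
    evidence_bits = (int(sp), int(tm), int(pass1), int(pass2), int(pass3))
    w = np.asarray(weights, dtype=float)
    if w.shape != (5,) or (w < 0).any():
        raise EnsembleError("weights must be 5 non-negative numbers")
    a0, b0 = prior
    a = a0 + float(np.dot(w, evidence_bits))
    b = b0 + float(np.dot(w, 1 - np.asarray(evidence_bits)))
    return Decision(
        classification=classification,
        decision_probability=a / (a + b),
        evidence={
            "sp": bool(sp),
            "tm": bool(tm),
            "stage1_pass": bool(pass1),
            "stage2_pass": bool(pass2),
            "stage3_pass": bool(pass3),
        },
    )


# ---------------------------------------------------------------------------
# MCMC cross-check (independent of the conjugate closed forms)


def mcmc_beta_posterior_mean(
    x: int,
    n: int,
    alpha0: float = 1.0,
    beta0: float = 1.0,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    chains: int = 4,
    seed: int = 0,
) -> float:
    """Posterior mean of pi via random-walk Metropolis on logit(pi).

    Samples Binomial(n, pi) likelihood x Beta(alpha0, beta0) prior without
    invoking conjugacy; the proposal scale is set from a delta-method
    estimate of the posterior spread.
    """
    rng = np.random.default_rng(seed)
    a, b = alpha0 + x, beta0 + n - x  # only for the proposal scale
    m = a / (a + b)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
    step = 2.4 * sd / max(m * (1 - m), 1e-6)
    step = min(step, 5.0)

    def log_post(z: np.ndarray) -> np.ndarray:
        # z = logit(pi); includes the Jacobian of the transform
        log_p = -np.logaddexp(0.0, -z)
        log_q = -np.logaddexp(0.0, z)
        return (x + alpha0) * log_p + (n - x + beta0) * log_q

    z = rng.normal(0.0, 1.0, size=chains)
    lp = log_post(z)
    total = np.zeros(chains)
    kept = 0
    for it in range(n_iter):
        prop = z + rng.normal(0.0, step, size=chains)
        lp_prop = log_post(prop)
        accept = np.log(rng.random(chains)) < lp_prop - lp
        z = np.where(accept, prop, z)
        lp = np.where(accept, lp_prop, lp)
        if it >= burn_in:
            total += 1.0 / (1.0 + np.exp(-z))
            kept += 1
    return float(total.mean() / kept)


def mcmc_dirichlet_posterior_mean(
    counts: Sequence[int],
    alpha0: Optional[Sequence[float]] = None,
    n_iter: int = 10_000,
    burn_in: int = 2_000,
    chains: int = 4,
    seed: int = 0,
) -> np.ndarray:
    """Posterior mean of theta via random-walk Metropolis in softmax space.

    The state is z in R^(k-1) with theta = softmax([z, 0]); under this
    transform the Multinomial x Dirichlet target becomes
    sum_i (x_i + alpha0_i) log theta_i (Jacobian included).  The proposal
    scale adapts toward ~25% acceptance during burn-in only.
    """
    counts = np.asarray(counts, dtype=float)
    k = counts.size
    if alpha0 is None:
        alpha0 = np.ones(k)
    alpha0 = np.asarray(alpha0, dtype=float)
    exponent = counts + alpha0  # (x_i + a0_i) per coordinate
    rng = np.random.default_rng(seed)

    def log_post(z: np.ndarray) -> np.ndarray:
        # z: (chains, k-1) -> theta: (chains, k)
        full = np.concatenate([z, np.zeros((z.shape[0], 1))], axis=1)
        log_theta = full - np.logaddexp.reduce(full, axis=1, keepdims=True)
        return log_theta @ exponent

    z = rng.normal(0.0, 0.5, size=(chains, k - 1))
    lp = log_post(z)
    step = 2.4 / np.sqrt(k - 1)
    theta_sum = np.zeros((chains, k))
    kept = 0
    acc_window: list[float] = []
    for it in range(n_iter):
        prop = z + rng.normal(0.0, step, size=z.shape)
        lp_prop = log_post(prop)
        accept = np.log(rng.random(chains)) < lp_prop - lp
        z[accept] = prop[accept]
        lp = np.where(accept, lp_prop, lp)
        if it < burn_in:
            acc_window.append(accept.mean())
            if len(acc_window) == 100:
                rate = float(np.mean(acc_window))
                if rate < 0.15:
                    step *= 0.7
                elif rate > 0.40:
                    step *= 1.4
                acc_window.clear()
        else:
            full = np.concatenate([z, np.zeros((chains, 1))], axis=1)
            e = np.exp(full - full.max(axis=1, keepdims=True))
            theta_sum += e / e.sum(axis=1, keepdims=True)
            kept += 1
    return theta_sum.mean(axis=0) / kept
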