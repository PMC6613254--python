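"""Probability computations for Leunbach's power-series score model.

A bounded integer total score ``X`` on a scale with maximum score ``m`` is
modelled by a power series distribution

    P(X = x | xi) = xi^x * gamma_x / sum_h xi^h * gamma_h,   x = 0..m,

where ``xi >= 0`` is a person parameter (trait level on a multiplicative
scale; ``theta = log(xi)`` is the familiar additive logit-type scale) and the
``gamma_x >= 0`` are score parameters playing the role Rasch item parameters
play for a polytomous "super item".  Two scales A and B measuring the same
trait share the person parameter; their total ``R = X1 + X2`` is again a
power series variable whose score parameters ``omega_r`` are the discrete
convolution of the two gamma vectors, and the split of ``R`` into ``(x, r-x)``
is independent of ``xi`` — the total score is sufficient for the person
parameter, which is what licenses conditional inference.

Everything here is computed on the log scale so that score ranges up to ~100
and extreme person parameters cannot overflow.  ``xi = 0`` and ``xi = inf``
are honoured as explicit limits (point masses at the boundary of the support).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoreParameterVector",
    "PersonParameter",
    "OmegaVector",
    "UnsupportedTotalScoreError",
    "score_pmf",
    "omega_convolution",
    "total_score_pmf",
    "joint_pmf",
    "conditional_split_pmf",
    "expected_score",
    "score_variance",
]


class UnsupportedTotalScoreError(ValueError):
    """Raised when conditioning on a total score with zero probability."""


@dataclass(frozen=True)
class ScoreParameterVector:
    """Score parameters ``gamma_0 .. gamma_m`` of one scale.

    Entries must be non-negative with at least one positive entry; zeros mark
    scores that can never be attained (e.g. raw scores absent from the sample
    when parameters were estimated by CML).
    """

    gamma: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gamma, dtype=float)
        if g.ndim != 1 or g.size == 0:
            raise ValueError("gamma must be a non-empty 1-d vector")
        if np.any(g < 0) or not np.all(np.isfinite(g)):
            raise ValueError("gamma entries must be finite and >= 0")
        if not np.any(g > 0):
            raise ValueError("gamma must have at least one positive entry")
        g = g.copy()
        g.setflags(write=False)
        object.__setattr__(self, "gamma", g)

    @property
    def max_score(self) -> int:
        """Theoretical maximum score ``m`` (length of gamma minus one)."""
        return self.gamma.size - 1

    @property
    def log_gamma(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.gamma)

    @property
    def min_support(self) -> int:
        """Smallest score with positive gamma."""
        return int(np.flatnonzero(self.gamma > 0)[0])

    @property
    def max_support(self) -> int:
        """Largest score with positive gamma."""
        return int(np.flatnonzero(self.gamma > 0)[-1])

    @property
    def scores(self) -> np.ndarray:
        return np.arange(self.gamma.size)

    def rescaled(self, b: float = 1.0, a: float = 1.0) -> "ScoreParameterVector":
        """Return gamma_x -> b * a^x * gamma_x (the model's invariance class)."""
        if b <= 0 or a <= 0:
            raise ValueError("rescaling constants must be positive")
        return ScoreParameterVector(b * a ** self.scores * self.gamma)


@dataclass(frozen=True)
class PersonParameter:
    """Person parameter on the additive scale ``theta = log(xi)``.

    ``theta = -inf`` (xi = 0) and ``theta = +inf`` are valid limits giving
    point masses at the lowest / highest attainable score.
    """

    theta: float

    @classmethod
    def from_xi(cls, xi: float) -> "PersonParameter":
        if xi < 0 or math.isnan(xi):
            raise ValueError("xi must be >= 0")
        return cls(theta=-math.inf if xi == 0 else math.log(xi))

    @property
    def xi(self) -> float:
        return math.exp(self.theta) if self.theta < math.inf else math.inf


@dataclass(frozen=True)
class OmegaVector:
    """Score parameters ``omega_r`` of the total ``R = X1 + X2``.

    ``omega_r = sum_x gamma_{1x} * gamma_{2,r-x}`` — the discrete convolution
    of the two scales' gamma vectors, indexed by r = 0..m1+m2.
    """

    omega: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.omega, dtype=float)
        w = w.copy()
        w.setflags(write=False)
        object.__setattr__(self, "omega", w)

    @property
    def max_total(self) -> int:
        return self.omega.size - 1

    def as_params(self) -> ScoreParameterVector:
        """View the combined instrument as one power-series scale."""
        return ScoreParameterVector(self.omega)


def _point_mass(size: int, index: int) -> np.ndarray:
    p = np.zeros(size)
    p[index] = 1.0
    return p


def _log_weight_pmf(log_gamma: np.ndarray, theta: float) -> np.ndarray:
    """Normalize exp(x*theta + log gamma_x) stably; -inf entries get mass 0."""
    logw = np.arange(log_gamma.size) * theta + log_gamma
    w = np.exp(logw - logw.max())
    return w / w.sum()


def score_pmf(params: ScoreParameterVector, person: PersonParameter) -> np.ndarray:
    """P(X = x | xi) for x = 0..m, as a vector summing to one."""
    if person.theta == -math.inf:
        return _point_mass(params.gamma.size, params.min_support)
    if person.theta == math.inf:
        return _point_mass(params.gamma.size, params.max_support)
    return _log_weight_pmf(params.log_gamma, person.theta)


def omega_convolution(
    params_a: ScoreParameterVector, params_b: ScoreParameterVector
) -> OmegaVector:
    """Convolve the two gamma vectors into the total-score parameters."""
    return OmegaVector(np.convolve(params_a.gamma, params_b.gamma))


def total_score_pmf(omega: OmegaVector, person: PersonParameter) -> np.ndarray:
    """P(X1 + X2 = r | xi) for r = 0..m1+m2."""
    return score_pmf(omega.as_params(), person)


def joint_pmf(
    params_a: ScoreParameterVector,
    params_b: ScoreParameterVector,
    person: PersonParameter,
) -> np.ndarray:
    """Joint P(X1 = x1, X2 = x2 | xi) as an (m1+1) x (m2+1) matrix.

    Under conditional independence given xi this is the outer product of the
    two marginal pmfs.
    """
    return np.outer(score_pmf(params_a, person), score_pmf(params_b, person))


def conditional_split_pmf(
    params_a: ScoreParameterVector,
    params_b: ScoreParameterVector,
    r: int,
) -> np.ndarray:
    """P(X1 = x | R = r) for x = 0..m1 — free of the person parameter.

    The vector has zeros outside the feasible split range
    ``max(0, r-m2) .. min(r, m1)``; within it the mass is proportional to
    ``gamma_{1x} * gamma_{2,r-x}``.

    Raises
    ------
    UnsupportedTotalScoreError
        If ``omega_r = 0`` (the total score r cannot occur under the model).
    """
    m1, m2 = params_a.max_score, params_b.max_score
    if not 0 <= r <= m1 + m2:
        raise UnsupportedTotalScoreError(f"total score {r} outside 0..{m1 + m2}")
    x = np.arange(max(0, r - m2), min(r, m1) + 1)
    w = params_a.gamma[x] * params_b.gamma[r - x]
    total = w.sum()
    if total <= 0:
        raise UnsupportedTotalScoreError(f"omega_{r} = 0: total score {r} unsupported")
    p = np.zeros(m1 + 1)
    p[x] = w / total
    return p


def expected_score(params: ScoreParameterVector, person: PersonParameter) -> float:
    """Expected score E(X | xi) — the test characteristic curve at theta.

    Strictly increasing in theta for non-degenerate gamma, with limits
    ``min_support`` (theta -> -inf) and ``max_support`` (theta -> +inf).
    """
    if person.theta == -math.inf:
        return float(params.min_support)
    if person.theta == math.inf:
        return float(params.max_support)
    p = _log_weight_pmf(params.log_gamma, person.theta)
    return float(p @ params.scores)


def score_variance(params: ScoreParameterVector, person: PersonParameter) -> float:
    """Var(X | xi); the derivative of the TCC with respect to theta."""
    if not math.isfinite(person.theta):
        return 0.0
    p = _log_weight_pmf(params.log_gamma, person.theta)
    mu = p @ params.scores
    return float(p @ (params.scores - mu) ** 2)
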