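"""Synthetic score data with (and without) the structure the model assumes.

The generator emulates the kind of data the equating machinery targets: two
(or three) bounded integer total scores per respondent from cross-sectional
self-report instruments — score ranges like 0-24 (ESS-shaped), 0-12 or up to
0-108 — driven by a shared latent trait.  Person parameters theta are drawn
from a normal distribution (the conventional choice in Rasch simulation;
conditional estimation is free of any person-distribution assumption, so the
choice is a generator convention, not a model assumption) and scores are
sampled conditionally independently from the power-series distributions.

Controlled violations for power studies come in two families.  Person-level
trait divergence: a two-trait variant draws (theta_1, theta_2) from a
bivariate normal with given correlation (1 = unidimensional = the exact
model), optionally with a scale factor on theta_2 emulating logit scales
with different units.  A caveat worth knowing: with normal traits these
mechanisms are largely invisible to conditional inference — the Gaussian
moment structure exp(sigma^2 (x^2 + y^2 + 2 rho x y) / 2) factorizes into
row x column x diagonal terms, which is exactly the family the conditional
model spans — so the fit tests stay near their nominal level even at
correlation 0.  Local dependence between the scores themselves is what the
conditional tests can see: ``copy_rate`` (a person's B score is transposed
directly from their A score, emulating shared or near-duplicate items) and
``careless_rate`` (the B score is replaced by a uniform draw, emulating
careless responding).

Scales can be specified by their gamma vectors directly or built from
partial-credit Rasch items (thresholds), whose summed scores follow the
power-series model by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ScoreParameterVector
from .estimation import ScoreContingencyTable

__all__ = [
    "SimulationScenario",
    "gamma_from_thresholds",
    "simulate_table",
    "simulate_misfit_table",
    "simulate_scores",
    "simulate_from_rasch_items",
]


@dataclass(frozen=True)
class SimulationScenario:
    """Study conditions for one synthetic two-scale (or three-scale) sample.

    ``trait_correlation = 1`` reproduces the exact unidimensional model;
    values below 1 generate misfit.  ``theta_scale_b`` rescales the second
    trait (different logit units), another misfit mechanism.
    """

    gamma_a: ScoreParameterVector
    gamma_b: ScoreParameterVector
    gamma_c: ScoreParameterVector | None = None
    n: int = 722
    mu: float = 0.0
    sigma: float = 1.0
    trait_correlation: float = 1.0
    theta_scale_b: float = 1.0
    copy_rate: float = 0.0
    careless_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not 0 <= self.trait_correlation <= 1:
            raise ValueError("trait_correlation must lie in [0, 1]")
        for rate in (self.copy_rate, self.careless_rate):
            if not 0 <= rate <= 1:
                raise ValueError("contamination rates must lie in [0, 1]")

    @property
    def is_null(self) -> bool:
        """True when the scenario follows the exact unidimensional model."""
        return (
            self.trait_correlation == 1.0
            and self.theta_scale_b == 1.0
            and self.copy_rate == 0.0
            and self.careless_rate == 0.0
        )


def gamma_from_thresholds(items: list[list[float]]) -> ScoreParameterVector:
    """Score parameters of a sum of partial-credit items given thresholds.

    Each item with thresholds ``(tau_1 .. tau_k)`` has category weights
    ``g_c = exp(-sum_{j<=c} tau_j)`` (g_0 = 1); the scale's gamma vector is
    the convolution of its items' weight vectors.
    """
    if not items:
        raise ValueError("need at least one item")
    gamma = np.ones(1)
    for thresholds in items:
        t = np.asarray(thresholds, dtype=float)
        if t.size < 1:
            raise ValueError("each item needs at least one threshold")
        g = np.exp(-np.concatenate(([0.0], np.cumsum(t))))
        gamma = np.convolve(gamma, g)
    return ScoreParameterVector(gamma)


def _sample_scores(
    params: ScoreParameterVector, thetas: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Sample one score per person from the power-series pmf at their theta."""
    x = np.arange(params.gamma.size)
    logw = thetas[:, None] * x[None, :] + params.log_gamma[None, :]
    logw -= logw.max(axis=1, keepdims=True)
    w = np.exp(logw)
    cdf = np.cumsum(w, axis=1)
    cdf /= cdf[:, -1:]
    u = rng.random(thetas.size)
    return (u[:, None] > cdf).sum(axis=1).astype(np.int64)


def _draw_thetas(
    scenario: SimulationScenario, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    rho = scenario.trait_correlation
    z1 = rng.standard_normal(scenario.n)
    if rho == 1.0:
        z2 = z1
    else:
        z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal(scenario.n)
    t1 = scenario.mu + scenario.sigma * z1
    t2 = (scenario.mu + scenario.sigma * z2) * scenario.theta_scale_b
    return t1, t2


def simulate_scores(scenario: SimulationScenario) -> pd.DataFrame:
    """Per-person wide score data frame (columns A, B and optionally C).

    All scales share the first trait except scale B, which uses the second
    (identical when ``trait_correlation = 1`` and ``theta_scale_b = 1``).
    """
    rng = np.random.default_rng(scenario.seed)
    t1, t2 = _draw_thetas(scenario, rng)
    scores_a = _sample_scores(scenario.gamma_a, t1, rng)
    scores_b = _sample_scores(scenario.gamma_b, t2, rng)
    m_a = scenario.gamma_a.max_score
    m_b = scenario.gamma_b.max_score
    if scenario.copy_rate > 0:
        copied = rng.random(scenario.n) < scenario.copy_rate
        scores_b[copied] = np.round(scores_a[copied] * m_b / m_a).astype(np.int64)
    if scenario.careless_rate > 0:
        careless = rng.random(scenario.n) < scenario.careless_rate
        scores_b[careless] = rng.integers(0, m_b + 1, careless.sum())
    data = {"A": scores_a, "B": scores_b}
    if scenario.gamma_c is not None:
        data["C"] = _sample_scores(scenario.gamma_c, t1, rng)
    df = pd.DataFrame(data)
    df.index.name = "person"
    return df


def simulate_table(scenario: SimulationScenario) -> ScoreContingencyTable:
    """Simulate a two-way (A, B) score table under the exact model."""
    if not scenario.is_null:
        raise ValueError("use simulate_misfit_table for scenarios with a violation")
    return _to_table(scenario)


def simulate_misfit_table(scenario: SimulationScenario) -> ScoreContingencyTable:
    """Simulate a table under one of the controlled model violations."""
    if scenario.is_null:
        raise ValueError("scenario has no misfit mechanism; use simulate_table")
    return _to_table(scenario)


def _to_table(scenario: SimulationScenario) -> ScoreContingencyTable:
    df = simulate_scores(scenario)
    return ScoreContingencyTable.from_scores(
        df["A"].to_numpy(),
        df["B"].to_numpy(),
        max_a=scenario.gamma_a.max_score,
        max_b=scenario.gamma_b.max_score,
    )


def simulate_from_rasch_items(
    items_a: list[list[float]],
    items_b: list[list[float]],
    n: int = 722,
    mu: float = 0.0,
    sigma: float = 1.0,
    seed: int | None = None,
) -> ScoreContingencyTable:
    """Simulate item-level partial-credit responses and sum them per scale.

    Equivalent in distribution to ``simulate_table`` with the gamma vectors
    implied by the thresholds (the power-series property of Rasch totals);
    fit tests on such data should accept at nominal rates.
    """
    rng = np.random.default_rng(seed)
    thetas = mu + sigma * rng.standard_normal(n)
    scores = []
    for items in (items_a, items_b):
        if not items:
            raise ValueError("each scale needs at least one item")
        total = np.zeros(n, dtype=np.int64)
        for thresholds in items:
            item_params = gamma_from_thresholds([thresholds])
            total += _sample_scores(item_params, thetas, rng)
        scores.append(total)
    max_a = sum(len(t) for t in items_a)
    max_b = sum(len(t) for t in items_b)
    return ScoreContingencyTable.from_scores(
        scores[0], scores[1], max_a=max_a, max_b=max_b
    )
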