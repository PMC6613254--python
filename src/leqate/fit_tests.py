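"""Tests of fit of the Leunbach model to a two-way score table.

Three tests are used, mirroring the multidimensionality checks familiar from
Rasch analysis:

1. a conditional likelihood ratio test (G2) comparing observed and expected
   counts given the total score, with a parametric-bootstrap p-value (score
   tables are typically large and sparse, so the asymptotic chi-square
   reference is not trusted);
2. a comparison of the observed Goodman-Kruskal gamma correlation of the two
   scores with its expected value under the model — the discrepancy
   observed-minus-expected is referred to its parametric-bootstrap null
   distribution, two-sided;
3. a count of persons whose two scores depart significantly (5% level) from
   each other under the model.  The standalone operation reports an
   asymptotic chi-square p-value for the flagged proportion exceeding the
   model-implied flag probability; in the assembled report the count is
   instead referred to its parametric-bootstrap null distribution, because
   the flags depend on the fitted model and the asymptotic reference is
   badly conservative.

Following the convention of Cox & Snell, only p <= 0.01 — or more than one
test significant at 5% — is treated as strong evidence against the model.

The parametric bootstrap conditions on the observed total-score counts n_r:
each pseudo-table redistributes the n_r persons over the splits of diagonal
r according to the fitted conditional distribution, consistent with the
conditional-inference framing (no person-distribution assumption enters).
The model is refitted on every bootstrap table before G2 is evaluated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict
from typing import Iterator, Literal

import numpy as np
from scipy import stats

from .estimation import LeunbachFit, ScoreContingencyTable, fit_cml

__all__ = [
    "FitReport",
    "MisfitResult",
    "conditional_lrt",
    "expected_counts",
    "goodman_kruskal_gamma",
    "parametric_bootstrap_tables",
    "bootstrap_p",
    "person_misfit_test",
    "run_fit_tests",
]

logger = logging.getLogger(__name__)


def expected_counts(fit: LeunbachFit, r_counts: np.ndarray) -> np.ndarray:
    """Fitted conditional expected counts n_r * P(x, r-x | r) per cell."""
    m1 = fit.params_a.gamma.size
    m2 = fit.params_b.gamma.size
    exp = np.zeros((m1, m2))
    for r in np.flatnonzero(r_counts[: m1 + m2 - 1]):
        x = np.arange(max(0, r - (m2 - 1)), min(r, m1 - 1) + 1)
        try:
            p = fit.conditional_split(int(r))[x]
        except Exception:
            continue
        exp[x, r - x] = r_counts[r] * p
    return exp


def conditional_lrt(
    table: ScoreContingencyTable,
    fit: LeunbachFit,
    expected: np.ndarray | None = None,
) -> float:
    """G2 = 2 sum_{cells with obs>0} obs * ln(obs/exp), exp conditional on r."""
    obs = table.counts.astype(float)
    exp = expected_counts(fit, table.total_margin) if expected is None else expected
    pos = obs > 0
    if np.any(pos & (exp <= 0)):
        logger.warning("observed count in a cell with zero fitted expectation")
        return math.inf
    return float(2.0 * np.sum(obs[pos] * np.log(obs[pos] / exp[pos])))


def goodman_kruskal_gamma(counts: np.ndarray) -> float:
    """Goodman-Kruskal gamma (C - D) / (C + D) of an ordinal two-way table.

    Returns NaN when there are no untied pairs (C + D = 0).
    Accepts real-valued tables (used for the model-expected table).
    """
    c = np.asarray(counts, dtype=float)
    if c.sum() < 2:
        raise ValueError("need at least two observations")
    # tail[x, y] = sum over x' > x, y' > y
    cum = np.cumsum(np.cumsum(c[::-1, ::-1], axis=0), axis=1)[::-1, ::-1]
    gt = np.zeros_like(c)
    gt[:-1, :-1] = cum[1:, 1:]
    # lower tail in y: sum over x' > x, y' < y
    cum_lo = np.cumsum(np.cumsum(c[::-1, :], axis=0), axis=1)[::-1, :]
    dt = np.zeros_like(c)
    dt[:-1, 1:] = cum_lo[1:, :-1]
    concordant = float(np.sum(c * gt))
    discordant = float(np.sum(c * dt))
    denom = concordant + discordant
    if denom == 0:
        return math.nan
    return (concordant - discordant) / denom


def parametric_bootstrap_tables(
    fit: LeunbachFit,
    r_counts: np.ndarray,
    n_tables: int,
    seed: int | np.random.Generator | None = None,
) -> Iterator[ScoreContingencyTable]:
    """Simulate tables from the fitted conditional model, holding n_r fixed.

    Each generated table has exactly the observed total-score counts; within
    diagonal r the n_r splits are drawn from the fitted P(x | r).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    m1 = fit.params_a.gamma.size
    m2 = fit.params_b.gamma.size
    active = [
        (int(r), fit.conditional_split(int(r)))
        for r in np.flatnonzero(r_counts[: m1 + m2 - 1])
    ]
    for _ in range(n_tables):
        counts = np.zeros((m1, m2), dtype=np.int64)
        for r, p in active:
            draws = rng.multinomial(int(r_counts[r]), p)
            x = np.flatnonzero(draws)
            counts[x, r - x] += draws[x]
        yield ScoreContingencyTable(counts, fit.scale_names)


def bootstrap_p(
    observed_stat: float,
    bootstrap_stats: np.ndarray,
    direction: Literal["greater", "two_sided"] = "greater",
) -> float:
    """Bootstrap p-value with the (1 + #extreme) / (S + 1) convention.

    ``greater`` counts bootstrap statistics >= the observed one (upper-tail
    statistics such as G2); ``two_sided`` compares absolute deviations from
    the bootstrap mean.  NaN bootstrap values are dropped.
    """
    boots = np.asarray(bootstrap_stats, dtype=float)
    boots = boots[~np.isnan(boots)]
    if boots.size == 0:
        raise ValueError("need at least one bootstrap statistic")
    if direction == "greater":
        extreme = np.sum(boots >= observed_stat - 1e-12)
    elif direction == "two_sided":
        center = boots.mean()
        extreme = np.sum(np.abs(boots - center) >= abs(observed_stat - center) - 1e-12)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    return float((1 + extreme) / (boots.size + 1))


@dataclass(frozen=True)
class MisfitResult:
    """Outcome of the person-misfit count test.

    ``null_proportion`` is the model-implied flag probability: the exact
    chance, under the fitted conditional distributions, that a person is
    flagged at the chosen level.  On discrete supports it sits somewhat
    below the nominal level, so the significance test compares the observed
    proportion against it rather than against the nominal level.
    """

    count: int
    proportion: float
    ci_low: float
    ci_high: float
    p: float
    null_proportion: float


def person_misfit_test(
    table: ScoreContingencyTable,
    fit: LeunbachFit,
    level: float = 0.05,
    method: Literal["midp", "exact"] = "midp",
) -> MisfitResult:
    """Count persons whose score split is significantly unlikely given r.

    For each person (cell) the split x of the total r is tested with a
    two-sided conditional exact test ordered by probability: splits no more
    probable than the observed one form the tail.  ``midp`` (default) gives
    half weight to splits exactly as probable as the observed one, which
    calibrates the flag rate close to the nominal level on discrete
    supports; ``exact`` includes them fully (conservative).

    Returns the flagged count, proportion, a 95% Wald interval, the exact
    model-implied flag probability, and a one-sided chi-square p-value for
    the observed proportion exceeding it (p = 1 when it does not).
    """
    counts = table.counts
    m1, m2 = counts.shape
    flagged = 0
    null_mass = 0.0  # expected number of flagged persons under the fit
    for r in np.flatnonzero(table.total_margin):
        x = np.arange(max(0, r - (m2 - 1)), min(r, m1 - 1) + 1)
        obs = counts[x, r - x]
        if obs.sum() == 0:
            continue
        p = fit.conditional_split(int(r))[x]
        # probability-ordering tail of each possible split, ties grouped
        uniq, inverse = np.unique(np.round(p / (p.max() + 1e-300), 12), return_inverse=True)
        group_mass = np.bincount(inverse, weights=p)
        below = np.concatenate(([0.0], np.cumsum(group_mass)[:-1]))
        if method == "midp":
            tail = (below + 0.5 * group_mass)[inverse]
        else:
            tail = (below + group_mass)[inverse]
        flag = tail <= level + 1e-12
        flagged += int(obs[flag].sum())
        null_mass += float(table.total_margin[r]) * float(p[flag].sum())
    n = table.n
    prop = flagged / n
    pi0 = null_mass / n
    half = 1.959963984540054 * math.sqrt(max(prop * (1 - prop), 0.0) / n)
    if prop > pi0 and 0 < pi0 < 1:
        x2 = n * (prop - pi0) ** 2 / (pi0 * (1 - pi0))
        p_value = 0.5 * float(stats.chi2.sf(x2, df=1))
    else:
        p_value = 1.0
    return MisfitResult(
        count=flagged,
        proportion=prop,
        ci_low=prop - half,
        ci_high=prop + half,
        p=p_value,
        null_proportion=pi0,
    )


@dataclass(frozen=True)
class FitReport:
    """The three fit-test results and the overall verdict.

    ``verdict`` follows the p <= 0.01 strong-evidence convention: strong
    evidence against the model iff any p <= 0.01 or at least two of the
    three tests are significant at 5%; moderate evidence iff exactly one
    p lies in (0.01, 0.05]; otherwise the model is considered to fit.
    """

    lrt_statistic: float
    lrt_p: float
    gamma_observed: float
    gamma_expected: float
    gamma_p: float
    misfit_count: int
    misfit_proportion: float
    misfit_ci: tuple[float, float]
    misfit_null_proportion: float
    misfit_p: float
    n_bootstrap: int
    seed: int | None
    verdict: str

    def to_dict(self) -> dict:
        d = asdict(self)
        d["misfit_ci"] = list(self.misfit_ci)
        return d


def _verdict(p_values: list[float]) -> str:
    strong = any(p <= 0.01 for p in p_values)
    sig5 = sum(p <= 0.05 for p in p_values)
    if strong or sig5 >= 2:
        return "strong_evidence_against"
    if sum(0.01 < p <= 0.05 for p in p_values) == 1:
        return "moderate_evidence"
    return "fit"


def run_fit_tests(
    table: ScoreContingencyTable,
    fit: LeunbachFit | None = None,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    refit_tolerance: float = 1e-8,
    misfit_method: Literal["midp", "exact"] = "midp",
) -> FitReport:
    """Run all three fit tests and assemble a report.

    ``n_bootstrap`` is the number S of parametric bootstrap tables (the
    reported runs use S = 1000; S = 199 is adequate for screening).  Each
    bootstrap table is refitted (warm-started from the original fit) before
    its G2 and expected-gamma are computed, so both bootstrap null
    distributions reflect the estimation step.
    """
    if fit is None:
        fit = fit_cml(table)
    if not fit.converged:
        logger.warning("running fit tests on a non-converged fit")

    g2_obs = conditional_lrt(table, fit)
    gamma_obs = goodman_kruskal_gamma(table.counts)
    gamma_exp = goodman_kruskal_gamma(expected_counts(fit, table.total_margin))
    # the gamma statistic is the observed-minus-expected discrepancy; its null
    # distribution must include the estimation step, hence the per-table refit
    gamma_disc_obs = gamma_obs - gamma_exp

    rng = np.random.default_rng(seed)
    g2_boot = np.empty(n_bootstrap)
    gamma_boot = np.empty(n_bootstrap)
    misfit_boot = np.empty(n_bootstrap)
    warm = (fit.params_a, fit.params_b)
    for i, boot_table in enumerate(
        parametric_bootstrap_tables(fit, table.total_margin, n_bootstrap, rng)
    ):
        boot_fit = fit_cml(
            boot_table, tolerance=refit_tolerance, normalization="raw", init=warm
        )
        boot_exp = expected_counts(boot_fit, boot_table.total_margin)
        g2_boot[i] = conditional_lrt(boot_table, boot_fit, expected=boot_exp)
        gamma_boot[i] = goodman_kruskal_gamma(
            boot_table.counts
        ) - goodman_kruskal_gamma(boot_exp)
        misfit_boot[i] = person_misfit_test(
            boot_table, boot_fit, method=misfit_method
        ).count

    lrt_p = bootstrap_p(g2_obs, g2_boot, "greater") if n_bootstrap else math.nan
    gamma_p = (
        bootstrap_p(gamma_disc_obs, gamma_boot, "two_sided")
        if n_bootstrap and not math.isnan(gamma_disc_obs)
        else math.nan
    )
    misfit = person_misfit_test(table, fit, method=misfit_method)
    # the count statistic is also referred to its parametric-bootstrap null
    # distribution: the flags depend on the fitted model, which makes any
    # asymptotic reference for the count badly conservative
    misfit_p = (
        bootstrap_p(float(misfit.count), misfit_boot, "greater")
        if n_bootstrap
        else misfit.p
    )
    verdict = _verdict(
        [p for p in (lrt_p, gamma_p, misfit_p) if not math.isnan(p)]
    )
    return FitReport(
        lrt_statistic=g2_obs,
        lrt_p=lrt_p,
        gamma_observed=gamma_obs,
        gamma_expected=gamma_exp,
        gamma_p=gamma_p,
        misfit_count=misfit.count,
        misfit_proportion=misfit.proportion,
        misfit_ci=(misfit.ci_low, misfit.ci_high),
        misfit_null_proportion=misfit.null_proportion,
        misfit_p=misfit_p,
        n_bootstrap=n_bootstrap,
        seed=seed,
        verdict=verdict,
    )
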