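"""Conditional maximum likelihood estimation of score parameters.

Persons contribute only through the two-way table of their (score on A,
score on B) pairs.  Conditionally on each total score ``r = x1 + x2`` the
split follows ``P(x, r-x | r) = gamma_{1x} gamma_{2,r-x} / omega_r``, so the
conditional likelihood is that of a quasi-independence loglinear model with
row effects (gamma_1), column effects (gamma_2) and a free stratum factor per
total-score diagonal.  Its MLE is computed by iterative proportional fitting
over the three margins (rows, columns, diagonals); at convergence the fitted
conditional expected counts match the observed row and column margins within
every diagonal.

The conditional likelihood identifies gamma only up to one multiplicative
constant per scale and a common geometric tilt ``a^x`` (absorbed by the
diagonal factors).  Neither affects conditional probabilities nor equating;
the reported parameters are normalized so that the first supported gamma of
each scale is 1 and, under the default "centered" convention, so that the
mean person estimate over observed interior total scores is 0.

Person parameters are estimated from a single score by maximum likelihood:
the MLE solves "expected score = observed score" and is found by safeguarded
Newton-Raphson on theta with bisection fallback.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import (
    OmegaVector,
    PersonParameter,
    ScoreParameterVector,
    conditional_split_pmf,
    expected_score,
    omega_convolution,
    score_variance,
)

__all__ = [
    "ScoreContingencyTable",
    "LeunbachFit",
    "ExtremeScoreError",
    "DegenerateTableError",
    "fit_cml",
    "conditional_loglik",
    "person_mle",
]

logger = logging.getLogger(__name__)


class ExtremeScoreError(ValueError):
    """Signals a score at (or outside) the support boundary: no finite MLE."""


class DegenerateTableError(ValueError):
    """Raised for tables that carry no conditional information at all."""


@dataclass(frozen=True)
class ScoreContingencyTable:
    """Observed joint counts of (score on A, score on B) over common persons.

    Rows index the score on scale A (0..m1), columns the score on B (0..m2).
    """

    counts: np.ndarray
    scale_names: tuple[str, str] = ("A", "B")
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2:
            raise ValueError("counts must be a 2-d matrix")
        if np.any(c < 0) or np.any(c != np.floor(c)):
            raise ValueError("counts must be non-negative integers")
        c = c.astype(np.int64)
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        object.__setattr__(self, "scale_names", tuple(self.scale_names))

    @classmethod
    def from_scores(
        cls,
        scores_a: np.ndarray,
        scores_b: np.ndarray,
        max_a: int | None = None,
        max_b: int | None = None,
        scale_names: tuple[str, str] = ("A", "B"),
    ) -> "ScoreContingencyTable":
        """Cross-tabulate per-person score pairs into a table."""
        a = np.asarray(scores_a, dtype=np.int64)
        b = np.asarray(scores_b, dtype=np.int64)
        if a.shape != b.shape or a.ndim != 1:
            raise ValueError("scores_a and scores_b must be equal-length vectors")
        ma = int(a.max()) if max_a is None else int(max_a)
        mb = int(b.max()) if max_b is None else int(max_b)
        if a.min() < 0 or b.min() < 0 or a.max() > ma or b.max() > mb:
            raise ValueError("scores outside declared 0..max range")
        counts = np.zeros((ma + 1, mb + 1), dtype=np.int64)
        np.add.at(counts, (a, b), 1)
        return cls(counts, scale_names)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def row_margin(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margin(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total_score_index(self) -> np.ndarray:
        """Matrix of r = x1 + x2 per cell."""
        m1, m2 = self.counts.shape
        return np.add.outer(np.arange(m1), np.arange(m2))

    @property
    def total_margin(self) -> np.ndarray:
        """Counts n_r of each total score r = 0..m1+m2."""
        cached = self._cache.get("total_margin")
        if cached is None:
            r = self.total_score_index
            cached = np.bincount(
                r.ravel(), weights=self.counts.ravel(), minlength=r.max() + 1
            ).astype(np.int64)
            self._cache["total_margin"] = cached
        return cached


@dataclass(frozen=True)
class LeunbachFit:
    """CML-fitted score parameters for a pair of scales.

    ``omega`` is the convolution of the two fitted gamma vectors;
    ``margin_a``/``margin_b`` keep the observed score frequencies (the weights
    used downstream in equating); ``normalization`` records the
    identifiability convention applied.
    """

    params_a: ScoreParameterVector
    params_b: ScoreParameterVector
    omega: OmegaVector
    scale_names: tuple[str, str]
    margin_a: np.ndarray
    margin_b: np.ndarray
    total_margin: np.ndarray
    normalization: dict
    converged: bool
    identifiable: bool
    iterations: int
    max_change: float
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def observed_scores_a(self) -> np.ndarray:
        return np.flatnonzero(self.margin_a)

    @property
    def observed_scores_b(self) -> np.ndarray:
        return np.flatnonzero(self.margin_b)

    @property
    def n(self) -> int:
        return int(self.total_margin.sum())

    def scale_index(self, scale: str) -> int:
        """Resolve a scale name (or the positional aliases 'a'/'b') to 0/1.

        Exact scale names take precedence over the aliases.
        """
        if scale in self.scale_names:
            return self.scale_names.index(scale)
        if scale in ("a", "A"):
            return 0
        if scale in ("b", "B"):
            return 1
        raise KeyError(f"unknown scale {scale!r}; fit has {self.scale_names}")

    def params(self, scale: str) -> ScoreParameterVector:
        """Score parameters for a scale given by name (or 'a'/'b')."""
        return (self.params_a, self.params_b)[self.scale_index(scale)]

    def conditional_split(self, r: int) -> np.ndarray:
        """Fitted P(X1 = x | R = r) over x = 0..m1 (memoized per fit)."""
        cached = self._cache.get(r)
        if cached is None:
            cached = conditional_split_pmf(self.params_a, self.params_b, r)
            self._cache[r] = cached
        return cached


def _support_mask(table: ScoreContingencyTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cells estimable under CML: observed row, observed column, observed diagonal."""
    row_obs = table.row_margin
    col_obs = table.col_margin
    tot_obs = table.total_margin
    r_idx = table.total_score_index
    mask = (
        (row_obs[:, None] > 0) & (col_obs[None, :] > 0) & (tot_obs[r_idx] > 0)
    )
    return mask, r_idx, tot_obs


def _informative_diagonals(mask: np.ndarray, r_idx: np.ndarray, tot_obs: np.ndarray) -> np.ndarray:
    """Total scores whose diagonal admits more than one estimable split."""
    cells_per_r = np.bincount(r_idx.ravel(), weights=mask.ravel(), minlength=tot_obs.size)
    return np.flatnonzero((tot_obs > 0) & (cells_per_r >= 2))


def _ipf_cycles_numpy(
    m: np.ndarray,
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    row_obs: np.ndarray,
    col_obs: np.ndarray,
    tot_obs: np.ndarray,
    mask: np.ndarray,
    tolerance: float,
    max_iterations: int,
) -> tuple[int, float]:
    """Pure-numpy IPF over the three margins (rows, columns, diagonals).

    Updates m and the factors a, b, c in place; returns (cycles, max change
    in fitted conditional split probabilities over the final cycle).
    """
    n1, n2 = m.shape
    r_idx = np.add.outer(np.arange(n1), np.arange(n2))
    sup_a = row_obs > 0
    sup_b = col_obs > 0
    safe_tot = np.where(tot_obs > 0, tot_obs, 1.0)
    prev_p = np.where(mask, m / safe_tot[r_idx], 0.0)
    max_change = math.inf
    iterations = 0
    for iterations in range(1, max_iterations + 1):
        row_fit = m.sum(axis=1)
        fa = np.where(
            sup_a & (row_fit > 0), row_obs / np.where(row_fit > 0, row_fit, 1.0), 1.0
        )
        a *= fa
        m *= fa[:, None]

        col_fit = m.sum(axis=0)
        fb = np.where(
            sup_b & (col_fit > 0), col_obs / np.where(col_fit > 0, col_fit, 1.0), 1.0
        )
        b *= fb
        m *= fb[None, :]

        tot_fit = np.bincount(r_idx.ravel(), weights=m.ravel(), minlength=tot_obs.size)
        fc = np.where(
            (tot_obs > 0) & (tot_fit > 0),
            tot_obs / np.where(tot_fit > 0, tot_fit, 1.0),
            1.0,
        )
        c *= fc
        m *= fc[r_idx]

        p = np.where(mask, m / safe_tot[r_idx], 0.0)
        max_change = float(np.max(np.abs(p - prev_p))) if p.size else 0.0
        prev_p = p
        if max_change <= tolerance:
            break
        if iterations % 50 == 0:
            # renormalize factors to avoid float drift; m is rebuilt exactly
            sa = a[sup_a].max()
            sb = b[sup_b].max()
            a /= sa
            b /= sb
            c *= sa * sb
            m[:] = np.outer(a, b) * c[r_idx] * mask
    return iterations, max_change


try:  # optional compiled inner loop; the numpy path is the reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _ipf_cycles_numba(m, a, b, c, row_obs, col_obs, tot_obs, mask, tolerance, max_iterations):  # pragma: no cover - exercised via fit_cml
        n1, n2 = m.shape
        n_tot = tot_obs.size
        prev_p = np.zeros((n1, n2))
        for x in range(n1):
            for y in range(n2):
                if mask[x, y]:
                    prev_p[x, y] = m[x, y] / tot_obs[x + y]
        fc = np.ones(n_tot)
        tot_fit = np.zeros(n_tot)
        max_change = 1e300
        iterations = 0
        for it in range(1, max_iterations + 1):
            iterations = it
            for x in range(n1):
                s = 0.0
                for y in range(n2):
                    s += m[x, y]
                if row_obs[x] > 0 and s > 0:
                    f = row_obs[x] / s
                    a[x] *= f
                    for y in range(n2):
                        m[x, y] *= f
            for y in range(n2):
                s = 0.0
                for x in range(n1):
                    s += m[x, y]
                if col_obs[y] > 0 and s > 0:
                    f = col_obs[y] / s
                    b[y] *= f
                    for x in range(n1):
                        m[x, y] *= f
            for r in range(n_tot):
                tot_fit[r] = 0.0
            for x in range(n1):
                for y in range(n2):
                    tot_fit[x + y] += m[x, y]
            for r in range(n_tot):
                if tot_obs[r] > 0 and tot_fit[r] > 0:
                    fc[r] = tot_obs[r] / tot_fit[r]
                    c[r] *= fc[r]
                else:
                    fc[r] = 1.0
            max_change = 0.0
            for x in range(n1):
                for y in range(n2):
                    m[x, y] *= fc[x + y]
                    if mask[x, y]:
                        pv = m[x, y] / tot_obs[x + y]
                        d = abs(pv - prev_p[x, y])
                        if d > max_change:
                            max_change = d
                        prev_p[x, y] = pv
            if max_change <= tolerance:
                break
            if it % 50 == 0:
                sa = 0.0
                sb = 0.0
                for x in range(n1):
                    if row_obs[x] > 0 and a[x] > sa:
                        sa = a[x]
                for y in range(n2):
                    if col_obs[y] > 0 and b[y] > sb:
                        sb = b[y]
                for x in range(n1):
                    a[x] /= sa
                for y in range(n2):
                    b[y] /= sb
                for r in range(n_tot):
                    c[r] *= sa * sb
                for x in range(n1):
                    for y in range(n2):
                        if mask[x, y]:
                            m[x, y] = a[x] * b[y] * c[x + y]
                        else:
                            m[x, y] = 0.0
        return iterations, max_change

    def _run_ipf(m, a, b, c, row_obs, col_obs, tot_obs, mask, tolerance, max_iterations):
        return _ipf_cycles_numba(
            m, a, b, c,
            np.ascontiguousarray(row_obs, dtype=np.float64),
            np.ascontiguousarray(col_obs, dtype=np.float64),
            np.ascontiguousarray(tot_obs, dtype=np.float64),
            np.ascontiguousarray(mask),
            float(tolerance), int(max_iterations),
        )

except ImportError:  # pragma: no cover
    _run_ipf = _ipf_cycles_numpy


def fit_cml(
    table: ScoreContingencyTable,
    tolerance: float = 1e-9,
    max_iterations: int = 200_000,
    normalization: str = "centered",
    init: tuple[ScoreParameterVector, ScoreParameterVector] | None = None,
) -> LeunbachFit:
    """Conditional maximum likelihood fit of the Leunbach model by IPF.

    Parameters
    ----------
    table
        Observed two-way score table.
    tolerance
        Convergence criterion: maximum absolute change, over one full IPF
        cycle, of the fitted conditional split probabilities.
    max_iterations
        Maximum number of IPF cycles; exceeding it returns a fit flagged
        ``converged=False`` rather than raising.
    normalization
        ``"centered"`` (first supported gamma = 1 per scale, geometric tilt
        chosen so the mean person estimate over observed interior total
        scores is 0) or ``"raw"`` (first supported gamma = 1, tilt as the
        IPF factors happened to land).  Equating output is invariant to the
        choice.
    init
        Optional warm-start gamma vectors (e.g. the fit of the table a
        bootstrap resample came from).
    """
    if table.n == 0:
        raise DegenerateTableError("empty table: no persons")
    counts = table.counts.astype(float)
    mask, r_idx, tot_obs = _support_mask(table)
    row_obs = table.row_margin.astype(float)
    col_obs = table.col_margin.astype(float)
    tot_f = tot_obs.astype(float)
    sup_a = row_obs > 0
    sup_b = col_obs > 0
    informative = _informative_diagonals(mask, r_idx, tot_obs)
    identifiable = informative.size > 0
    if not identifiable:
        logger.warning(
            "table carries no conditional information (every observed total "
            "score admits a single split); gamma is not identifiable"
        )

    # factors of the quasi-independence representation m[x,y] = a_x b_y c_{x+y}
    a = np.where(sup_a, 1.0, 0.0)
    b = np.where(sup_b, 1.0, 0.0)
    if init is not None:
        ia, ib = init
        ga = np.zeros_like(a)
        gb = np.zeros_like(b)
        ga[: ia.gamma.size][sup_a[: ia.gamma.size]] = ia.gamma[sup_a[: ia.gamma.size]]
        gb[: ib.gamma.size][sup_b[: ib.gamma.size]] = ib.gamma[sup_b[: ib.gamma.size]]
        a = np.where((ga > 0) & sup_a, ga, a)
        b = np.where((gb > 0) & sup_b, gb, b)
    c = np.where(tot_f > 0, 1.0, 0.0)
    if init is not None:
        # at the solution m[x,y] = n_r gamma1_x gamma2_y / omega_r, so the
        # warm start for the diagonal factors is n_r / omega_r
        omega0 = np.convolve(a, b)[: tot_f.size]
        good = (tot_f > 0) & (omega0 > 0)
        c[good] = tot_f[good] / omega0[good]

    m = np.outer(a, b) * c[r_idx] * mask
    iterations, max_change = _run_ipf(
        m, a, b, c, row_obs, col_obs, tot_f, mask, tolerance, max_iterations
    )
    converged = max_change <= tolerance
    if not converged:
        logger.warning(
            "CML/IPF did not converge in %d cycles (max change %.3g > %.3g)",
            max_iterations, max_change, tolerance,
        )

    gamma_a = np.where(sup_a, a, 0.0)
    gamma_b = np.where(sup_b, b, 0.0)
    norm_record: dict = {"constraint": "first supported gamma = 1 per scale"}
    # per-scale constants
    gamma_a = gamma_a / gamma_a[gamma_a > 0][0]
    gamma_b = gamma_b / gamma_b[gamma_b > 0][0]

    if normalization == "centered" and identifiable:
        shift = _centering_shift(gamma_a, gamma_b, tot_obs)
        if shift is not None:
            x_a = np.arange(gamma_a.size)
            x_b = np.arange(gamma_b.size)
            gamma_a = gamma_a * np.exp(shift * x_a)
            gamma_b = gamma_b * np.exp(shift * x_b)
            gamma_a = gamma_a / gamma_a[gamma_a > 0][0]
            gamma_b = gamma_b / gamma_b[gamma_b > 0][0]
            norm_record["tilt"] = "centered"
            norm_record["tilt_shift"] = float(shift)
    elif normalization == "raw":
        norm_record["tilt"] = "raw"
    elif normalization != "centered":
        raise ValueError(f"unknown normalization {normalization!r}")

    params_a = ScoreParameterVector(gamma_a)
    params_b = ScoreParameterVector(gamma_b)
    return LeunbachFit(
        params_a=params_a,
        params_b=params_b,
        omega=omega_convolution(params_a, params_b),
        scale_names=table.scale_names,
        margin_a=table.row_margin.copy(),
        margin_b=table.col_margin.copy(),
        total_margin=tot_obs.copy(),
        normalization=norm_record,
        converged=converged,
        identifiable=identifiable,
        iterations=iterations,
        max_change=max_change,
    )


def _centering_shift(
    gamma_a: np.ndarray, gamma_b: np.ndarray, tot_obs: np.ndarray
) -> float | None:
    """Tilt exponent making the mean theta-hat over interior total scores 0."""
    omega = np.convolve(gamma_a, gamma_b)
    combined = ScoreParameterVector(omega)
    lo, hi = combined.min_support, combined.max_support
    interior = [r for r in np.flatnonzero(tot_obs) if lo < r < hi]
    if not interior:
        return None
    thetas = [person_mle(combined, r).theta for r in interior]
    return float(np.mean(thetas))


def conditional_loglik(fit: LeunbachFit, table: ScoreContingencyTable) -> float:
    """Conditional log likelihood sum_cells n_xy * log P(x | r) under the fit.

    Invariant to the normalization convention.  Observed cells the fitted
    model assigns probability zero yield ``-inf`` with a warning.
    """
    counts = table.counts
    if counts.shape != (fit.params_a.gamma.size, fit.params_b.gamma.size):
        raise ValueError("fit and table are dimensionally incompatible")
    ll = 0.0
    for r in np.flatnonzero(table.total_margin):
        diag_x = np.arange(
            max(0, r - fit.params_b.max_score), min(r, fit.params_a.max_score) + 1
        )
        obs = counts[diag_x, r - diag_x]
        if obs.sum() == 0:
            continue
        try:
            p = fit.conditional_split(int(r))[diag_x]
        except Exception:
            warnings.warn(f"total score {r} unsupported under fit; loglik = -inf")
            return -math.inf
        if np.any((obs > 0) & (p <= 0)):
            warnings.warn(f"observed split with zero fitted probability at r={r}")
            return -math.inf
        pos = obs > 0
        ll += float(obs[pos] @ np.log(p[pos]))
    return ll


def person_mle(
    params: ScoreParameterVector,
    score: float,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> PersonParameter:
    """MLE of the person parameter from a single observed score.

    Solves ``expected_score(params, theta) = score`` by Newton-Raphson on
    theta (derivative = score variance) inside a sign-changing bracket, with
    bisection whenever a Newton step leaves the bracket.  Real-valued targets
    are allowed (used internally by equating).

    Raises
    ------
    ExtremeScoreError
        For scores at or beyond the support boundary, where no finite MLE
        exists; callers apply the endpoint convention.
    """
    lo_s, hi_s = params.min_support, params.max_support
    if not lo_s < score < hi_s:
        raise ExtremeScoreError(
            f"score {score} is extreme for support {lo_s}..{hi_s}: no finite MLE"
        )

    def f(theta: float) -> float:
        return expected_score(params, PersonParameter(theta)) - score

    lo, hi = -1.0, 1.0
    while f(lo) > 0:
        lo *= 2.0
        if lo < -745:  # exp underflow bound; support guarantees a root before this
            break
    while f(hi) < 0:
        hi *= 2.0
        if hi > 745:
            break

    theta = 0.5 * (lo + hi)
    for _ in range(max_iter):
        fe = f(theta)
        if abs(fe) <= tol:
            break
        if fe > 0:
            hi = theta
        else:
            lo = theta
        v = score_variance(params, PersonParameter(theta))
        step_ok = v > 1e-300
        if step_ok:
            nxt = theta - fe / v
            if not (lo < nxt < hi):
                step_ok = False
        if not step_ok:
            nxt = 0.5 * (lo + hi)
        theta = nxt
    return PersonParameter(theta)
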