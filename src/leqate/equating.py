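"""Score-to-score equating and its bootstrap standard error.

Direct (common-person) equating follows the true-score recipe: for a source
score x, (1) estimate the person parameter whose expected source score is x,
(2) evaluate the expected target score at that person parameter, (3) round
to the nearest integer (halves away from zero).  Extreme source scores have
no finite person estimate and map to the corresponding extreme of the
target's observed range.

The Standard Error of Equating (SEE) is the standard deviation, over S
nonparametric bootstrap resamples of the observed contingency table, of the
equated score; the S-1 denominator around the bootstrap mean is used.  A
weighted mean SEE (weights = observed source-score frequencies) summarizes a
table; values below 0.91 are regarded as acceptable — the worst acceptable
error distribution (roughly a third of replicates each at -1, 0, +1 plus
2.5% at +/-2) has SEE 0.91.

Indirect (common-scale) equating from B to C via A composes two direct
equating tables: B -> expected A (sample 1), then linear interpolation of
the expected-C curve of sample 2 between integer A scores.  Its SEE is
bootstrapped by resampling both tables independently and replaying the
whole procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import expected_score
from .estimation import (
    LeunbachFit,
    ScoreContingencyTable,
    fit_cml,
    person_mle,
)

__all__ = [
    "EquatingTable",
    "BootstrapErrorDistribution",
    "ACCEPTABLE_SEE",
    "round_expected",
    "equate_direct",
    "weighted_see_mean",
    "see_from_error_distribution",
    "see_bootstrap",
    "equate_indirect",
    "equate_indirect_from_tables",
    "see_bootstrap_indirect",
]

logger = logging.getLogger(__name__)

#: Weighted-mean SEE below this value is regarded as acceptable.
ACCEPTABLE_SEE = 0.91

_COLUMNS = ["source_score", "theta", "expected_target", "equated_target", "see", "weight"]


def round_expected(expected: float) -> int:
    """Round an expected score to the nearest integer, halves away from zero."""
    return int(math.floor(abs(expected) + 0.5) * (1 if expected >= 0 else -1))


@dataclass
class EquatingTable:
    """Per-source-score equating results for one direction.

    ``table`` holds one row per observed source score with columns
    source_score, theta (person estimate; -inf/+inf at the endpoints),
    expected_target, equated_target, see (NaN until bootstrapped) and
    weight (observed relative frequency of the source score).
    """

    source: str
    target: str
    table: pd.DataFrame
    S: int | None = None
    seed: int | None = None
    n_failed: int = 0

    @property
    def weighted_see_mean(self) -> float:
        sees = self.table["see"].to_numpy()
        if np.all(np.isnan(sees)):
            return math.nan
        mean, _ = weighted_see_mean(sees, self.table["weight"].to_numpy())
        return mean

    @property
    def see_acceptable(self) -> bool:
        return self.weighted_see_mean < ACCEPTABLE_SEE

    def to_csv(self, path: str | Path) -> None:
        """Write the table as CSV with metadata in '#' comment lines."""
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# source={self.source}\n# target={self.target}\n")
            if self.S is not None:
                fh.write(f"# S={self.S}\n")
            if self.seed is not None:
                fh.write(f"# seed={self.seed}\n")
            self.table.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EquatingTable":
        meta: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                meta[key.strip()] = value.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            df = pd.read_csv(fh)
        return cls(
            source=meta.get("source", "A"),
            target=meta.get("target", "B"),
            table=df[_COLUMNS],
            S=int(meta["S"]) if "S" in meta else None,
            seed=int(meta["seed"]) if "seed" in meta else None,
        )

    def summary(self) -> dict:
        return {
            "source": self.source,
            "target": self.target,
            "weighted_see_mean": self.weighted_see_mean,
            "see_acceptable": bool(self.see_acceptable)
            if not math.isnan(self.weighted_see_mean)
            else None,
            "S": self.S,
            "seed": self.seed,
            "n_failed": self.n_failed,
        }


@dataclass(frozen=True)
class BootstrapErrorDistribution:
    """Relative frequencies of bootstrap equating errors per source score.

    ``errors[s]`` maps the (uncapped) integer error — bootstrapped equated
    score minus the point estimate — to its relative frequency among the
    replicates in which source score s was observed.  ``display()`` caps the
    bins at -2/+2 the way the error distribution is conventionally printed.
    """

    errors: dict[int, dict[int, float]]
    S: int
    n_samples: dict[int, int]

    def see(self, source_score: int) -> float:
        """SEE recomputed from the stored error distribution."""
        return see_from_error_distribution(
            self.errors[source_score], n_samples=self.n_samples[source_score]
        )

    def display(self) -> pd.DataFrame:
        rows = []
        for s, freqs in sorted(self.errors.items()):
            binned = {"-2+": 0.0, "-1": 0.0, "0": 0.0, "+1": 0.0, "+2+": 0.0}
            for e, f in freqs.items():
                if e <= -2:
                    binned["-2+"] += f
                elif e == -1:
                    binned["-1"] += f
                elif e == 0:
                    binned["0"] += f
                elif e == 1:
                    binned["+1"] += f
                else:
                    binned["+2+"] += f
            rows.append({"source_score": s, **binned})
        return pd.DataFrame(rows)


def see_from_error_distribution(
    freqs: dict[int, float] | dict[float, float],
    n_samples: int | None = None,
) -> float:
    """SEE from an error distribution: sd of the error around its mean.

    ``freqs`` maps error values to relative frequencies (summing to one).
    With ``n_samples`` given, the S/(S-1) small-sample correction matching
    the bootstrap SEE formula is applied; without it the population formula
    is used — e.g. {-1: .05, 0: .9, +1: .05} -> sqrt(0.10) = 0.316 and
    {-2: .025, -1: .225, 0: .5, +1: .225, +2: .025} -> sqrt(0.65) = 0.81.
    """
    e = np.array(list(freqs.keys()), dtype=float)
    f = np.array(list(freqs.values()), dtype=float)
    if np.any(f < 0) or f.sum() <= 0:
        raise ValueError("frequencies must be non-negative and sum > 0")
    f = f / f.sum()
    m1 = float(f @ e)
    var = float(f @ (e - m1) ** 2)
    if n_samples is not None and n_samples > 1:
        var *= n_samples / (n_samples - 1)
    return math.sqrt(var)


def weighted_see_mean(
    sees: np.ndarray, weights: np.ndarray
) -> tuple[float, bool]:
    """Weighted average SEE and its acceptability flag (mean < 0.91).

    NaN SEE entries (scores never bootstrapped) are excluded together with
    their weights.
    """
    sees = np.asarray(sees, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if sees.shape != weights.shape:
        raise ValueError("sees and weights must have equal length")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    keep = ~np.isnan(sees)
    total = weights[keep].sum()
    if total <= 0:
        raise ValueError("weights must not all be zero")
    mean = float((sees[keep] * weights[keep]).sum() / total)
    return mean, mean < ACCEPTABLE_SEE


def equate_direct(fit: LeunbachFit, source: str = "a") -> EquatingTable:
    """Point-estimate equating table from the source scale to the other one.

    One row per observed source score; endpoints map to the target's
    observed extremes, interior scores go through the person-parameter MLE
    and the target's test characteristic curve.
    """
    idx = fit.scale_index(source)
    if idx == 0:
        src, tgt = fit.params_a, fit.params_b
        margin = fit.margin_a
    else:
        src, tgt = fit.params_b, fit.params_a
        margin = fit.margin_b
    src_name = fit.scale_names[idx]
    tgt_name = fit.scale_names[1 - idx]
    if not fit.converged:
        logger.warning("equating from a non-converged fit")

    observed = np.flatnonzero(margin)
    n = margin.sum()
    rows = []
    for s in observed:
        s = int(s)
        if s <= src.min_support:
            theta, exp_t = -math.inf, float(tgt.min_support)
        elif s >= src.max_support:
            theta, exp_t = math.inf, float(tgt.max_support)
        else:
            person = person_mle(src, s)
            theta = person.theta
            exp_t = expected_score(tgt, person)
        rows.append(
            {
                "source_score": s,
                "theta": theta,
                "expected_target": exp_t,
                "equated_target": round_expected(exp_t),
                "see": math.nan,
                "weight": margin[s] / n,
            }
        )
    return EquatingTable(source=src_name, target=tgt_name, table=pd.DataFrame(rows, columns=_COLUMNS))


def _resample_table(
    table: ScoreContingencyTable, rng: np.random.Generator
) -> ScoreContingencyTable:
    """Nonparametric bootstrap: multinomial resample of n persons over cells."""
    p = table.counts.ravel() / table.n
    draw = rng.multinomial(table.n, p).reshape(table.counts.shape)
    return ScoreContingencyTable(draw, table.scale_names)


def _collect_see(
    point: EquatingTable,
    replicate_maps: list[dict[int, int]],
    S: int,
    seed: int | None,
    n_failed: int,
) -> tuple[EquatingTable, BootstrapErrorDistribution]:
    """Fill SEE columns of `point` from per-replicate equated-score maps."""
    errors: dict[int, dict[int, float]] = {}
    n_samples: dict[int, int] = {}
    sees = []
    for _, row in point.table.iterrows():
        s = int(row["source_score"])
        values = np.array([m[s] for m in replicate_maps if s in m], dtype=float)
        if values.size >= 2:
            see = float(values.std(ddof=1))
            errs = (values - row["equated_target"]).astype(int)
            uniq, cnt = np.unique(errs, return_counts=True)
            errors[s] = {int(e): float(c / values.size) for e, c in zip(uniq, cnt)}
            n_samples[s] = int(values.size)
        else:
            see = math.nan
            errors[s] = {}
            n_samples[s] = int(values.size)
        sees.append(see)
    point.table["see"] = sees
    point.S = S
    point.seed = seed
    point.n_failed = n_failed
    if n_failed > 0.05 * S:
        logger.warning("%d of %d bootstrap fits failed", n_failed, S)
    return point, BootstrapErrorDistribution(errors=errors, S=S, n_samples=n_samples)


def see_bootstrap(
    table: ScoreContingencyTable,
    source: str = "a",
    S: int = 1000,
    seed: int | None = None,
    tolerance: float = 1e-8,
) -> tuple[EquatingTable, BootstrapErrorDistribution]:
    """Direct equating with bootstrap SEE per source score.

    S multinomial resamples of the observed table are each refitted
    (warm-started from the original fit) and re-equated; the SEE of a source
    score is the S-1-denominator standard deviation of its bootstrapped
    equated scores.
    """
    fit = fit_cml(table)
    point = equate_direct(fit, source)
    rng = np.random.default_rng(seed)
    warm = (fit.params_a, fit.params_b)
    maps: list[dict[int, int]] = []
    n_failed = 0
    for _ in range(S):
        boot = _resample_table(table, rng)
        try:
            bfit = fit_cml(boot, tolerance=tolerance, normalization="raw", init=warm)
            if not bfit.converged:
                raise RuntimeError("bootstrap fit did not converge")
            btab = equate_direct(bfit, source)
        except Exception:
            n_failed += 1
            continue
        maps.append(
            dict(
                zip(
                    btab.table["source_score"].astype(int),
                    btab.table["equated_target"].astype(int),
                )
            )
        )
    return _collect_see(point, maps, S, seed, n_failed)


def equate_indirect_from_tables(
    table_ba: EquatingTable, table_ac: EquatingTable
) -> EquatingTable:
    """Compose B -> A and A -> C direct tables into a B -> C table.

    The expected A score of each B score is carried through the sample-2
    expected-C curve by linear interpolation on the grid of observed A
    scores (the midpoint rule for half-integer expected A scores is the
    special case).  Expected A scores outside sample 2's observed A range
    are clamped to its ends with a warning.
    """
    if table_ba.target != table_ac.source:
        raise ValueError(
            f"tables do not chain: B->{table_ba.target!r} vs {table_ac.source!r}->C"
        )
    a_grid = table_ac.table["source_score"].to_numpy(dtype=float)
    e_c = table_ac.table["expected_target"].to_numpy(dtype=float)
    rows = []
    for _, row in table_ba.table.iterrows():
        s = float(row["expected_target"])
        if s < a_grid[0] or s > a_grid[-1]:
            logger.warning(
                "expected %s score %.2f outside observed range %g..%g; clamped",
                table_ba.target, s, a_grid[0], a_grid[-1],
            )
        exp_c = float(np.interp(s, a_grid, e_c))
        rows.append(
            {
                "source_score": int(row["source_score"]),
                "theta": row["theta"],
                "expected_target": exp_c,
                "equated_target": round_expected(exp_c),
                "see": math.nan,
                "weight": row["weight"],
            }
        )
    return EquatingTable(
        source=table_ba.source,
        target=table_ac.target,
        table=pd.DataFrame(rows, columns=_COLUMNS),
    )


def _indirect_direction(
    fit_ba: LeunbachFit, fit_ac: LeunbachFit
) -> tuple[str, str, str]:
    """Identify (B, A, C) scale names: A is the scale the fits share."""
    common = set(fit_ba.scale_names) & set(fit_ac.scale_names)
    if len(common) != 1:
        raise ValueError(
            f"fits must share exactly one scale; got {fit_ba.scale_names} "
            f"and {fit_ac.scale_names}"
        )
    via = common.pop()
    b = next(s for s in fit_ba.scale_names if s != via)
    c = next(s for s in fit_ac.scale_names if s != via)
    return b, via, c


def equate_indirect(fit_ba: LeunbachFit, fit_ac: LeunbachFit) -> EquatingTable:
    """Indirect equating B -> C through the scale common to both fits."""
    b, via, c = _indirect_direction(fit_ba, fit_ac)
    return equate_indirect_from_tables(
        equate_direct(fit_ba, b), equate_direct(fit_ac, via)
    )


def see_bootstrap_indirect(
    table_ba: ScoreContingencyTable,
    table_ac: ScoreContingencyTable,
    S: int = 1000,
    seed: int | None = None,
    tolerance: float = 1e-8,
) -> tuple[EquatingTable, BootstrapErrorDistribution]:
    """Indirect equating with bootstrap SEE.

    Both samples' tables are resampled independently in every replicate and
    the full three-step procedure is replayed; SEE and weighted mean are
    computed as in the direct case with B-score weights from sample 1.
    """
    fit_ba = fit_cml(table_ba)
    fit_ac = fit_cml(table_ac)
    b, via, _ = _indirect_direction(fit_ba, fit_ac)
    point = equate_indirect(fit_ba, fit_ac)
    rng = np.random.default_rng(seed)
    warm_ba = (fit_ba.params_a, fit_ba.params_b)
    warm_ac = (fit_ac.params_a, fit_ac.params_b)
    maps: list[dict[int, int]] = []
    n_failed = 0
    for _ in range(S):
        boot_ba = _resample_table(table_ba, rng)
        boot_ac = _resample_table(table_ac, rng)
        try:
            bf_ba = fit_cml(boot_ba, tolerance=tolerance, normalization="raw", init=warm_ba)
            bf_ac = fit_cml(boot_ac, tolerance=tolerance, normalization="raw", init=warm_ac)
            if not (bf_ba.converged and bf_ac.converged):
                raise RuntimeError("bootstrap fit did not converge")
            btab = equate_indirect(bf_ba, bf_ac)
        except Exception:
            n_failed += 1
            continue
        maps.append(
            dict(
                zip(
                    btab.table["source_score"].astype(int),
                    btab.table["equated_target"].astype(int),
                )
            )
        )
    return _collect_see(point, maps, S, seed, n_failed)
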