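"""Reading per-person score files and assembling contingency tables.

The expected input is a wide CSV: one row per respondent, one column per
scale holding integer total scores (plus an optional identifier column).
Scale metadata declares each scale's theoretical range, e.g. 0-24 for an
8-item 0-3 scale; out-of-range values are rejected with row-level
diagnostics.  Missing scores are allowed — a contingency table for a pair of
scales uses exactly the persons with both scores present (pairwise complete
cases).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import ScoreContingencyTable

__all__ = ["ScoreDataset", "read_scores", "contingency_table"]


@dataclass
class ScoreDataset:
    """Validated per-person scores with per-scale declared ranges."""

    scores: pd.DataFrame
    ranges: dict[str, tuple[int, int]]

    @property
    def scales(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def n(self) -> int:
        return len(self.scores)


def read_scores(
    path: str | Path,
    ranges: dict[str, tuple[int, int]] | None = None,
    missing_code: str | int | None = None,
    id_column: str | None = None,
) -> ScoreDataset:
    """Read and validate a wide per-person score CSV.

    Parameters
    ----------
    path
        CSV with a header row naming the scales.
    ranges
        Mapping scale -> (min, max) theoretical score range.  Scales not
        listed get the observed 0..max range.  Only listed scales are kept
        when a mapping is supplied.
    missing_code
        Cell value (besides an empty cell) to treat as missing.
    id_column
        Column of person identifiers; duplicates are rejected.  Defaults to
        a column named ``person`` or ``id`` when present.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if id_column is None:
        for cand in ("person", "id"):
            if cand in df.columns:
                id_column = cand
                break
    if id_column is not None:
        if id_column not in df.columns:
            raise ValueError(f"id column {id_column!r} not in file")
        ids = df[id_column]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate person identifiers: {list(dupes)}")
        df = df.drop(columns=[id_column]).set_index(ids.rename("person"))

    if ranges is not None:
        missing_scales = set(ranges) - set(df.columns)
        if missing_scales:
            raise ValueError(f"scales not in file: {sorted(missing_scales)}")
        df = df[list(ranges)]

    errors: list[str] = []
    parsed = {}
    for scale in df.columns:
        col = df[scale]
        if missing_code is not None:
            col = col.mask(col.astype(str).str.strip() == str(missing_code))
        values = pd.to_numeric(col, errors="coerce")
        bad = col.notna() & values.isna()
        for row in df.index[bad][:5]:
            errors.append(f"{scale}: unparseable value {col[row]!r} in row {row!r}")
        nonint = values.notna() & (values != np.floor(values))
        for row in df.index[nonint][:5]:
            errors.append(f"{scale}: non-integer score {values[row]} in row {row!r}")
        lo, hi = (0, int(np.nanmax(values.to_numpy(dtype=float), initial=0)))
        if ranges is not None and scale in ranges:
            lo, hi = ranges[scale]
        out = values.notna() & ((values < lo) | (values > hi))
        for row in df.index[out][:5]:
            errors.append(
                f"{scale}: score {int(values[row])} outside {lo}..{hi} in row {row!r}"
            )
        parsed[scale] = values
    if errors:
        raise ValueError("invalid score file:\n  " + "\n  ".join(errors))
    out_df = pd.DataFrame(parsed, index=df.index).astype("Int64")
    final_ranges = {
        scale: (ranges[scale] if ranges and scale in ranges else (0, int(out_df[scale].max())))
        for scale in out_df.columns
    }
    return ScoreDataset(scores=out_df, ranges=final_ranges)


def contingency_table(
    dataset: ScoreDataset, scale_a: str, scale_b: str
) -> ScoreContingencyTable:
    """Two-way score table for a pair of scales over pairwise-complete persons."""
    for scale in (scale_a, scale_b):
        if scale not in dataset.scores.columns:
            raise KeyError(f"scale {scale!r} not in dataset (has {dataset.scales})")
    pair = dataset.scores[[scale_a, scale_b]].dropna()
    if pair.empty:
        raise ValueError(f"no persons with both {scale_a!r} and {scale_b!r} scores")
    return ScoreContingencyTable.from_scores(
        pair[scale_a].to_numpy(dtype=np.int64),
        pair[scale_b].to_numpy(dtype=np.int64),
        max_a=dataset.ranges[scale_a][1],
        max_b=dataset.ranges[scale_b][1],
        scale_names=(scale_a, scale_b),
    )
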