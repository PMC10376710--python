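"""Binning onto the mission grid, baseline differencing, normalization.

Raw records are collapsed per (subject, measurement) to at most one value per
mission-grid bin by averaging all observations whose day falls inside the
bin.  Each binned series is then differenced against its pre-flight baseline
bin (-45 d) and scaled to unit Euclidean norm over its present bins:

    X~(t_i) = X(t_i) - X(-45),      Q(t_i) = X~(t_i) / ||X~||_2.

Series missing the baseline bin, or with too few present bins, are dropped
with a recorded reason; series identical to their baseline everywhere
(||X~|| = 0) are flagged degenerate and excluded from classification rather
than divided by zero.  No imputation is performed anywhere — the spectral
stage tolerates missing bins by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from spacetrend.grid import TimeGrid

#: ||X~|| below this is treated as exactly zero (degenerate series).
DEGENERATE_TOL = 1e-12

#: Default minimum number of present bins (baseline included) to keep a series.
DEFAULT_MIN_BINS = 5


def bin_records(
    records: pd.DataFrame, grid: TimeGrid | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse raw records to the mission grid.

    Parameters
    ----------
    records
        Long-format frame with columns subject_id, measurement_id,
        time_days, value.  Rows with missing values are ignored; rows whose
        day falls outside the grid window are dropped and logged.

    Returns
    -------
    binned, dropped
        ``binned``: wide frame indexed by (subject_id, measurement_id) with
        one column per grid label; absent bins are NaN.  ``dropped``: the
        out-of-window raw rows, with a ``reason`` column.
    """
    grid = grid or TimeGrid()
    df = records.loc[:, ["subject_id", "measurement_id", "time_days", "value"]].copy()
    df = df[np.isfinite(df["value"].astype(float))]
    idx = grid.bin_indices(df["time_days"].to_numpy(dtype=float))
    out = idx < 0
    dropped = df[out].copy()
    dropped["reason"] = "outside study window"
    df = df[~out]
    df["bin"] = np.asarray(grid.labels)[idx[~out]]
    binned = (
        df.groupby(["subject_id", "measurement_id", "bin"], sort=True)["value"]
        .mean()
        .unstack("bin")
        .reindex(columns=list(grid.labels))
    )
    binned.columns.name = None
    return binned, dropped


def filter_series(
    values: np.ndarray, grid: TimeGrid | None = None, min_bins: int = DEFAULT_MIN_BINS
) -> tuple[bool, str | None]:
    """Keep/drop decision for one binned series, with the reason for a drop."""
    grid = grid or TimeGrid()
    values = np.asarray(values, dtype=float)
    if np.isnan(values[grid.baseline_index]):
        return False, "no baseline"
    if np.sum(~np.isnan(values)) < min_bins:
        return False, f"fewer than {min_bins} bins present"
    return True, None


def baseline_normalize(
    values: np.ndarray, baseline_index: int
) -> tuple[np.ndarray, bool]:
    """Difference against the baseline bin and scale to unit norm.

    Returns (normalized values, degenerate flag).  Missing bins stay NaN and
    do not contribute to the norm.  A series equal to its baseline at every
    present bin has zero norm; it is returned unscaled (all zeros at present
    bins) with the degenerate flag set.
    """
    values = np.asarray(values, dtype=float)
    centered = values - values[baseline_index]
    norm = float(np.sqrt(np.nansum(centered**2)))
    if norm < DEGENERATE_TOL:
        return centered, True
    return centered / norm, False


@dataclass
class PreprocessResult:
    """Outputs of the preprocessing stage for a whole cohort."""

    binned: pd.DataFrame        # all binned series (kept and dropped)
    normalized: pd.DataFrame    # unit-norm series, same wide layout
    drop_log: pd.DataFrame      # (subject_id, measurement_id, reason)
    degenerate: pd.DataFrame    # series with zero baseline-differenced norm


def preprocess_cohort(
    records: pd.DataFrame,
    grid: TimeGrid | None = None,
    min_bins: int = DEFAULT_MIN_BINS,
) -> PreprocessResult:
    """Run binning, filtering and normalization over a cohort."""
    grid = grid or TimeGrid()
    binned, _ = bin_records(records, grid)
    drops: list[tuple[str, str, str]] = []
    kept_rows: list[tuple[tuple[str, str], np.ndarray]] = []
    degen: list[tuple[str, str]] = []
    for key, row in binned.iterrows():
        values = row.to_numpy(dtype=float)
        keep, reason = filter_series(values, grid, min_bins)
        if not keep:
            drops.append((*key, reason))
            continue
        q, is_degen = baseline_normalize(values, grid.baseline_index)
        if is_degen:
            degen.append(key)
            continue
        kept_rows.append((key, q))
    normalized = pd.DataFrame(
        [q for _, q in kept_rows],
        index=pd.MultiIndex.from_tuples(
            [k for k, _ in kept_rows], names=["subject_id", "measurement_id"]
        ) if kept_rows else binned.index[:0],
        columns=binned.columns,
    )
    drop_log = pd.DataFrame(drops, columns=["subject_id", "measurement_id", "reason"])
    degenerate = pd.DataFrame(degen, columns=["subject_id", "measurement_id"])
    return PreprocessResult(binned, normalized, drop_log, degenerate)


def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a wide series matrix as TSV (rows subject x measurement)."""
    matrix.to_csv(path, sep="\t")
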