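"""Spectral trend classification of short, unevenly sampled series.

The classifier works per subject.  For each normalized series Q the classical
Lomb-Scargle periodogram P(f) is computed over the present bins (missing
bins are simply absent — no imputation), and the autocorrelations rho_l at
integer grid lags l in {0, ..., N/2} are obtained as the normalized inverse
Fourier (cosine) transform of P(f).  A bootstrap null set is generated by
resampling the subject's pooled normalized values with replacement onto the
full grid; its per-lag autocorrelation quantiles give thresholds rho_q[l],
and the quantiles of its per-series maxima and minima give spike bounds.
A series is assigned:

* ``Lag M`` where M is the smallest lag with rho_M >= rho_q[M];
* else ``SpikeMax`` if max(Q) exceeds the bootstrap maxima quantile, or
  ``SpikeMin`` if min(Q) falls below the bootstrap minima quantile
  (lower-tail);
* else no trend.

Numerical construction
----------------------
The periodogram is the classical tau-shifted Lomb-Scargle form after mean
subtraction, which is algebraically identical to the explained sum of squares
(halved) of a per-frequency least-squares sinusoid fit.  The mission grid is
treated ordinally for the spectral stage: bin i sits at time i, so a lag of
1 means "one mission-phase step" regardless of the uneven day spacing of the
bins, and missing bins leave gaps in the index grid that the Lomb-Scargle
estimator absorbs.  The frequency grid is f_k = k / (2 N) for k = 1..N.
For a complete series this makes the cosine-transform autocorrelations
*exactly* equal to the direct lagged-product autocorrelations of the
mean-centered series (the discrete Wiener-Khinchin identity with zero
padding); with gaps it is their natural least-squares generalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from spacetrend.grid import TimeGrid

#: Quantile level for lag thresholds and spike bounds.
DEFAULT_LEVEL = 0.95
#: Bootstrap set size for null distributions.
DEFAULT_N_BOOT = 100_000

LAG = "lag"
SPIKE_MAX = "spike_max"
SPIKE_MIN = "spike_min"
NO_TREND = "no_trend"

TREND_FAMILIES = (LAG, SPIKE_MAX, SPIKE_MIN)


@dataclass(frozen=True)
class SpectralGrids:
    """Shared frequency and lag grids for one analysis run."""

    times: np.ndarray      # ordinal bin positions 0..N-1
    freqs: np.ndarray      # cycles per bin step
    lag_times: np.ndarray  # bin steps; lag l <-> delay l
    n_lags: int            # floor(N/2)


def spectral_grids(grid: TimeGrid | None = None) -> SpectralGrids:
    grid = grid or TimeGrid()
    n = grid.n_bins
    freqs = np.arange(1, n + 1) / (2.0 * n)
    n_lags = n // 2
    return SpectralGrids(
        times=np.arange(n, dtype=float),
        freqs=freqs,
        lag_times=np.arange(n_lags + 1, dtype=float),
        n_lags=n_lags,
    )


@dataclass(frozen=True)
class Periodogram:
    freqs: np.ndarray
    power: np.ndarray


@dataclass(frozen=True)
class AutocorrelationProfile:
    lags: np.ndarray
    rho: np.ndarray


@dataclass(frozen=True)
class TrendClass:
    """Outcome of classification for one series.

    kind is one of "lag", "spike_max", "spike_min", "no_trend"; lag is the
    smallest significant lag M when kind == "lag"; p_value is the bootstrap
    p-value of the deciding statistic (used only for the FDR gate).
    """

    kind: str
    lag: int | None = None
    p_value: float = 1.0


def _tau_basis(times: np.ndarray, freq: float) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Tau-shifted cosine/sine basis and their squared norms at one frequency."""
    w = 2.0 * np.pi * freq
    tau = np.arctan2(np.sum(np.sin(2 * w * times)), np.sum(np.cos(2 * w * times))) / (2 * w)
    ct = np.cos(w * (times - tau))
    st = np.sin(w * (times - tau))
    return ct, st, float(np.sum(ct**2)), float(np.sum(st**2))


_NORM_EPS = 1e-12


def lomb_scargle_power(
    values: np.ndarray, times: np.ndarray, freqs: np.ndarray
) -> np.ndarray:
    """Classical Lomb-Scargle power of one series at the given frequencies.

    NaN values are treated as missing and skipped together with their times.
    The sample mean of the present values is removed first.  Requires at
    least 3 present points.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    present = ~np.isnan(values)
    values, times = values[present], times[present]
    if len(values) < 3:
        raise ValueError("Lomb-Scargle needs at least 3 present points")
    x = values - values.mean()
    power = np.empty(len(freqs))
    for i, f in enumerate(np.asarray(freqs, dtype=float)):
        ct, st, big_c, big_s = _tau_basis(times, f)
        c = float(np.dot(x, ct))
        s = float(np.dot(x, st))
        pc = c * c / big_c if big_c > _NORM_EPS else 0.0
        ps = s * s / big_s if big_s > _NORM_EPS else 0.0
        power[i] = 0.5 * (pc + ps)
    return power


def _batch_power(values: np.ndarray, times: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """Vectorized Lomb-Scargle for a (B, N) batch of complete series."""
    x = values - values.mean(axis=1, keepdims=True)
    power = np.empty((values.shape[0], len(freqs)))
    for i, f in enumerate(freqs):
        ct, st, big_c, big_s = _tau_basis(times, f)
        c = x @ ct
        s = x @ st
        p = np.zeros(values.shape[0])
        if big_c > _NORM_EPS:
            p += c * c / big_c
        if big_s > _NORM_EPS:
            p += s * s / big_s
        power[:, i] = 0.5 * p
    return power


def autocorrelations(
    power: np.ndarray, freqs: np.ndarray, lag_times: np.ndarray
) -> np.ndarray:
    """Autocorrelations as the normalized inverse cosine transform of power.

    rho_l = sum_k P(f_k) cos(2 pi f_k tau_l) / sum_k P(f_k); rho_0 = 1 by
    construction and |rho_l| <= 1 since each rho_l is a convex combination
    of cosines.  Raises on all-zero power (degenerate series upstream).
    """
    power = np.asarray(power, dtype=float)
    total = power.sum(axis=-1, keepdims=True)
    if np.any(total <= 0):
        raise ValueError("all-zero periodogram: degenerate series")
    phase = np.cos(2.0 * np.pi * np.outer(np.asarray(lag_times), np.asarray(freqs)))
    return (power @ phase.T) / total


def autocorrelation_profile(
    values: np.ndarray, grids: SpectralGrids
) -> AutocorrelationProfile:
    """Periodogram-based autocorrelation profile of one (possibly gappy) series."""
    power = lomb_scargle_power(values, grids.times, grids.freqs)
    rho = autocorrelations(power, grids.freqs, grids.lag_times)
    return AutocorrelationProfile(lags=np.arange(grids.n_lags + 1), rho=rho)


@dataclass
class NullDistribution:
    """Bootstrap null quantiles and the distributions behind them.

    rho_q[l-1] is the per-lag threshold for lags 1..n_lags at ``level``;
    max_q / min_q bound the spike tests (min_q is the lower-tail quantile of
    bootstrap minima).  The sorted bootstrap statistics are retained so that
    empirical p-values can be computed for the FDR gate.
    """

    rho_q: np.ndarray
    max_q: float
    min_q: float
    level: float
    n_boot: int
    seed: int
    rho_sorted: np.ndarray = field(repr=False)      # (n_boot, n_lags), sorted per lag
    maxima_sorted: np.ndarray = field(repr=False)
    minima_sorted: np.ndarray = field(repr=False)

    def lag_p_value(self, lag: int, rho_obs: float) -> float:
        """Upper-tail empirical p of rho at one lag (1-based)."""
        col = self.rho_sorted[:, lag - 1]
        n_ge = len(col) - np.searchsorted(col, rho_obs, side="left")
        return float((1 + n_ge) / (len(col) + 1))

    def spike_max_p_value(self, x_max: float) -> float:
        n = len(self.maxima_sorted)
        n_ge = n - np.searchsorted(self.maxima_sorted, x_max, side="left")
        return float((1 + n_ge) / (n + 1))

    def spike_min_p_value(self, x_min: float) -> float:
        n_le = np.searchsorted(self.minima_sorted, x_min, side="right")
        return float((1 + n_le) / (len(self.minima_sorted) + 1))


def bootstrap_series(
    pool: np.ndarray, n_series: int, n_points: int, rng: np.random.Generator
) -> np.ndarray:
    """Null series drawn i.i.d. with replacement from a value pool."""
    pool = np.asarray(pool, dtype=float)
    pool = pool[~np.isnan(pool)]
    if pool.size == 0:
        raise ValueError("empty bootstrap pool")
    return rng.choice(pool, size=(n_series, n_points), replace=True)


def bootstrap_autocorrelations(
    pool: np.ndarray, grids: SpectralGrids, n_boot: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Bootstrap null series and their autocorrelation profiles.

    Returns (series, rho) with shapes (n_boot, N) and (n_boot, n_lags + 1).
    Series whose periodogram is identically zero (all drawn values equal;
    possible only for tiny pools) get rho = 1 at lag 0 and 0 elsewhere.
    """
    series = bootstrap_series(pool, n_boot, len(grids.times), rng)
    power = _batch_power(series, grids.times, grids.freqs)
    total = power.sum(axis=1)
    ok = total > 0
    rho = np.zeros((n_boot, grids.n_lags + 1))
    rho[:, 0] = 1.0
    if ok.any():
        phase = np.cos(2.0 * np.pi * np.outer(grids.lag_times, grids.freqs))
        rho[ok] = (power[ok] @ phase.T) / total[ok, None]
    return series, rho


def build_null(
    pool: np.ndarray,
    grids: SpectralGrids,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    seed: int = 0,
) -> NullDistribution:
    """Bootstrap null distribution for one subject's pooled values."""
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    series, rho = bootstrap_autocorrelations(pool, grids, n_boot, rng)
    rho_lags = rho[:, 1:]
    rho_q = np.quantile(rho_lags, level, axis=0)
    maxima = series.max(axis=1)
    minima = series.min(axis=1)
    return NullDistribution(
        rho_q=rho_q,
        max_q=float(np.quantile(maxima, level)),
        min_q=float(np.quantile(minima, 1.0 - level)),
        level=level,
        n_boot=n_boot,
        seed=seed,
        rho_sorted=np.sort(rho_lags, axis=0),
        maxima_sorted=np.sort(maxima),
        minima_sorted=np.sort(minima),
    )


def classify_series(
    profile: AutocorrelationProfile,
    values: np.ndarray,
    null: NullDistribution,
) -> TrendClass:
    """Assign one series its trend class.

    ``values`` are the series' normalized intensities (same scale as the
    bootstrap pool); only series failing the lag criterion are tested for
    spikes.  Equality with a threshold counts as exceedance for the lag
    test (>=); spike tests are strict (> / <).  The reported p-value is the
    empirical tail probability of the deciding statistic — rho at the
    deciding lag M, or the spike extremum — so a classed series always has
    p below 1 - level, and the FDR gate composes consistently with the
    classification rule.
    """
    rho = np.asarray(profile.rho, dtype=float)
    if len(rho) - 1 != len(null.rho_q):
        raise ValueError("profile and null distribution lag ranges differ")
    exceed = np.nonzero(rho[1:] >= null.rho_q)[0]
    if exceed.size:
        m = int(exceed[0]) + 1
        return TrendClass(LAG, lag=m, p_value=null.lag_p_value(m, float(rho[m])))
    values = np.asarray(values, dtype=float)
    x_max = float(np.nanmax(values))
    x_min = float(np.nanmin(values))
    if x_max > null.max_q:
        return TrendClass(SPIKE_MAX, p_value=null.spike_max_p_value(x_max))
    if x_min < null.min_q:
        return TrendClass(SPIKE_MIN, p_value=null.spike_min_p_value(x_min))
    p_best = min(
        null.lag_p_value(lag, float(rho[lag])) for lag in range(1, len(rho))
    )
    return TrendClass(NO_TREND, p_value=p_best)


def subject_seed(seed: int, subject_index: int) -> int:
    """Stable per-subject bootstrap seed derived from the run seed."""
    return int(np.random.SeedSequence([seed, subject_index]).generate_state(1)[0] % (2**31))


def classify_cohort(
    normalized: pd.DataFrame,
    grid: TimeGrid | None = None,
    n_boot: int = DEFAULT_N_BOOT,
    level: float = DEFAULT_LEVEL,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, NullDistribution]]:
    """Classify every series of a cohort, subject by subject.

    ``normalized`` is the wide unit-norm matrix from preprocessing, indexed
    by (subject_id, measurement_id).  Each subject gets its own bootstrap
    null built from that subject's pooled present values, and a
    Benjamini-Hochberg gate at ``alpha`` across the subject's measurements.

    Returns the classification table (columns kind, lag, p_value,
    significant) and the per-subject null distributions.
    """
    grid = grid or TimeGrid()
    grids = spectral_grids(grid)
    rows = []
    nulls: dict[str, NullDistribution] = {}
    subjects = normalized.index.get_level_values("subject_id").unique()
    for si, sid in enumerate(sorted(subjects)):
        block = normalized.xs(sid, level="subject_id")
        pool = block.to_numpy(dtype=float).ravel()
        null = build_null(pool, grids, n_boot=n_boot, level=level,
                          seed=subject_seed(seed, si))
        nulls[sid] = null
        sub_rows = []
        for mid, series in block.iterrows():
            values = series.to_numpy(dtype=float)
            profile = autocorrelation_profile(values, grids)
            cls = classify_series(profile, values, null)
            sub_rows.append((sid, mid, cls.kind, cls.lag, cls.p_value))
        pvals = np.array([r[4] for r in sub_rows])
        sig = significance_adjust(pvals, alpha=alpha)
        for r, s in zip(sub_rows, sig):
            rows.append((*r, bool(s) and r[2] != NO_TREND))
    table = pd.DataFrame(
        rows,
        columns=["subject_id", "measurement_id", "kind", "lag", "p_value", "significant"],
    )
    return table, nulls


def significance_adjust(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg selection at level alpha; returns a boolean mask."""
    p_values = np.asarray(p_values, dtype=float)
    if p_values.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p_values < 0) | (p_values > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p_values, alpha=alpha, method="fdr_bh")
    return reject
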