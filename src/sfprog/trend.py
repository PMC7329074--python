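"""Per-index linear trends over visit-series prefixes.

Progression on a single index is assessed by ordinary least squares of the
index value on visit time (months from baseline), with a one-tailed Student-t
test that the slope is negative (worsening). The one-tailed p-value is the
lower-tail probability of t(n-2) at the observed t-statistic, so under a
stable eye with Gaussian noise it is Uniform(0, 1) and the test holds its
nominal specificity by construction.

Fits over series prefixes (the first 5, 6, ... visits) are independent — no
sequential adjustment — mirroring how series-length effects are studied.
Series with no deterioration direction of their own use worsening = negative
slope; a ``direction`` flag exists for indices where worsening is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats

__all__ = ["EyeSeries", "TrendResult", "fit_trend", "fit_all_prefixes", "batch_ols"]

DEFAULT_LENGTHS = (5, 6, 7, 8, 9)


@dataclass
class EyeSeries:
    """Ordered per-eye visit series for one index.

    ``times`` are months from baseline (strictly increasing, times[0] == 0 by
    convention); ``values`` are in the index's native units (µm or dB).
    """

    eye_id: str
    index_name: str
    times: np.ndarray
    values: np.ndarray
    subgroups: dict[str, str] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a series needs at least 2 visits")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("visit times must be strictly increasing")
        if not (np.all(np.isfinite(self.times)) and np.all(np.isfinite(self.values))):
            raise ValueError("times and values must be finite (no missing values)")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TrendResult:
    """OLS slope and one-tailed test for one series prefix."""

    slope: float
    stderr: float
    t_stat: float
    df: int
    p_one_tailed: float
    n: int


def fit_trend(series: EyeSeries, prefix_length: int | None = None, direction: str = "negative") -> TrendResult:
    """Fit OLS on the first ``prefix_length`` visits; one-tailed slope test.

    Parameters
    ----------
    series
        The visit series.
    prefix_length
        Number of leading visits to use; defaults to the whole series. Must be
        >= 3 so the residual degrees of freedom (n - 2) are positive.
    direction
        ``"negative"``: worsening is a negative slope (RNFLT, MS);
        ``"positive"``: worsening is a positive slope.

    Notes
    -----
    A perfect fit (zero residual variance) has an undefined t-statistic; the
    limiting p-values are used: 0 when the slope worsens, 1 when it improves,
    0.5 when it is exactly flat.
    """
    n = len(series) if prefix_length is None else int(prefix_length)
    if n < 3:
        raise ValueError(f"prefix_length must be >= 3 (got {n}); df would be < 1")
    if n > len(series):
        raise ValueError(f"prefix_length {n} exceeds series length {len(series)}")
    if direction not in ("negative", "positive"):
        raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")

    t = series.times[:n]
    y = series.values[:n]
    if np.ptp(t) == 0:
        raise ValueError("zero time variance in the requested prefix")

    res = stats.linregress(t, y)
    slope, se = float(res.slope), float(res.stderr)
    df = n - 2
    sign = 1.0 if direction == "negative" else -1.0

    # scipy reports nan stderr when the residuals vanish; detect that case
    # explicitly so the perfect-fit limits below apply.
    sse = float(np.sum((y - res.intercept - slope * t) ** 2))
    if sse == 0.0:
        se = 0.0
    if se == 0.0:  # perfect fit: limit of the t-test
        if slope * sign < 0:
            return TrendResult(slope, 0.0, -np.inf, df, 0.0, n)
        if slope * sign > 0:
            return TrendResult(slope, 0.0, np.inf, df, 1.0, n)
        return TrendResult(slope, 0.0, 0.0, df, 0.5, n)

    t_stat = slope / se
    # lower tail for worsening-negative; upper tail when worsening is positive
    p = float(stats.t.cdf(sign * t_stat, df))
    return TrendResult(slope, se, float(t_stat), df, p, n)


def fit_all_prefixes(
    series: EyeSeries,
    lengths: tuple[int, ...] | list[int] | set[int] = DEFAULT_LENGTHS,
    direction: str = "negative",
) -> dict[int, TrendResult]:
    """Independent prefix fits for every requested series length."""
    lengths = sorted(int(k) for k in lengths)
    for k in lengths:
        if k < 3:
            raise ValueError(f"series length {k} is below the minimum of 3")
        if k > len(series):
            raise ValueError(
                f"series length {k} exceeds the {len(series)}-visit series for eye {series.eye_id}"
            )
    return {k: fit_trend(series, k, direction=direction) for k in lengths}


def batch_ols(times: np.ndarray, values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised OLS over many series at once.

    ``times`` and ``values`` are (n_series, n_visits) arrays. Returns arrays of
    slopes, one-tailed p-values for slope < 0, and t-statistics. Used by the
    simulator where tens of thousands of series are fitted; agrees with
    :func:`fit_trend` to numerical precision (enforced by tests).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape or times.ndim != 2:
        raise ValueError("times and values must be matching 2-D arrays")
    n = times.shape[1]
    if n < 3:
        raise ValueError("need at least 3 visits per series")

    tc = times - times.mean(axis=1, keepdims=True)
    yc = values - values.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", tc, tc)
    if np.any(sxx == 0):
        raise ValueError("zero time variance in at least one series")
    slope = np.einsum("ij,ij->i", tc, yc) / sxx
    resid = yc - slope[:, None] * tc
    sse = np.einsum("ij,ij->i", resid, resid)
    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(sse / df / sxx)
        t_stat = slope / se
    p = stats.t.cdf(t_stat, df)
    # perfect-fit limits
    exact = se == 0
    if np.any(exact):
        t_stat = np.where(exact, np.sign(slope) * np.inf, t_stat)
        t_stat = np.where(exact & (slope == 0), 0.0, t_stat)
        p = np.where(exact, np.where(slope < 0, 0.0, np.where(slope > 0, 1.0, 0.5)), p)
    return slope, p, t_stat
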