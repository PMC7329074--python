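"""Cohort-level outcome metrics for progression criteria.

Because true progression status is unknown in real cohorts, criteria are
compared at fixed specificity through three lenses:

* positive rate — the percentage of eyes flagged as progressing, a
  sensitivity proxy once specificity is held constant, with a binomial
  confidence interval (Wilson score by default);
* agreement — Cohen's kappa between two criteria on the same eyes, or between
  consecutive series lengths for the same criterion, with the conventional
  qualitative bands (slight/fair/moderate/substantial/almost perfect);
* time-to-detection — a Kaplan-Meier curve where the "event" is the first
  series length at which an eye is flagged, timed at that visit; eyes never
  flagged are right-censored at their last analysed visit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "FlagTable",
    "PositiveRateSummary",
    "KappaResult",
    "KMCurve",
    "positive_rate",
    "positive_rate_table",
    "cohens_kappa",
    "between_criterion_agreement",
    "between_visit_agreement",
    "km_time_to_detection",
]

logger = logging.getLogger(__name__)

KAPPA_BANDS = (
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.00, "almost perfect"),
)


@dataclass
class FlagTable:
    """Eyes × series-lengths × criteria boolean progression calls.

    ``flags`` is long-format with columns ``eye_id, series_length, criterion,
    flag``; every (eye, length, criterion) cell must be present so that all
    metrics are computed on identical eye sets. ``visit_times`` (columns
    ``eye_id, visit, month``, visits 1-based) supplies event timing for the
    survival analysis.
    """

    flags: pd.DataFrame
    visit_times: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = {"eye_id", "series_length", "criterion", "flag"}
        missing = required - set(self.flags.columns)
        if missing:
            raise ValueError(f"flags missing columns: {sorted(missing)}")
        if self.flags.duplicated(["eye_id", "series_length", "criterion"]).any():
            raise ValueError("duplicate (eye, length, criterion) cells in flag table")
        counts = self.flags.groupby(["series_length", "criterion"])["eye_id"].count()
        if counts.nunique() > 1:
            raise ValueError("criteria must be evaluated on identical eye sets")

    @property
    def eyes(self) -> list:
        return sorted(self.flags["eye_id"].unique())

    @property
    def criteria(self) -> list[str]:
        return sorted(self.flags["criterion"].unique())

    @property
    def series_lengths(self) -> list[int]:
        return sorted(int(k) for k in self.flags["series_length"].unique())

    def vector(self, criterion: str, series_length: int) -> pd.Series:
        """Boolean flags for one cell, indexed by eye_id (sorted)."""
        sub = self.flags[
            (self.flags["criterion"] == criterion)
            & (self.flags["series_length"] == series_length)
        ]
        if sub.empty:
            raise KeyError(f"no flags for criterion {criterion!r} at length {series_length}")
        return sub.set_index("eye_id")["flag"].sort_index().astype(bool)


@dataclass(frozen=True)
class PositiveRateSummary:
    criterion: str
    series_length: int
    rate: float  # percent
    ci_low: float
    ci_high: float
    n_eyes: int
    n_flagged: int


def positive_rate(
    flags: FlagTable,
    criterion: str,
    series_length: int,
    ci_method: str = "wilson",
    conf_level: float = 0.95,
) -> PositiveRateSummary:
    """Percentage of eyes flagged, with a binomial CI (Wilson default, 'beta'
    for exact Clopper-Pearson)."""
    v = flags.vector(criterion, series_length)
    n = len(v)
    if n == 0:
        raise ValueError("empty cohort")
    k = int(v.sum())
    lo, hi = proportion_confint(k, n, alpha=1 - conf_level, method=ci_method)
    return PositiveRateSummary(criterion, series_length, 100.0 * k / n, 100.0 * lo, 100.0 * hi, n, k)


def positive_rate_table(flags: FlagTable, ci_method: str = "wilson") -> pd.DataFrame:
    """Tidy table of positive rates for every criterion × series length."""
    rows = [
        positive_rate(flags, c, k, ci_method=ci_method).__dict__
        for c in flags.criteria
        for k in flags.series_lengths
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KappaResult:
    kappa: float  # nan when undefined
    band: str | None
    observed_agreement: float
    expected_agreement: float
    n: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.kappa)


def _band(kappa: float) -> str:
    if kappa < 0:
        return "less than chance"
    for upper, label in KAPPA_BANDS:
        if kappa <= upper:
            return label
    return "almost perfect"


def cohens_kappa(flags_a, flags_b) -> KappaResult:
    """Cohen's unweighted kappa between two binary classifications.

    Undefined (reported as nan) when both raters are constant and identical,
    since the chance-agreement denominator 1 - p_e vanishes.
    """
    a = np.asarray(flags_a, dtype=bool)
    b = np.asarray(flags_b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be 1-D boolean vectors of equal length")
    n = len(a)
    if n < 2:
        raise ValueError("kappa needs at least 2 observations")

    po = float(np.mean(a == b))
    pa, pb = float(np.mean(a)), float(np.mean(b))
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        logger.info("kappa undefined: both classifications constant and identical")
        return KappaResult(float("nan"), None, po, pe, n)
    kappa = (po - pe) / (1 - pe)
    return KappaResult(kappa, _band(kappa), po, pe, n)


def between_criterion_agreement(flags: FlagTable, series_length: int | None = None) -> pd.DataFrame:
    """Pairwise kappa between criteria, per series length."""
    lengths = flags.series_lengths if series_length is None else [series_length]
    crits = flags.criteria
    rows = []
    for k in lengths:
        vecs = {c: flags.vector(c, k).to_numpy() for c in crits}
        for i, ca in enumerate(crits):
            for cb in crits[i + 1 :]:
                res = cohens_kappa(vecs[ca], vecs[cb])
                rows.append(
                    {
                        "series_length": k,
                        "criterion_a": ca,
                        "criterion_b": cb,
                        "kappa": res.kappa,
                        "band": res.band,
                    }
                )
    return pd.DataFrame(rows)


def between_visit_agreement(flags: FlagTable, criterion: str) -> pd.DataFrame:
    """Kappa between flags at consecutive series lengths for one criterion."""
    lengths = flags.series_lengths
    rows = []
    for k1, k2 in zip(lengths, lengths[1:]):
        res = cohens_kappa(flags.vector(criterion, k1), flags.vector(criterion, k2))
        rows.append(
            {
                "criterion": criterion,
                "length_a": k1,
                "length_b": k2,
                "kappa": res.kappa,
                "band": res.band,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class KMCurve:
    """Product-limit time-to-detection curve for one criterion."""

    criterion: str
    times: np.ndarray  # months, starting at 0
    survival: np.ndarray  # P(not yet flagged)
    at_risk: np.ndarray
    median_months: float | None  # None when the curve never reaches 0.5
    n_events: int
    n_censored: int
    durations: np.ndarray = dc_field(repr=False, default=None)
    events: np.ndarray = dc_field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"month": self.times, "survival": self.survival, "at_risk": self.at_risk}
        )


def km_time_to_detection(flags: FlagTable, criterion: str) -> KMCurve:
    """Kaplan-Meier estimate of time until an eye is first flagged.

    The event for an eye is the smallest analysed series length k at which the
    criterion flags it; the event time is the month of that k-th visit. Eyes
    never flagged are right-censored at their last analysed visit.
    """
    if flags.visit_times is None:
        raise ValueError("flag table carries no visit times; cannot run survival analysis")
    vt = flags.visit_times.set_index(["eye_id", "visit"])["month"]
    lengths = flags.series_lengths
    last_k = lengths[-1]

    durations, events = [], []
    for eye in flags.eyes:
        event_k = None
        for k in lengths:
            if flags.vector(criterion, k).loc[eye]:
                event_k = k
                break
        k_used = event_k if event_k is not None else last_k
        try:
            month = float(vt.loc[(eye, k_used)])
        except KeyError:
            raise ValueError(f"missing visit time for eye {eye!r}, visit {k_used}") from None
        durations.append(month)
        events.append(event_k is not None)

    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)

    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(sf.index).to_numpy(dtype=float)
    med = float(kmf.median_survival_time_)
    median = None if math.isinf(med) else med

    return KMCurve(
        criterion=criterion,
        times=times,
        survival=surv,
        at_risk=at_risk,
        median_months=median,
        n_events=int(events.sum()),
        n_censored=int((~events).sum()),
        durations=durations,
        events=events,
    )
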