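"""Cohort input/output, QC filters, and end-to-end assessment.

Cohorts are long-format tables of per-eye, per-visit index measurements. The
native schema is ``eye_id, visit, month, index_name, value`` (months from each
eye's baseline), but arbitrary CSV layouts — including wide files that carry
one column per index and date columns instead of months — are accommodated
through a :class:`ColumnMap`, so deposited datasets with their own headers can
be read without editing the file.

Optional QC mirrors common longitudinal inclusion criteria: a minimum number
of visits per eye (default 9), consecutive visits separated by at least 2 and
at most 36 months, and, when both a structural and a functional test date are
present, the two tests of a visit taken no more than 30 days apart. Excluded
eyes are reported, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import pandas as pd
import yaml

from .criteria import CalibratedCriterion, CriterionNode, calibrate
from .evaluation import (
    FlagTable,
    KMCurve,
    between_criterion_agreement,
    between_visit_agreement,
    km_time_to_detection,
    positive_rate_table,
)
from .trend import EyeSeries, fit_all_prefixes

__all__ = [
    "ColumnMap",
    "CohortTable",
    "AssessmentResult",
    "load_cohort",
    "save_cohort",
    "cohort_series",
    "run_assessment",
]

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 30.4375  # mean Gregorian month


@dataclass
class ColumnMap:
    """Mapping from an arbitrary CSV layout onto the native cohort schema.

    ``layout`` is ``"long"`` (one row per eye-visit-index, with ``index_name``
    and ``value`` columns) or ``"wide"`` (one row per eye-visit, one column
    per index named through ``index_columns``). Exactly one of ``month`` or
    ``date`` must be set; ISO-8601 dates are converted to fractional months
    from each eye's first visit. ``pairing_dates`` optionally names per-index
    date columns (wide layout) checked against the 30-day pairing rule.
    """

    eye_id: str = "eye_id"
    layout: str = "long"
    month: str | None = "month"
    date: str | None = None
    index_name: str = "index_name"
    value: str = "value"
    index_columns: dict[str, str] = dc_field(default_factory=dict)  # csv col -> index name
    patient_id: str | None = None
    subgroups: dict[str, str] = dc_field(default_factory=dict)  # csv col -> label name
    pairing_dates: dict[str, str] = dc_field(default_factory=dict)  # index name -> csv col

    @staticmethod
    def from_yaml(path) -> "ColumnMap":
        with open(path) as fh:
            return ColumnMap(**(yaml.safe_load(fh) or {}))

    def required_columns(self) -> list[str]:
        cols = [self.eye_id]
        if (self.month is None) == (self.date is None):
            raise ValueError("exactly one of 'month' or 'date' must be set")
        cols.append(self.month or self.date)
        if self.layout == "long":
            cols += [self.index_name, self.value]
        elif self.layout == "wide":
            if not self.index_columns:
                raise ValueError("wide layout needs index_columns")
            cols += list(self.index_columns)
        else:
            raise ValueError(f"layout must be 'long' or 'wide', got {self.layout!r}")
        return cols


@dataclass
class CohortTable:
    """Normalised long-format cohort plus the QC audit trail."""

    data: pd.DataFrame  # eye_id, visit, month, index_name, value [+ extras]
    qc_report: pd.DataFrame  # eye_id, reason
    n_input_eyes: int

    @property
    def eyes(self) -> list:
        return sorted(self.data["eye_id"].unique())

    @property
    def indices(self) -> list[str]:
        return sorted(self.data["index_name"].unique())


def load_cohort(
    path,
    mapping: ColumnMap | None = None,
    *,
    min_visits: int = 9,
    spacing_months: tuple[float, float] | None = (2.0, 36.0),
    pairing_days: float | None = 30.0,
    qc: bool = True,
) -> CohortTable:
    """Read a cohort CSV, normalise times, and apply optional QC filters.

    QC exclusions operate on whole eyes and every exclusion is recorded with a
    reason; retained + excluded eye counts always equal the input count.
    Setting ``qc=False`` keeps every eye (exclusion list stays empty).
    """
    mapping = mapping or ColumnMap()
    df = pd.read_csv(path)
    missing = [c for c in mapping.required_columns() if c not in df.columns]
    if missing:
        raise ValueError(f"cannot map columns {missing} onto {sorted(df.columns)}")

    time_col = mapping.month or mapping.date
    keep = {mapping.eye_id: "eye_id", time_col: "_time"}
    if mapping.patient_id:
        keep[mapping.patient_id] = "patient_id"
    for col, label in mapping.subgroups.items():
        keep[col] = label

    if mapping.layout == "wide":
        frames = []
        for col, index in mapping.index_columns.items():
            sub = df[list(keep) + [col]].rename(columns={**keep, col: "value"})
            sub["index_name"] = index
            date_col = mapping.pairing_dates.get(index)
            if date_col:
                if date_col not in df.columns:
                    raise ValueError(f"pairing date column {date_col!r} not in file")
                sub["_pair_date"] = pd.to_datetime(df[date_col], format="ISO8601")
            frames.append(sub)
        long = pd.concat(frames, ignore_index=True)
    else:
        keep[mapping.index_name] = "index_name"
        keep[mapping.value] = "value"
        long = df[list(keep)].rename(columns=keep)

    if mapping.date:
        dates = pd.to_datetime(long["_time"], format="ISO8601")
        baseline = dates.groupby(long["eye_id"]).transform("min")
        long["month"] = (dates - baseline).dt.days / DAYS_PER_MONTH
    else:
        t = pd.to_numeric(long["_time"], errors="coerce")
        if t.isna().any():
            bad = long.index[t.isna()].tolist()[:5]
            raise ValueError(f"unparseable visit times in rows {bad}")
        long["month"] = t - t.groupby(long["eye_id"]).transform("min")
    long = long.drop(columns=["_time"])

    dup = long.duplicated(["eye_id", "month", "index_name"], keep=False)
    if dup.any():
        rows = long.index[dup].tolist()[:10]
        raise ValueError(f"duplicate (eye, visit, index) records in rows {rows}")

    # assign 1-based visit ranks per eye from the sorted distinct visit months
    long = long.sort_values(["eye_id", "month", "index_name"], kind="mergesort")
    long["visit"] = long.groupby("eye_id")["month"].transform(
        lambda m: m.rank(method="dense").astype(int)
    )

    n_input = long["eye_id"].nunique()
    exclusions: list[dict] = []
    if qc:
        for eye, grp in long.groupby("eye_id"):
            months = sorted(grp["month"].unique())
            reason = None
            if len(months) < min_visits:
                reason = f"insufficient visits ({len(months)} < {min_visits})"
            elif spacing_months is not None:
                lo, hi = spacing_months
                gaps = [b - a for a, b in zip(months, months[1:])]
                if any(g < lo for g in gaps):
                    reason = f"spacing < {lo:g} months"
                elif any(g > hi for g in gaps):
                    reason = f"spacing > {hi:g} months"
            if reason is None and pairing_days is not None and "_pair_date" in grp.columns:
                pair = grp.dropna(subset=["_pair_date"])
                if not pair.empty:
                    spread = pair.groupby("visit")["_pair_date"].agg(
                        lambda d: (d.max() - d.min()).days
                    )
                    if (spread > pairing_days).any():
                        v = int(spread.idxmax())
                        reason = f"structure-function pairing > {pairing_days:g} days at visit {v}"
            if reason is not None:
                exclusions.append({"eye_id": eye, "reason": reason})
                logger.info("QC excluded eye %s: %s", eye, reason)

    excluded = {e["eye_id"] for e in exclusions}
    retained = long[~long["eye_id"].isin(excluded)].copy()
    retained = retained.drop(columns=["_pair_date"], errors="ignore")
    qc_report = pd.DataFrame(exclusions, columns=["eye_id", "reason"])
    return CohortTable(data=retained.reset_index(drop=True), qc_report=qc_report, n_input_eyes=n_input)


def save_cohort(cohort: CohortTable | pd.DataFrame, path) -> None:
    """Write a cohort back out in the native long schema (lossless round trip)."""
    data = cohort.data if isinstance(cohort, CohortTable) else cohort
    data.to_csv(path, index=False)


def cohort_series(data: pd.DataFrame) -> dict[str, dict[str, EyeSeries]]:
    """Pivot a native long cohort into ``{eye_id: {index_name: EyeSeries}}``."""
    out: dict[str, dict[str, EyeSeries]] = {}
    for (eye, index), grp in data.groupby(["eye_id", "index_name"], sort=True):
        grp = grp.sort_values("month")
        out.setdefault(str(eye), {})[str(index)] = EyeSeries(
            eye_id=str(eye),
            index_name=str(index),
            times=grp["month"].to_numpy(),
            values=grp["value"].to_numpy(),
        )
    return out


@dataclass
class AssessmentResult:
    """Everything the end-to-end pipeline produces for one cohort."""

    calibrated: dict[str, CalibratedCriterion]
    flag_table: FlagTable
    positive_rates: pd.DataFrame
    criterion_agreement: pd.DataFrame
    visit_agreement: pd.DataFrame
    km_curves: dict[str, KMCurve]

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.flag_table.flags.to_csv(out / "flags.csv", index=False)
        if self.flag_table.visit_times is not None:
            self.flag_table.visit_times.to_csv(out / "visit_times.csv", index=False)
        self.positive_rates.to_csv(out / "positive_rates.csv", index=False)
        self.criterion_agreement.to_csv(out / "criterion_agreement.csv", index=False)
        self.visit_agreement.to_csv(out / "visit_agreement.csv", index=False)
        pd.DataFrame(
            [
                {
                    "criterion": label,
                    "target_specificity": c.target_specificity,
                    "marginal_alpha": c.marginal_alpha,
                }
                for label, c in self.calibrated.items()
            ]
        ).to_csv(out / "calibration.csv", index=False)
        for label, curve in self.km_curves.items():
            safe = "".join(ch if ch.isalnum() else "_" for ch in label)
            curve.to_frame().to_csv(out / f"km_{safe}.csv", index=False)


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage label
        raise RuntimeError(f"[{name}] {exc}") from exc


def run_assessment(
    cohort: CohortTable | pd.DataFrame,
    criteria: dict[str, CriterionNode | list | str],
    specificity: float = 0.95,
    lengths: tuple[int, ...] = (5, 6, 7, 8, 9),
    ci_method: str = "wilson",
    survival: bool = True,
) -> AssessmentResult:
    """Calibrate criteria, fit per-eye trends, flag progression, and score.

    Deterministic end to end: calibration is analytic, trend fits are OLS, and
    each stage failure aborts with a message naming the stage. Criteria may be
    given as :class:`CriterionNode` trees or nested-list expressions such as
    ``["ANY", "RNFLT_global", "MS_global"]``.
    """
    data = cohort.data if isinstance(cohort, CohortTable) else cohort

    trees = {label: CriterionNode.from_spec(spec) for label, spec in criteria.items()}
    calibrated = {
        label: _stage("calibrate", calibrate, tree, specificity) for label, tree in trees.items()
    }
    for label, c in calibrated.items():
        logger.info(
            "calibrated %s at specificity %.4f: marginal alpha %.6f",
            label, specificity, c.marginal_alpha,
        )

    series = _stage("load", cohort_series, data)
    lengths = tuple(sorted(int(k) for k in lengths))

    flag_rows, time_rows = [], []
    for eye, per_index in series.items():
        pvals: dict[int, dict[str, float]] = {k: {} for k in lengths}
        for index, s in per_index.items():
            fits = _stage("trend", fit_all_prefixes, s, lengths)
            for k, res in fits.items():
                pvals[k][index] = res.p_one_tailed
        any_series = next(iter(per_index.values()))
        for rank, month in enumerate(any_series.times, start=1):
            time_rows.append({"eye_id": eye, "visit": rank, "month": float(month)})
        for k in lengths:
            for label, crit in calibrated.items():
                fired = _stage("evaluate", crit.evaluate, pvals[k])
                flag_rows.append(
                    {"eye_id": eye, "series_length": k, "criterion": label, "flag": bool(fired)}
                )

    flag_table = _stage(
        "flags",
        FlagTable,
        pd.DataFrame(flag_rows),
        pd.DataFrame(time_rows).drop_duplicates(["eye_id", "visit"]),
    )

    rates = _stage("positive_rates", positive_rate_table, flag_table, ci_method)
    agreement_cols = ["series_length", "criterion_a", "criterion_b", "kappa", "band"]
    visit_cols = ["criterion", "length_a", "length_b", "kappa", "band"]
    if len(flag_table.eyes) < 2:
        logger.info("fewer than 2 eyes: agreement statistics undefined, tables left empty")
        crit_kappa = pd.DataFrame(columns=agreement_cols)
        visit_kappa = pd.DataFrame(columns=visit_cols)
    else:
        crit_kappa = _stage("agreement", between_criterion_agreement, flag_table)
        visit_kappa = pd.concat(
            [
                _stage("agreement", between_visit_agreement, flag_table, c)
                for c in flag_table.criteria
            ],
            ignore_index=True,
        )
    km_curves = (
        {c: _stage("survival", km_time_to_detection, flag_table, c) for c in flag_table.criteria}
        if survival
        else {}
    )
    return AssessmentResult(
        calibrated=calibrated,
        flag_table=flag_table,
        positive_rates=rates,
        criterion_agreement=crit_kappa,
        visit_agreement=visit_kappa,
        km_curves=km_curves,
    )
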