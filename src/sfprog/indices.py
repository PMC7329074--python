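"""Summary indices from raw measurements.

Visual-field mean sensitivity (MS) is computed from pointwise 24-2 static
automated perimetry (SAP) sensitivities: decibel values are converted to the
linear differential-light-sensitivity scale (``linear = 10**(dB/10)``),
averaged over the locations of interest, and converted back to dB. Averaging
in the linear scale avoids the overestimation of defect depth that arithmetic
dB averaging produces. The two locations adjacent to the physiological blind
spot are always excluded, leaving 52 informative locations on a full 24-2
grid.

Sector indices (infero-temporal IT, supero-temporal ST, central) use a
location-to-sector assignment shipped as an editable CSV transcribed from the
published Garway-Heath structure-function map; left-eye fields are mirrored
into right-eye orientation before assignment. Retinal nerve fiber layer
thickness (RNFLT) indices arrive pre-summarised from the instrument and pass
through untouched, so this module only needs the perimetry side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "BLIND_SPOT_LOCATIONS",
    "IndexValue",
    "PointwiseField",
    "ReliabilityResult",
    "SectorMap",
    "db_to_linear",
    "linear_to_db",
    "garway_heath_map",
    "central_map",
    "mean_sensitivity",
    "reliability_filter",
    "read_pointwise_csv",
]

Location = tuple[int, int]

#: 24-2 locations flanking the blind spot, right-eye orientation (x temporal).
BLIND_SPOT_LOCATIONS: frozenset[Location] = frozenset({(15, 3), (15, -3)})

#: Number of informative locations on a complete 24-2 grid.
N_FULL_GRID = 54
N_INFORMATIVE = 52


def db_to_linear(db: float) -> float:
    """Decibel sensitivity to linear scale, ``10**(dB/10)``.

    This is the single place the dB convention lives; MS computation and any
    future staging code must go through it.
    """
    return 10.0 ** (db / 10.0)


def linear_to_db(linear: float) -> float:
    """Inverse of :func:`db_to_linear`."""
    return 10.0 * math.log10(linear)


@dataclass(frozen=True)
class IndexValue:
    """One per-visit observation of a summary index.

    ``value`` is in µm for RNFLT indices and dB for MS indices;
    ``visit_time`` is months from the eye's baseline visit.
    """

    index_name: str
    value: float
    visit_time: float | None = None


@dataclass
class PointwiseField:
    """A single 24-2 SAP test: pointwise sensitivities plus reliability.

    ``sensitivities`` maps ``(x_deg, y_deg)`` locations (right-eye orientation
    unless ``laterality == "left"``) to sensitivity in dB. Reliability
    fractions are in [0, 1].
    """

    eye_id: str
    laterality: str = "right"
    sensitivities: dict[Location, float] = dc_field(default_factory=dict)
    fp: float | None = None
    fn: float | None = None
    fl: float | None = None
    visit_time: float | None = None

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")
        for loc, v in self.sensitivities.items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite sensitivity at {loc}: {v}")

    def to_right_orientation(self) -> "PointwiseField":
        """Mirror a left-eye field about the vertical midline (negate x)."""
        if self.laterality == "right":
            return self
        mirrored = {(-x, y): v for (x, y), v in self.sensitivities.items()}
        return PointwiseField(
            eye_id=self.eye_id,
            laterality="right",
            sensitivities=mirrored,
            fp=self.fp,
            fn=self.fn,
            fl=self.fl,
            visit_time=self.visit_time,
        )


@dataclass(frozen=True)
class SectorMap:
    """Assignment of 24-2 locations to named sectors (right-eye orientation)."""

    name: str
    assignment: Mapping[Location, str]

    def locations(self, sector: str) -> frozenset[Location]:
        return frozenset(loc for loc, s in self.assignment.items() if s == sector)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.assignment.values():
            out[s] = out.get(s, 0) + 1
        return out


def _load_default_assignment() -> dict[Location, str]:
    with resources.files("sfprog.data").joinpath("garway_heath_24_2.csv").open() as fh:
        df = pd.read_csv(fh)
    return {(int(r.x_deg), int(r.y_deg)): str(r.sector) for r in df.itertuples()}


_DEFAULT_ASSIGNMENT = _load_default_assignment()


def garway_heath_map() -> SectorMap:
    """The shipped Garway-Heath disc-sector assignment (IT/ST/T/N/IN/SN).

    The paper trail for this map is a published figure, not a table, so the
    shipped CSV is an editable transcription; pass your own :class:`SectorMap`
    to :func:`mean_sensitivity` to override it.
    """
    return SectorMap("garway_heath", dict(_DEFAULT_ASSIGNMENT))


def central_map() -> SectorMap:
    """Partition into the 16-point central region (|x|, |y| <= 9°) and 'other'."""
    assignment = {}
    for loc, sector in _DEFAULT_ASSIGNMENT.items():
        if sector == "blind_spot":
            assignment[loc] = "blind_spot"
        elif abs(loc[0]) <= 9 and abs(loc[1]) <= 9:
            assignment[loc] = "central"
        else:
            assignment[loc] = "other"
    return SectorMap("central", assignment)


def sector_map_from_csv(path) -> SectorMap:
    """Read a custom ``x_deg,y_deg,sector`` CSV into a :class:`SectorMap`."""
    df = pd.read_csv(path)
    missing = {"x_deg", "y_deg", "sector"} - set(df.columns)
    if missing:
        raise ValueError(f"sector map CSV missing columns: {sorted(missing)}")
    return SectorMap(
        name=str(path),
        assignment={(int(r.x_deg), int(r.y_deg)): str(r.sector) for r in df.itertuples()},
    )


def mean_sensitivity(
    field: PointwiseField,
    sector: str | None = None,
    sector_map: SectorMap | None = None,
    *,
    clamp_negative: bool = True,
    allow_partial: bool = False,
) -> IndexValue:
    """Mean sensitivity in dB over a sector (or globally), averaged linearly.

    Parameters
    ----------
    field
        The pointwise test; left eyes are mirrored to right-eye orientation
        before sector lookup.
    sector
        Sector label within ``sector_map`` (``"IT"``, ``"ST"``, ``"central"``,
        ...); ``None`` means global, i.e. every non-blind-spot location.
    sector_map
        Defaults to the Garway-Heath map for disc sectors and the central
        partition when ``sector == "central"``.
    clamp_negative
        Perimeters floor at 0 dB; negative inputs are clamped to 0 before
        linearisation. Set False to reject them instead.
    allow_partial
        When False (default), a global computation requires the full 52
        informative locations.

    Returns
    -------
    IndexValue
        ``MS_global`` or ``MS_<sector>`` in dB.
    """
    field = field.to_right_orientation()
    if sector_map is None:
        sector_map = central_map() if sector == "central" else garway_heath_map()

    if sector is None:
        wanted = None
    else:
        wanted = sector_map.locations(sector) - BLIND_SPOT_LOCATIONS
        if not wanted:
            raise ValueError(f"sector {sector!r} has no locations in map {sector_map.name!r}")

    values = []
    for loc, db in field.sensitivities.items():
        if loc in BLIND_SPOT_LOCATIONS:
            continue
        if wanted is not None and loc not in wanted:
            continue
        if db < 0:
            if not clamp_negative:
                raise ValueError(f"negative sensitivity {db} dB at {loc} (clamping disabled)")
            db = 0.0
        values.append(db)

    if sector is None and not allow_partial and len(values) != N_INFORMATIVE:
        raise ValueError(
            f"global MS requires {N_INFORMATIVE} non-blind-spot locations, got {len(values)}"
        )
    if wanted is not None and not allow_partial and len(values) != len(wanted):
        raise ValueError(
            f"sector {sector!r} expects {len(wanted)} locations, got {len(values)}"
        )
    if not values:
        raise ValueError(f"no locations available for sector {sector!r} after exclusions")

    linear_mean = sum(db_to_linear(v) for v in values) / len(values)
    name = "MS_global" if sector is None else f"MS_{sector}"
    return IndexValue(index_name=name, value=linear_to_db(linear_mean), visit_time=field.visit_time)


@dataclass(frozen=True)
class ReliabilityResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # allows `if reliability_filter(...)`
        return self.passed


def reliability_filter(
    field: PointwiseField,
    max_fp: float = 0.33,
    max_fn: float = 0.33,
    max_fl: float = 0.33,
    *,
    missing_fails: bool = True,
) -> ReliabilityResult:
    """Standard perimetry reliability screen.

    A test fails when any of false positives, false negatives or fixation
    losses is at or above its threshold (the usual criterion is "less than
    33%", so exactly 33% fails). Missing metrics fail closed by default.
    """
    for label, value, cutoff in (
        ("FP", field.fp, max_fp),
        ("FN", field.fn, max_fn),
        ("FL", field.fl, max_fl),
    ):
        if value is None:
            if missing_fails:
                return ReliabilityResult(False, f"{label} missing")
            continue
        if value >= cutoff:
            return ReliabilityResult(False, f"{label}={value:.2f} >= {cutoff:.2f}")
    return ReliabilityResult(True)


def read_pointwise_csv(path) -> list[PointwiseField]:
    """Read long-format pointwise SAP exports.

    Expected columns: ``eye_id, visit_time, laterality, x_deg, y_deg,
    sensitivity_db, fp, fn, fl`` (reliability columns optional). One
    :class:`PointwiseField` is returned per (eye_id, visit_time) group.
    """
    df = pd.read_csv(path)
    required = {"eye_id", "visit_time", "laterality", "x_deg", "y_deg", "sensitivity_db"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"pointwise CSV missing columns: {sorted(missing)}")

    fields: list[PointwiseField] = []
    for (eye_id, visit_time), grp in df.groupby(["eye_id", "visit_time"], sort=True):
        lats = grp["laterality"].unique()
        if len(lats) != 1:
            raise ValueError(f"inconsistent laterality for eye {eye_id} at visit {visit_time}")
        sens = {
            (int(r.x_deg), int(r.y_deg)): float(r.sensitivity_db) for r in grp.itertuples()
        }
        if len(sens) != len(grp):
            raise ValueError(f"duplicate locations for eye {eye_id} at visit {visit_time}")
        first = grp.iloc[0]

        def _opt(col: str) -> float | None:
            return float(first[col]) if col in grp.columns and pd.notna(first[col]) else None

        fields.append(
            PointwiseField(
                eye_id=str(eye_id),
                laterality=str(lats[0]),
                sensitivities=sens,
                fp=_opt("fp"),
                fn=_opt("fn"),
                fl=_opt("fl"),
                visit_time=float(visit_time),
            )
        )
    return fields


def _iter_full_grid() -> Iterable[Location]:
    return _DEFAULT_ASSIGNMENT.keys()
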