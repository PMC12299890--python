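"""Data model and readers/writers for concentration-time data.

Long-format concentration tables carry columns ``subject_id``, ``time_h``,
``conc_mg_per_L`` and optionally ``blq``. Values below the limit of
quantification (BLQ) may be spelled as the sentinel strings ``BLQ`` or
``<LOQ`` in the concentration column, or as concentration 0 alongside a
truthy ``blq`` column. Internally a BLQ observation is always stored as
concentration 0 with ``blq=True``.

Units are fixed and never inferred: hours, mg/L, mg (dose), grams (body
weight). Files are comma-separated UTF-8 with a header row and ``.`` as the
decimal mark.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .nca import NCAResult

logger = logging.getLogger(__name__)

#: accepted BLQ spellings in the concentration column (case-insensitive)
BLQ_SENTINELS = frozenset({"blq", "<loq"})

#: result-table column order (per-subject report)
RESULT_COLUMNS = (
    "subject_id",
    "cmax_mg_per_L",
    "tmax_h",
    "auclast_mg_h_per_L",
    "vd_L",
    "cl_L_per_h",
    "k_per_h",
    "t_half_h",
    "mrt_h",
    "dose_mg",
    "complete",
)


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (38.625 -> 38.63 at 2 dp).

    Report tables conventionally round half up; numpy's round-half-even
    would print 38.62 instead. Uses the shortest decimal representation of
    the float so values that print as exact halves round as a reader
    expects.
    """
    import decimal

    if not math.isfinite(x):
        return x
    q = decimal.Decimal(1).scaleb(-decimals)
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ConcentrationPoint:
    """One (time, concentration, BLQ-flag) observation for one subject."""

    time_h: float
    conc_mg_per_L: float
    blq: bool = False

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError(f"negative time {self.time_h!r} h")
        if self.conc_mg_per_L < 0:
            raise ValueError(f"negative concentration {self.conc_mg_per_L!r} mg/L")
        if self.blq and self.conc_mg_per_L != 0:
            raise ValueError("BLQ observation must carry concentration 0 mg/L")


@dataclass(frozen=True)
class SubjectProfile:
    """A subject's dose, body weight and time-ordered concentration points.

    ``body_weight_g`` and ``dose_mg`` may be ``None`` until a dose table is
    attached (see :func:`attach_doses`).
    """

    subject_id: str
    points: tuple[ConcentrationPoint, ...]
    body_weight_g: float | None = None
    dose_mg: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))
        times = [p.time_h for p in self.points]
        for a, b in zip(times, times[1:]):
            if not a < b:
                raise ValueError(
                    f"subject {self.subject_id!r}: times must be strictly increasing "
                    f"(got {a} followed by {b})"
                )
        if self.body_weight_g is not None and self.body_weight_g <= 0:
            raise ValueError("body weight must be positive")
        if self.dose_mg is not None and self.dose_mg <= 0:
            raise ValueError("dose must be positive")

    @property
    def times(self) -> np.ndarray:
        return np.array([p.time_h for p in self.points], dtype=float)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.conc_mg_per_L for p in self.points], dtype=float)

    @property
    def blq_flags(self) -> np.ndarray:
        return np.array([p.blq for p in self.points], dtype=bool)

    @property
    def n_blq(self) -> int:
        return int(self.blq_flags.sum())


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design: group label -> ordered time grid, plus membership.

    ``members`` maps each group label to the subject ids sampled on that
    group's grid; it may be omitted for designs used only descriptively.
    """

    groups: Mapping[str, tuple[float, ...]]
    members: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "groups", {k: tuple(float(t) for t in v) for k, v in self.groups.items()}
        )
        object.__setattr__(
            self, "members", {k: tuple(v) for k, v in self.members.items()}
        )
        if not self.groups:
            raise ValueError("study design has no groups")
        for label, grid in self.groups.items():
            if len(grid) == 0:
                raise ValueError(f"group {label!r} has an empty time grid")
            if any(t < 0 for t in grid):
                raise ValueError(f"group {label!r} has negative times")
            if any(a >= b for a, b in zip(grid, grid[1:])):
                raise ValueError(f"group {label!r} grid is not strictly increasing")
        for label in self.members:
            if label not in self.groups:
                raise ValueError(f"members listed for unknown group {label!r}")

    @property
    def subject_ids(self) -> tuple[str, ...]:
        out: list[str] = []
        for label in self.groups:
            out.extend(self.members.get(label, ()))
        return tuple(out)


def default_study_design() -> StudyDesign:
    """The two-subgroup staggered design of the source study.

    Three rats are bled at 0, 0.25, 0.5, 1, 1.5, 12 and 24 h post-dose and
    the other three at 2, 4, 8, 36 and 48 h, so a complete profile exists
    only at the group level.
    """
    return StudyDesign(
        groups={
            "subgroup1": (0.0, 0.25, 0.5, 1.0, 1.5, 12.0, 24.0),
            "subgroup2": (2.0, 4.0, 8.0, 36.0, 48.0),
        },
        members={
            "subgroup1": ("rat1", "rat2", "rat3"),
            "subgroup2": ("rat4", "rat5", "rat6"),
        },
    )


def _parse_conc_cell(value: object) -> tuple[float, bool]:
    """Return (concentration, blq) from one concentration cell."""
    if isinstance(value, str):
        stripped = value.strip()
        if stripped.lower() in BLQ_SENTINELS:
            return 0.0, True
        value = float(stripped)
    conc = float(value)  # type: ignore[arg-type]
    if math.isnan(conc):
        raise ValueError("missing concentration value")
    return conc, False


def read_concentration_table(source, *, blq_column: str = "blq") -> list[SubjectProfile]:
    """Read a long-format concentration table into per-subject profiles.

    Parameters
    ----------
    source
        Path or open text stream of a CSV with columns ``subject_id``,
        ``time_h``, ``conc_mg_per_L`` and optionally a BLQ flag column.
    blq_column
        Name of the optional boolean BLQ column.

    Returns
    -------
    list of SubjectProfile, sorted by subject id, points sorted by time.
    Doses and body weights are left unset; see :func:`attach_doses`.
    """
    df = pd.read_csv(source, dtype={"subject_id": str}, float_precision="round_trip")
    if df.empty:
        logger.warning("concentration table %r is empty", source)
        return []
    required = {"subject_id", "time_h", "conc_mg_per_L"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"concentration table missing columns: {sorted(missing)}")

    dup = df.duplicated(subset=["subject_id", "time_h"], keep=False)
    if dup.any():
        first = df.loc[dup, ["subject_id", "time_h"]].iloc[0]
        raise ValueError(
            f"duplicate (subject, time) pair: ({first['subject_id']!r}, {first['time_h']})"
        )

    profiles: list[SubjectProfile] = []
    for subject_id, sub in df.groupby("subject_id", sort=True):
        sub = sub.sort_values("time_h")
        points = []
        for _, row in sub.iterrows():
            conc, blq = _parse_conc_cell(row["conc_mg_per_L"])
            if blq_column in sub.columns and not blq:
                blq = bool(row[blq_column])
                if blq and conc != 0:
                    raise ValueError(
                        f"subject {subject_id!r} at t={row['time_h']} h flagged BLQ "
                        f"but concentration is {conc}, not 0"
                    )
            points.append(ConcentrationPoint(float(row["time_h"]), conc, blq))
        profiles.append(SubjectProfile(subject_id=str(subject_id), points=tuple(points)))
    return profiles


def write_concentration_table(profiles: Iterable[SubjectProfile], destination) -> None:
    """Write profiles back to the long CSV format (inverse of the reader)."""
    rows = [
        {
            "subject_id": p.subject_id,
            # shortest round-trip representation: lossless through read_csv
            "time_h": repr(pt.time_h),
            "conc_mg_per_L": repr(pt.conc_mg_per_L),
            "blq": pt.blq,
        }
        for p in profiles
        for pt in p.points
    ]
    pd.DataFrame(rows, columns=["subject_id", "time_h", "conc_mg_per_L", "blq"]).to_csv(
        destination, index=False
    )


def read_dose_table(source) -> pd.DataFrame:
    """Read a dose table CSV: subject_id, body_weight_g, dose_mg."""
    df = pd.read_csv(source, dtype={"subject_id": str})
    required = {"subject_id", "body_weight_g", "dose_mg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose table missing columns: {sorted(missing)}")
    return df


def attach_doses(
    profiles: Sequence[SubjectProfile],
    dose_table: pd.DataFrame,
    *,
    expected_dose_mg_per_kg: float | None = None,
) -> list[SubjectProfile]:
    """Populate body weight and administered dose from a dose table.

    Every subject in ``profiles`` must appear in ``dose_table``. If
    ``expected_dose_mg_per_kg`` is given (e.g. 10 for the single-dose rat
    study), doses inconsistent with weight x dose level beyond table
    rounding are logged as warnings.
    """
    table = dose_table.set_index(dose_table["subject_id"].astype(str))
    out: list[SubjectProfile] = []
    for profile in profiles:
        if profile.subject_id not in table.index:
            raise ValueError(f"subject {profile.subject_id!r} missing from dose table")
        row = table.loc[profile.subject_id]
        weight = float(row["body_weight_g"])
        dose = float(row["dose_mg"])
        if expected_dose_mg_per_kg is not None:
            nominal = expected_dose_mg_per_kg * weight / 1000.0
            if abs(dose - nominal) > 0.005 + 1e-9:
                logger.warning(
                    "subject %s: recorded dose %.3f mg differs from %.1f mg/kg x %.1f g "
                    "= %.3f mg", profile.subject_id, dose, expected_dose_mg_per_kg,
                    weight, nominal,
                )
        out.append(dataclasses.replace(profile, body_weight_g=weight, dose_mg=dose))
    return out


def _result_record(result: "NCAResult", decimals: int | None) -> dict:
    rec = {col: getattr(result, col) for col in RESULT_COLUMNS}
    if decimals is not None:
        for key, val in rec.items():
            if isinstance(val, float) and math.isfinite(val):
                rec[key] = round_half_away(val, decimals)
    return rec


def write_results(
    results: Sequence["NCAResult"],
    destination: str | Path,
    *,
    decimals: int | None = None,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[Path, Path]:
    """Write per-subject NCA results as CSV plus a JSON mirror.

    Columns follow the conventional report order (Cmax, Tmax, AUClast, Vd,
    CL, K, T0.5e, MRT). When ``groups`` maps labels to subject ids, a
    ``mean <label>`` row of arithmetic means is appended per group (the
    full mean/SEM/CI table is the summary module's job). Internal values
    stay full precision; ``decimals`` rounds only this report.

    Returns the (csv_path, json_path) written.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    destination = Path(destination)
    records = [_result_record(r, decimals) for r in results]
    df = pd.DataFrame(records, columns=list(RESULT_COLUMNS))
    if groups:
        by_id = {r.subject_id: r for r in results}
        numeric = [c for c in RESULT_COLUMNS if c not in ("subject_id", "complete")]
        for label, ids in groups.items():
            sel = [by_id[i] for i in ids if i in by_id]
            if not sel:
                continue
            row: dict = {"subject_id": f"mean {label}", "complete": all(r.complete for r in sel)}
            for col in numeric:
                vals = [getattr(r, col) for r in sel]
                mean = float(np.mean(vals))
                row[col] = round_half_away(mean, decimals) if decimals is not None else mean
            df = pd.concat([df, pd.DataFrame([row])], ignore_index=True)
    csv_path = destination.with_suffix(".csv")
    json_path = destination.with_suffix(".json")
    df.to_csv(csv_path, index=False)
    json_path.write_text(json.dumps(df.to_dict(orient="records"), indent=2, default=float))
    return csv_path, json_path


def read_results(source) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results`."""
    return pd.read_csv(source, dtype={"subject_id": str})
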