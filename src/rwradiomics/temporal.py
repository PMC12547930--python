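"""Scan-level averaging, fraction-to-week mapping, per-patient tables.

Subimage feature vectors are averaged (element-wise arithmetic mean)
across all subimages and slices of a scan; daily MVCT scan vectors are
then averaged within treatment weeks.  The 74 Gy / 37-fraction regimen
maps onto 7 weeks (weeks 1-6: five fractions each, week 7: fractions
31-37); the 60 Gy / 20-fraction regimen maps onto 4 five-fraction
weeks.  The planning CT forms its own "CT" time point.

Week-level tables are wide data frames indexed by patient with columns
``"<time_point>:<feature>"`` (e.g. ``"W1:FOS1"``).  Patients lacking
every fraction of a week get missing cells there; model fitting at a
time point later drops those patients with a logged roster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .catalogue import FEATURE_CODES
from .io import REGIMEN_FRACTIONS, CohortRecord, ValidationError

logger = logging.getLogger(__name__)

#: week_index -> (first fraction, last fraction), per regimen
WEEK_MAP: dict[str, dict[int, tuple[int, int]]] = {
    "74Gy_37F": {k: (5 * (k - 1) + 1, 5 * k) for k in range(1, 7)} | {7: (31, 37)},
    "60Gy_20F": {k: (5 * (k - 1) + 1, 5 * k) for k in range(1, 5)},
}

TIME_POINT_CT = "CT"


def weeks_for_regimen(regimen: str) -> list[int]:
    if regimen not in WEEK_MAP:
        raise ValidationError(f"unknown regimen: {regimen}")
    return sorted(WEEK_MAP[regimen])


def time_points_for_regimen(regimen: str) -> list[str]:
    """CT plus W1..Wmax, in treatment order."""
    return [TIME_POINT_CT] + [f"W{k}" for k in weeks_for_regimen(regimen)]


def fraction_to_week(fraction_index: int, regimen: str) -> int:
    """Map a 1-based fraction index to its treatment week."""
    n = REGIMEN_FRACTIONS.get(regimen)
    if n is None:
        raise ValidationError(f"unknown regimen: {regimen}")
    f = int(fraction_index)
    if not 1 <= f <= n:
        raise ValidationError(f"fraction {f} out of range 1..{n} for {regimen}")
    for week, (lo, hi) in WEEK_MAP[regimen].items():
        if lo <= f <= hi:
            return week
    raise AssertionError("week map does not partition the fractions")


def aggregate_scan(feature_vectors) -> np.ndarray:
    """Element-wise mean across the scan's subimage feature vectors."""
    arrs = [np.asarray(getattr(v, "values", v), dtype=float) for v in feature_vectors]
    if not arrs:
        raise ValidationError("cannot aggregate an empty subimage list")
    return np.mean(np.stack(arrs), axis=0)


def build_week_table(
    cohort: list[CohortRecord], scan_features: pd.DataFrame
) -> pd.DataFrame:
    """Per-patient time-point feature table.

    ``scan_features`` has one row per scan with columns ``patient_id``,
    ``modality``, ``fraction_index`` and the 118 feature columns.  The
    output is indexed by patient with columns ``"CT:<f>"`` and
    ``"W<k>:<f>"``; a patient with no fraction in a week has NaN cells
    there (roster logged).
    """
    missing_feats = set(FEATURE_CODES) - set(scan_features.columns)
    if missing_feats:
        raise ValidationError(f"scan features missing columns: {sorted(missing_feats)[:3]}...")

    by_regimen = {rec.patient_id: rec.regimen for rec in cohort}
    frames: dict[str, pd.Series] = {}
    rows = []
    for rec in cohort:
        pid = rec.patient_id
        sf = scan_features[scan_features["patient_id"] == pid]
        if sf.empty:
            raise ValidationError(f"no scan features for patient {pid}")
        parts = {}
        ct = sf[sf["modality"] == "planning_ct"]
        if len(ct) == 1:
            parts[TIME_POINT_CT] = ct[FEATURE_CODES].iloc[0].astype(float)
        elif len(ct) > 1:
            raise ValidationError(f"patient {pid} has multiple planning scans")
        mv = sf[sf["modality"] == "mvct"].copy()
        if not mv.empty:
            mv["week"] = [
                fraction_to_week(int(f), by_regimen[pid]) for f in mv["fraction_index"]
            ]
        for week in weeks_for_regimen(rec.regimen):
            grp = mv[mv["week"] == week] if not mv.empty else mv
            if grp.empty:
                logger.warning("patient %s has no fractions in week %d", pid, week)
                continue
            if len(grp) < WEEK_MAP[rec.regimen][week][1] - WEEK_MAP[rec.regimen][week][0] + 1:
                logger.info(
                    "patient %s: week %d averaged over %d fraction(s)",
                    pid, week, len(grp),
                )
            parts[f"W{week}"] = grp[FEATURE_CODES].astype(float).mean(axis=0)
        row = {}
        for tp, vec in parts.items():
            for feat, val in vec.items():
                row[f"{tp}:{feat}"] = val
        rows.append(pd.Series(row, name=pid))
    table = pd.DataFrame(rows)
    table.index.name = "patient_id"
    return table


def time_point_columns(table: pd.DataFrame, time_point: str) -> list[str]:
    prefix = f"{time_point}:"
    return [c for c in table.columns if c.startswith(prefix)]


def assemble_design(
    table: pd.DataFrame,
    time_point: str,
    mode: str = "separate",
    selections: dict[str, list[str]] | None = None,
    order: list[str] | None = None,
) -> pd.DataFrame:
    """Design matrix for one time point.

    ``separate`` mode returns the time point's full feature block.
    ``cumulative`` mode returns the union of the separate-analysis
    selections (``selections[tp]``, prefixed column names) at CT and all
    weeks up to and including ``time_point``; it requires those
    selections to have been computed first.  ``order`` gives the time
    point ordering (default: CT first, then ascending weeks present in
    the table).
    """
    if mode == "separate":
        cols = time_point_columns(table, time_point)
        if not cols:
            raise ValidationError(f"time point {time_point} not present in table")
        return table[cols]
    if mode != "cumulative":
        raise ValidationError(f"unknown mode: {mode}")
    if selections is None:
        raise ValidationError(
            "cumulative design requested before separate-analysis selections"
        )
    if order is None:
        weeks = sorted(
            int(c.split(":")[0][1:])
            for c in table.columns
            if c.startswith("W")
        )
        order = [TIME_POINT_CT] + [f"W{k}" for k in sorted(set(weeks))]
    if time_point not in order:
        raise ValidationError(f"time point {time_point} not in order {order}")
    upto = order[: order.index(time_point) + 1]
    cols: list[str] = []
    for tp in upto:
        if tp not in selections:
            raise ValidationError(
                f"cumulative design at {time_point} needs the separate-analysis "
                f"selection for {tp}"
            )
        cols.extend(c for c in selections[tp] if c not in cols)
    return table[cols]


def tidy_table(table: pd.DataFrame) -> pd.DataFrame:
    """Long form (patient_id, time_point, feature_name, value)."""
    long = table.reset_index().melt(
        id_vars="patient_id", var_name="column", value_name="value"
    )
    parts = long["column"].str.split(":", n=1, expand=True)
    long["time_point"] = parts[0]
    long["feature_name"] = parts[1]
    return long[["patient_id", "time_point", "feature_name", "value"]]
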