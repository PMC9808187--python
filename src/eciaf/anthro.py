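"""LMS z-scores, the restricted tail adjustment, and plausibility screening.

Implements the standard-analysis z-score workflow for child anthropometry:
compute HAZ, WAZ, WHZ and BMIZ from measured height and weight against an
LMS reference; re-express the weight-based scores beyond +/-3 SD on the
restricted linear tail anchored at the +/-2 and +/-3 SD reference curves;
flag biologically implausible values; and drop flagged or under-age
children while tallying the reasons.

Scalar entry points operate on :class:`ChildRecord`; the frame entry
points (:func:`compute_zscores_frame`, :func:`apply_exclusions`) are the
vectorized path the pipeline and simulator use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .reference import LMSTable, ReferenceCoverageError, default_reference

__all__ = [
    "ChildRecord",
    "ZScoreSet",
    "FLAG_LIMITS",
    "lms_zscore",
    "lms_inverse",
    "restricted_adjust",
    "compute_zscores",
    "compute_zscores_frame",
    "flag_implausible",
    "flag_implausible_frame",
    "apply_exclusions",
]

#: Plausibility limits (closed intervals, SD units): a z-score strictly
#: outside its interval is flagged as biologically implausible.  These are
#: the standard-analysis fixed-exclusion limits; edit here to adopt
#: alternatives.
FLAG_LIMITS: dict[str, tuple[float, float]] = {
    "haz": (-6.0, 6.0),
    "waz": (-6.0, 5.0),
    "whz": (-5.0, 5.0),
    "bmiz": (-5.0, 5.0),
}

#: weight-based indicators that receive the restricted tail adjustment
_ADJUSTED = {"waz": "weight_for_age", "whz": "weight_for_height", "bmiz": "bmi_for_age"}


class InvalidMeasurementError(ValueError):
    pass


@dataclass(frozen=True)
class ChildRecord:
    """One surveyed child: identifiers, design variables and raw measurements."""

    child_id: str
    survey: str
    region: str
    psu: str
    household: str
    sex: str  # "male" | "female"
    age_months: int
    weight_kg: float
    height_cm: float
    sampling_weight: float = 1.0


@dataclass
class ZScoreSet:
    """HAZ/WAZ/WHZ/BMIZ for one child plus plausibility/age flags.

    A flagged component is still stored; exclusion is a separate step.
    """

    haz: float | None = None
    waz: float | None = None
    whz: float | None = None
    bmiz: float | None = None
    flags: set[str] = field(default_factory=set)


def lms_zscore(x, L, M, S):
    """LMS z-score of measurement ``x``: ((x/M)^L - 1)/(L*S), log form at L=0.

    Strictly increasing in ``x`` for fixed parameters.  Accepts scalars or
    arrays; raises :class:`InvalidMeasurementError` on nonpositive x, M or S.
    """
    x = np.asarray(x, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(x <= 0) or np.any(M <= 0) or np.any(S <= 0):
        raise InvalidMeasurementError("lms_zscore requires x > 0, M > 0, S > 0")
    log_ratio = np.log(x / M)
    # |L| below ~1e-150 underflows L*S; such L is numerically the log form
    log_form = np.abs(L) < 1e-150
    safe_L = np.where(log_form, 1.0, L)
    # expm1 form: exact limit log(x/M)/S as L -> 0, no catastrophic cancellation
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(log_form, log_ratio / S, np.expm1(safe_L * log_ratio) / (safe_L * S))
    return z if z.ndim else float(z)


def lms_inverse(z, L, M, S):
    """Measurement at z-score ``z``: the inverse of :func:`lms_zscore`.

    For L != 0 requires 1 + L*S*z > 0 (the Box-Cox domain).
    """
    z = np.asarray(z, dtype=float)
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    S = np.asarray(S, dtype=float)
    if np.any(M <= 0) or np.any(S <= 0):
        raise InvalidMeasurementError("lms_inverse requires M > 0 and S > 0")
    base = 1.0 + L * S * z
    if np.any((L != 0) & (base <= 0)):
        raise InvalidMeasurementError("z outside the Box-Cox domain (1 + L*S*z <= 0)")
    log_form = np.abs(L) < 1e-150
    safe_L = np.where(log_form, 1.0, L)
    # log1p form: stable for L near zero, exact limit M*exp(S*z)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(log_form, M * np.exp(S * z), M * np.exp(np.log1p(safe_L * S * z) / safe_L))
    return x if x.ndim else float(x)


def restricted_adjust(z_raw: float, x: float, sd_curve: Callable[[float], float]) -> float:
    """Map a weight-based z-score beyond +/-3 SD onto the restricted linear tail.

    ``sd_curve`` maps a z value to the measurement at that many reference SD
    (i.e. :func:`lms_inverse` with the child's LMS parameters).  Inside
    +/-3 SD the raw score is returned unchanged; beyond, the score is
    ``3 + (x - SD3)/(SD3 - SD2)`` (mirrored below -3), which is continuous
    at the knots and order-preserving.
    """
    if not np.isfinite(z_raw):
        return z_raw
    if -3.0 <= z_raw <= 3.0:
        return float(z_raw)
    if z_raw > 3.0:
        sd3, sd2 = sd_curve(3.0), sd_curve(2.0)
        if sd3 == sd2:
            raise ReferenceCoverageError("degenerate reference: SD3 equals SD2")
        return 3.0 + (x - sd3) / (sd3 - sd2)
    sd3n, sd2n = sd_curve(-3.0), sd_curve(-2.0)
    if sd3n == sd2n:
        raise ReferenceCoverageError("degenerate reference: SD-3 equals SD-2")
    return -3.0 + (x - sd3n) / (sd2n - sd3n)


def _restricted_adjust_vec(z, x, L, M, S):
    """Vectorized restricted adjustment given per-element LMS parameters."""
    z = np.asarray(z, dtype=float).copy()
    hi = z > 3.0
    lo = z < -3.0
    if hi.any():
        sd3 = lms_inverse(3.0, L[hi], M[hi], S[hi])
        sd2 = lms_inverse(2.0, L[hi], M[hi], S[hi])
        z[hi] = 3.0 + (np.asarray(x)[hi] - sd3) / (sd3 - sd2)
    if lo.any():
        sd3n = lms_inverse(-3.0, L[lo], M[lo], S[lo])
        sd2n = lms_inverse(-2.0, L[lo], M[lo], S[lo])
        z[lo] = -3.0 + (np.asarray(x)[lo] - sd3n) / (sd2n - sd3n)
    return z


def compute_zscores(
    child: ChildRecord,
    ref: LMSTable | None = None,
    *,
    restricted: bool = True,
) -> ZScoreSet:
    """All four z-scores for one child.

    HAZ from height at (age, sex); WAZ from weight at (age, sex); WHZ from
    weight keyed on measured height; BMIZ from weight/height^2 at (age,
    sex).  The restricted tail adjustment applies to WAZ, WHZ and BMIZ
    (not HAZ) unless ``restricted=False``.  Children under 6 completed
    months get the ``under_6_months`` flag.  A missing measurement yields a
    missing component, never an imputation.
    """
    ref = ref or default_reference()
    frame = pd.DataFrame([_record_to_row(child)])
    out = compute_zscores_frame(frame, ref, restricted=restricted)
    row = out.iloc[0]
    zset = ZScoreSet(
        haz=None if pd.isna(row["haz"]) else float(row["haz"]),
        waz=None if pd.isna(row["waz"]) else float(row["waz"]),
        whz=None if pd.isna(row["whz"]) else float(row["whz"]),
        bmiz=None if pd.isna(row["bmiz"]) else float(row["bmiz"]),
    )
    if row["under_6_months"]:
        zset.flags.add("under_6_months")
    return zset


def _record_to_row(child: ChildRecord) -> dict:
    return {
        "child_id": child.child_id,
        "survey": child.survey,
        "region": child.region,
        "psu": child.psu,
        "household": child.household,
        "sex": child.sex,
        "age_months": child.age_months,
        "weight_kg": child.weight_kg,
        "height_cm": child.height_cm,
        "sampling_weight": child.sampling_weight,
    }


def compute_zscores_frame(
    records: pd.DataFrame,
    ref: LMSTable | None = None,
    *,
    restricted: bool = True,
) -> pd.DataFrame:
    """Vectorized :func:`compute_zscores` over a child-record frame.

    Returns a copy of ``records`` with columns ``haz, waz, whz, bmiz`` and
    boolean ``under_6_months`` appended.  Rows with a missing measurement
    get NaN in the components that need it.
    """
    ref = ref or default_reference()
    out = records.copy()
    n = len(out)
    haz = np.full(n, np.nan)
    waz = np.full(n, np.nan)
    whz = np.full(n, np.nan)
    bmiz = np.full(n, np.nan)

    age = pd.to_numeric(out["age_months"], errors="coerce").to_numpy(dtype=float)
    height = pd.to_numeric(out["height_cm"], errors="coerce").to_numpy(dtype=float)
    weight = pd.to_numeric(out["weight_kg"], errors="coerce").to_numpy(dtype=float)
    bmi = weight / (height / 100.0) ** 2

    for sex in ("male", "female"):
        sel = (out["sex"] == sex).to_numpy()
        if not sel.any():
            continue
        ok_h = sel & np.isfinite(height) & (height > 0) & np.isfinite(age)
        if ok_h.any():
            L, M, S = ref.lookup_many("height_for_age", sex, age[ok_h])
            haz[ok_h] = lms_zscore(height[ok_h], L, M, S)
        ok_w = sel & np.isfinite(weight) & (weight > 0) & np.isfinite(age)
        if ok_w.any():
            L, M, S = ref.lookup_many("weight_for_age", sex, age[ok_w])
            z = lms_zscore(weight[ok_w], L, M, S)
            waz[ok_w] = _restricted_adjust_vec(z, weight[ok_w], L, M, S) if restricted else z
        ok_wh = sel & np.isfinite(weight) & (weight > 0) & np.isfinite(height) & (height > 0)
        if ok_wh.any():
            L, M, S = ref.lookup_many("weight_for_height", sex, height[ok_wh])
            z = lms_zscore(weight[ok_wh], L, M, S)
            whz[ok_wh] = _restricted_adjust_vec(z, weight[ok_wh], L, M, S) if restricted else z
        ok_b = ok_wh & np.isfinite(age)
        if ok_b.any():
            L, M, S = ref.lookup_many("bmi_for_age", sex, age[ok_b])
            z = lms_zscore(bmi[ok_b], L, M, S)
            bmiz[ok_b] = _restricted_adjust_vec(z, bmi[ok_b], L, M, S) if restricted else z

    out["haz"], out["waz"], out["whz"], out["bmiz"] = haz, waz, whz, bmiz
    out["under_6_months"] = age < 6
    return out


def flag_implausible(zset: ZScoreSet) -> ZScoreSet:
    """Add ``*_flag`` entries for components outside the plausibility limits.

    Limits are closed intervals (:data:`FLAG_LIMITS`): a value exactly on a
    boundary is plausible.  Missing components are skipped.
    """
    for name, (lo, hi) in FLAG_LIMITS.items():
        value = getattr(zset, name)
        if value is not None and np.isfinite(value) and not (lo <= value <= hi):
            zset.flags.add(f"{name}_flag")
    return zset


def flag_implausible_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorized flagging: adds boolean ``haz_flag`` .. ``bmiz_flag`` columns."""
    out = frame.copy()
    for name, (lo, hi) in FLAG_LIMITS.items():
        z = out[name].to_numpy(dtype=float)
        out[f"{name}_flag"] = np.isfinite(z) & ((z < lo) | (z > hi))
    return out


def apply_exclusions(frame: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop under-6-month and implausibly-flagged children, tallying reasons.

    The age rule is applied first: a child failing both is tallied once,
    under ``under_6_months``.  The number of rows kept plus the tally total
    equals the input size.  Flag columns are computed on the fly when
    absent.
    """
    if not {"haz_flag", "waz_flag", "whz_flag", "bmiz_flag"} <= set(frame.columns):
        frame = flag_implausible_frame(frame)
    under6 = frame["under_6_months"].to_numpy(dtype=bool)
    flagged = (
        frame[["haz_flag", "waz_flag", "whz_flag", "bmiz_flag"]].to_numpy(dtype=bool).any(axis=1)
    )
    tally = {
        "under_6_months": int(under6.sum()),
        "flagged": int((flagged & ~under6).sum()),
    }
    included = frame.loc[~under6 & ~flagged].reset_index(drop=True)
    return included, tally


def records_to_frame(records: Sequence[ChildRecord]) -> pd.DataFrame:
    """Convenience: build a child-record frame from :class:`ChildRecord` objects."""
    return pd.DataFrame([_record_to_row(r) for r in records])
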