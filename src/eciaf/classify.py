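"""CIAF / eCIAF classification of anthropometric failure.

The composite index of anthropometric failure (CIAF) partitions children
into mutually exclusive groups by their combination of stunting (HAZ < -2),
wasting (WHZ < -2) and underweight (WAZ < -2); the extended index (eCIAF)
adds two over-nutrition groups defined on overweight (WHZ > +2 by default,
switchable to BMIZ > +2).  Group codes:

=====  ==========================================
A      no failure
B      wasting only
C      wasting and underweight
D      stunting, wasting and underweight
E      stunting and underweight
F      stunting only
Y      underweight only
G      stunting and overweight          (eCIAF)
H      overweight only                  (eCIAF)
X      stunting and wasting, not underweight (unlabelled in the
       classical taxonomy; counted as failure, reported separately)
=====  ==========================================

All thresholds are strict inequalities; a z-score of exactly -2.0 is not
a failure.  The logically possible underweight-and-overweight combination
is mapped to H (G when also stunted) with a data-quality warning, since
the taxonomy predates it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .anthro import ZScoreSet

__all__ = [
    "AnthroIndicators",
    "CIAFGroup",
    "ECIAF_LABELS",
    "classify_conventional",
    "classify_eciaf",
    "classify_ciaf",
    "classify_frame",
    "overall_burden",
]

ECIAF_LABELS: dict[str, str] = {
    "A": "no failure",
    "B": "wasting only",
    "C": "wasting and underweight",
    "D": "stunting, wasting and underweight",
    "E": "stunting and underweight",
    "F": "stunting only",
    "Y": "underweight only",
    "G": "stunting and overweight",
    "H": "overweight only",
    "X": "stunting and wasting (not underweight)",
}


class ClassificationError(ValueError):
    pass


@dataclass(frozen=True)
class AnthroIndicators:
    stunted: bool
    wasted: bool
    underweight: bool
    overweight: bool = False

    def __post_init__(self) -> None:
        if self.wasted and self.overweight:
            raise ClassificationError(
                "wasted and overweight cannot both hold (both defined on WHZ)"
            )


@dataclass(frozen=True)
class CIAFGroup:
    code: str
    label: str


def classify_conventional(
    zset: ZScoreSet, *, overweight_on: Literal["whz", "bmiz"] = "whz"
) -> AnthroIndicators:
    """Conventional indicators from one child's z-scores (strict thresholds)."""
    for component in ("haz", "waz", "whz"):
        if getattr(zset, component) is None:
            raise ClassificationError(f"missing z-score component: {component}")
        if f"{component}_flag" in zset.flags:
            raise ClassificationError(f"flagged z-score component: {component}")
    over_source = getattr(zset, overweight_on)
    if over_source is None:
        raise ClassificationError(f"missing z-score component: {overweight_on}")
    return AnthroIndicators(
        stunted=zset.haz < -2.0,
        wasted=zset.whz < -2.0,
        underweight=zset.waz < -2.0,
        overweight=over_source > 2.0 and not (zset.whz < -2.0),
    )


def _eciaf_code(stunted: bool, wasted: bool, underweight: bool, overweight: bool) -> str:
    if overweight:
        # taxonomy predates underweight+overweight; fold onto H/G
        return "G" if stunted else "H"
    if stunted and wasted and underweight:
        return "D"
    if stunted and wasted:
        return "X"
    if stunted and underweight:
        return "E"
    if stunted:
        return "F"
    if wasted and underweight:
        return "C"
    if wasted:
        return "B"
    if underweight:
        return "Y"
    return "A"


def classify_eciaf(ind: AnthroIndicators) -> CIAFGroup:
    """Extended-CIAF group of one child (total on the indicator space)."""
    if ind.overweight and ind.underweight:
        warnings.warn(
            "underweight and overweight simultaneously; mapped to the overweight "
            "group — check data quality",
            stacklevel=2,
        )
    code = _eciaf_code(ind.stunted, ind.wasted, ind.underweight, ind.overweight)
    return CIAFGroup(code, ECIAF_LABELS[code])


def classify_ciaf(ind: AnthroIndicators) -> CIAFGroup:
    """Classical CIAF group: the eCIAF view with over-nutrition ignored."""
    code = _eciaf_code(ind.stunted, ind.wasted, ind.underweight, False)
    return CIAFGroup(code, ECIAF_LABELS[code])


def classify_frame(
    frame: pd.DataFrame, *, overweight_on: Literal["whz", "bmiz"] = "whz"
) -> pd.DataFrame:
    """Vectorized classification of a z-scored frame.

    Adds boolean ``stunted, wasted, underweight, overweight`` and string
    ``ciaf_group, eciaf_group`` columns.  Rows with a missing required
    component get pandas NA in the group columns.
    """
    out = frame.copy()
    haz = out["haz"].to_numpy(dtype=float)
    waz = out["waz"].to_numpy(dtype=float)
    whz = out["whz"].to_numpy(dtype=float)
    over_src = out[overweight_on].to_numpy(dtype=float)

    stunted = haz < -2.0
    wasted = whz < -2.0
    underweight = waz < -2.0
    overweight = (over_src > 2.0) & ~wasted
    complete = np.isfinite(haz) & np.isfinite(waz) & np.isfinite(whz) & np.isfinite(over_src)

    out["stunted"] = stunted & complete
    out["wasted"] = wasted & complete
    out["underweight"] = underweight & complete
    out["overweight"] = overweight & complete

    eciaf = np.array(
        [
            _eciaf_code(s, w, u, o)
            for s, w, u, o in zip(stunted, wasted, underweight, overweight)
        ],
        dtype=object,
    )
    ciaf = np.array(
        [_eciaf_code(s, w, u, False) for s, w, u in zip(stunted, wasted, underweight)],
        dtype=object,
    )
    eciaf[~complete] = None
    ciaf[~complete] = None
    out["eciaf_group"] = eciaf
    out["ciaf_group"] = ciaf
    return out


def overall_burden(
    groups: Sequence[CIAFGroup | str] | Iterable, index: Literal["ciaf", "eciaf"] = "eciaf"
) -> float:
    """Proportion of children with any failure (code != A) under the index.

    For ``index="ciaf"`` the over-nutrition codes G and H fold back to
    their undernutrition view (G -> F stays a failure, H -> A does not).
    """
    codes = [g.code if isinstance(g, CIAFGroup) else str(g) for g in groups]
    if not codes:
        raise ValueError("overall_burden of an empty sequence")
    if index == "ciaf":
        codes = ["A" if c == "H" else ("F" if c == "G" else c) for c in codes]
    elif index != "eciaf":
        raise ValueError(f"unknown index {index!r}")
    return sum(c != "A" for c in codes) / len(codes)
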