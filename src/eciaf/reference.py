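"""Growth-reference tables in LMS form.

The LMS method parameterizes a growth reference by a Box-Cox power ``L``,
a median ``M`` and a coefficient of variation ``S`` per key (age in
completed months for the age-keyed indicators, length/height in cm for
weight-for-height).  :class:`LMSTable` holds one such table for the four
indicators (height-for-age, weight-for-age, weight-for-height,
BMI-for-age) and both sexes, interpolating the three parameters linearly
in the key between tabulated rows.

The packaged default table (``data/synthetic_lms_reference.csv``) is a
SYNTHETIC stand-in, not the published WHO 2006 tables: smooth median
curves of realistic shape and magnitude for children 0-60 months /
45-120 cm, with the weight-for-age and BMI-for-age medians derived by
composing the height-for-age and weight-for-height medians so that a
child at the median of both height and weight scores zero on all four
indicators.  The pipeline's statistics depend only on the z-score scale,
so any internally consistent LMS table exercises it faithfully; absolute
raw-unit medians are not meant to match the WHO publication.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

INDICATORS = ("height_for_age", "weight_for_age", "weight_for_height", "bmi_for_age")
SEXES = ("male", "female")

#: indicators keyed by age in completed months
AGE_KEYED = ("height_for_age", "weight_for_age", "bmi_for_age")

_AGE_GRID = np.arange(0, 61, dtype=float)
_HEIGHT_GRID = np.arange(45.0, 130.0 + 0.25, 0.5)


class ReferenceCoverageError(ValueError):
    """Raised when a lookup key falls outside the tabulated range."""


def _median_height_for_age(age_months: np.ndarray, sex: str) -> np.ndarray:
    """Synthetic median length/height (cm) at a given age."""
    t = np.asarray(age_months, dtype=float)
    m = 46.818 + 0.4195 * t + 9.386 * np.log1p(t)
    return m * (0.985 if sex == "female" else 1.0)


def _median_weight_for_height(height_cm: np.ndarray, sex: str) -> np.ndarray:
    """Synthetic median weight (kg) at a given length/height."""
    x = np.asarray(height_cm, dtype=float) - 45.0
    m = 4.643 + 0.10383 * x + 0.0017013 * x**2
    return m * (0.97 if sex == "female" else 1.0)


# L (Box-Cox power) and S (coefficient of variation) per indicator and sex;
# constant over the key, in the range the published references span.
_L = {"height_for_age": 1.0, "weight_for_age": -0.15, "weight_for_height": -0.35, "bmi_for_age": -0.6}
_S = {
    ("height_for_age", "male"): 0.035,
    ("height_for_age", "female"): 0.036,
    ("weight_for_age", "male"): 0.110,
    ("weight_for_age", "female"): 0.115,
    ("weight_for_height", "male"): 0.082,
    ("weight_for_height", "female"): 0.085,
    ("bmi_for_age", "male"): 0.085,
    ("bmi_for_age", "female"): 0.088,
}


def build_synthetic_reference() -> pd.DataFrame:
    """Construct the synthetic LMS reference as a tidy frame.

    Columns ``indicator,sex,key,L,M,S``; one row per tabulated key.  The
    weight-for-age median is the weight-for-height median evaluated at the
    median height for that age, and the BMI-for-age median follows from
    those two, which keeps the four indicators mutually consistent.
    """
    blocks = []
    for sex in SEXES:
        m_hfa = _median_height_for_age(_AGE_GRID, sex)
        m_wfh_at_median_h = _median_weight_for_height(m_hfa, sex)
        m_bmi = m_wfh_at_median_h / (m_hfa / 100.0) ** 2
        for indicator, keys, med in (
            ("height_for_age", _AGE_GRID, m_hfa),
            ("weight_for_age", _AGE_GRID, m_wfh_at_median_h),
            ("bmi_for_age", _AGE_GRID, m_bmi),
            ("weight_for_height", _HEIGHT_GRID, _median_weight_for_height(_HEIGHT_GRID, sex)),
        ):
            blocks.append(
                pd.DataFrame(
                    {
                        "indicator": indicator,
                        "sex": sex,
                        "key": keys,
                        "L": _L[indicator],
                        "M": med,
                        "S": _S[(indicator, sex)],
                    }
                )
            )
    return pd.concat(blocks, ignore_index=True)


@dataclass(frozen=True)
class LMSParams:
    L: float
    M: float
    S: float


class LMSTable:
    """LMS reference rows with linear interpolation in the key.

    Parameters
    ----------
    frame
        Tidy frame with columns ``indicator,sex,key,L,M,S``.  Keys must be
        strictly increasing within each (indicator, sex) block and every
        row must have ``M > 0`` and ``S > 0``.
    """

    def __init__(self, frame: pd.DataFrame) -> None:
        required = {"indicator", "sex", "key", "L", "M", "S"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        if (frame["M"] <= 0).any() or (frame["S"] <= 0).any():
            raise ValueError("reference table requires M > 0 and S > 0 in every row")
        self._blocks: dict[tuple[str, str], dict[str, np.ndarray]] = {}
        for (indicator, sex), block in frame.groupby(["indicator", "sex"], sort=False):
            keys = block["key"].to_numpy(dtype=float)
            if not np.all(np.diff(keys) > 0):
                raise ValueError(f"keys not strictly increasing for ({indicator}, {sex})")
            self._blocks[(str(indicator), str(sex))] = {
                "key": keys,
                "L": block["L"].to_numpy(dtype=float),
                "M": block["M"].to_numpy(dtype=float),
                "S": block["S"].to_numpy(dtype=float),
            }
        self._frame = frame.reset_index(drop=True)

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame

    def coverage(self, indicator: str, sex: str) -> tuple[float, float]:
        block = self._block(indicator, sex)
        return float(block["key"][0]), float(block["key"][-1])

    def _block(self, indicator: str, sex: str) -> dict[str, np.ndarray]:
        try:
            return self._blocks[(indicator, sex)]
        except KeyError:
            raise ReferenceCoverageError(
                f"no reference rows for indicator={indicator!r}, sex={sex!r}"
            ) from None

    def lookup(self, indicator: str, sex: str, key: float) -> LMSParams:
        """Interpolated (L, M, S) at one key."""
        L, M, S = self.lookup_many(indicator, sex, np.asarray([key], dtype=float))
        return LMSParams(float(L[0]), float(M[0]), float(S[0]))

    def lookup_many(
        self, indicator: str, sex: str, keys: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Vectorized interpolated (L, M, S) arrays at the given keys."""
        block = self._block(indicator, sex)
        keys = np.asarray(keys, dtype=float)
        lo, hi = block["key"][0], block["key"][-1]
        bad = (keys < lo) | (keys > hi) | ~np.isfinite(keys)
        if bad.any():
            raise ReferenceCoverageError(
                f"{indicator}: key(s) {np.asarray(keys)[bad][:5]} outside "
                f"reference coverage [{lo}, {hi}] for sex={sex}"
            )
        L = np.interp(keys, block["key"], block["L"])
        M = np.interp(keys, block["key"], block["M"])
        S = np.interp(keys, block["key"], block["S"])
        return L, M, S

    # ---- IO -------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "LMSTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self._frame.to_csv(path, index=False)

    @classmethod
    def from_csv_dir(cls, directory) -> "LMSTable":
        """Load and concatenate every ``*.csv`` in a directory."""
        import pathlib

        paths = sorted(pathlib.Path(directory).glob("*.csv"))
        if not paths:
            raise FileNotFoundError(f"no reference CSVs in {directory}")
        return cls(pd.concat([pd.read_csv(p) for p in paths], ignore_index=True))


_DEFAULT: LMSTable | None = None


def default_reference() -> LMSTable:
    """The packaged synthetic LMS reference (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        ref = resources.files("eciaf") / "data" / "synthetic_lms_reference.csv"
        with resources.as_file(ref) as path:
            _DEFAULT = LMSTable.from_csv(path)
    return _DEFAULT
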