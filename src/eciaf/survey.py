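"""Design-based prevalence estimation for two-stage stratified cluster surveys.

Point estimates are weighted ratio estimators p = sum(w*y)/sum(w); variance
uses first-stage Taylor linearization with the with-replacement PSU
approximation: within stratum h holding n_h PSUs, the contribution is
n_h/(n_h - 1) * sum_j (z_hj - zbar_h)^2 where z_hj is the PSU total of the
linearized score (y_i - p) * w_i / sum(w).  Confidence intervals are
symmetric Wald on the proportion scale, clipped to [0, 1]; logit-scale
intervals are available behind a flag.  The secondary sampling unit
(household) is carried in the design spec for fidelity but does not enter
the first-stage variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from .classify import ECIAF_LABELS

__all__ = [
    "SurveyDesignSpec",
    "PrevalenceEstimate",
    "SinglePSUError",
    "weighted_prevalence",
    "subtype_prevalence_table",
    "regional_prevalence",
    "ci_overlap",
]

_Z975 = 1.959963984540054


@dataclass(frozen=True)
class SurveyDesignSpec:
    """Column names of the design variables in a classified record frame."""

    stratum_field: str = "region"
    psu_field: str = "psu"
    ssu_field: str = "household"
    weight_field: str = "sampling_weight"


class SinglePSUError(ValueError):
    """A stratum holds a single PSU and no handling strategy was chosen."""


@dataclass(frozen=True)
class PrevalenceEstimate:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    domain: str = "national"

    def as_percent(self, decimals: int = 1) -> str:
        return (
            f"{round(self.estimate * 100, decimals)} "
            f"({round(self.ci_low * 100, decimals)}-{round(self.ci_high * 100, decimals)})"
        )


def _resolve_predicate(
    frame: pd.DataFrame, predicate: str | Callable[[pd.DataFrame], np.ndarray]
) -> np.ndarray:
    """An indicator column name, an eCIAF group code, or a callable mask."""
    if callable(predicate):
        return np.asarray(predicate(frame), dtype=float)
    if predicate in frame.columns:
        return frame[predicate].to_numpy(dtype=float)
    if predicate in ECIAF_LABELS:
        return (frame["eciaf_group"] == predicate).to_numpy(dtype=float)
    raise KeyError(f"predicate {predicate!r} is neither a column nor a group code")


def _taylor_variance(
    y: np.ndarray,
    w: np.ndarray,
    strata: np.ndarray,
    psus: np.ndarray,
    estimate: float,
    single_psu: Literal["error", "collapse", "certainty"],
) -> float:
    wsum = w.sum()
    score = (y - estimate) * w / wsum
    df = pd.DataFrame({"stratum": strata, "psu": psus, "z": score})
    psu_totals = df.groupby(["stratum", "psu"], sort=False)["z"].sum()
    variance = 0.0
    singletons: list[pd.Series] = []
    for _, z_h in psu_totals.groupby(level="stratum", sort=False):
        n_h = len(z_h)
        if n_h < 2:
            if single_psu == "error":
                raise SinglePSUError(
                    "stratum with a single PSU; choose single_psu='collapse' or 'certainty'"
                )
            if single_psu == "certainty":
                continue
            singletons.append(z_h)
            continue
        variance += n_h / (n_h - 1) * float(((z_h - z_h.mean()) ** 2).sum())
    if singletons:
        # collapse: pool all singleton PSUs into one pseudo-stratum
        z_h = pd.concat(singletons)
        n_h = len(z_h)
        if n_h >= 2:
            variance += n_h / (n_h - 1) * float(((z_h - z_h.mean()) ** 2).sum())
    return variance


def weighted_prevalence(
    records: pd.DataFrame,
    design: SurveyDesignSpec,
    predicate: str | Callable[[pd.DataFrame], np.ndarray],
    domain: str | None = None,
    *,
    single_psu: Literal["error", "collapse", "certainty"] = "error",
    ci_scale: Literal["wald", "logit"] = "wald",
) -> PrevalenceEstimate:
    """Design-weighted prevalence of ``predicate`` with a 95% CI.

    ``domain`` restricts estimation to one stratum (domain estimation:
    weights used as-is, variance from that stratum's PSUs only).  Raises
    on an empty domain or all-zero weights.
    """
    frame = records
    if domain is not None:
        frame = frame[frame[design.stratum_field] == domain]
        if frame.empty:
            known = sorted(records[design.stratum_field].unique())
            raise ValueError(f"empty domain {domain!r}; known strata: {known}")
    y = _resolve_predicate(frame, predicate)
    keep = np.isfinite(y)
    frame, y = frame[keep], y[keep]
    if frame.empty:
        raise ValueError("no usable records for prevalence estimation")
    w = frame[design.weight_field].to_numpy(dtype=float)
    if (w < 0).any():
        raise ValueError("negative sampling weights")
    if w.sum() == 0:
        raise ValueError("all sampling weights are zero in the domain")

    estimate = float((w * y).sum() / w.sum())
    variance = _taylor_variance(
        y,
        w,
        frame[design.stratum_field].to_numpy(),
        frame[design.psu_field].to_numpy(),
        estimate,
        single_psu,
    )
    se = math.sqrt(max(variance, 0.0))
    if ci_scale == "logit" and 0.0 < estimate < 1.0 and se > 0:
        logit = math.log(estimate / (1 - estimate))
        se_logit = se / (estimate * (1 - estimate))
        lo = 1 / (1 + math.exp(-(logit - _Z975 * se_logit)))
        hi = 1 / (1 + math.exp(-(logit + _Z975 * se_logit)))
    else:
        lo = estimate - _Z975 * se
        hi = estimate + _Z975 * se
    return PrevalenceEstimate(
        estimate=estimate,
        se=se,
        ci_low=max(0.0, min(lo, 1.0)),
        ci_high=max(0.0, min(hi, 1.0)),
        n=int(len(frame)),
        domain=domain or "national",
    )


def subtype_prevalence_table(
    records: pd.DataFrame,
    design: SurveyDesignSpec,
    index: Literal["ciaf", "eciaf"] = "eciaf",
    **kwargs,
) -> pd.DataFrame:
    """One weighted-prevalence row per group code plus the overall-burden row.

    The subtype point estimates (including the no-failure row A) sum to 1;
    the overall row equals 1 - P(A) by the partition identity.
    """
    column = f"{index}_group"
    codes = ["A", "B", "C", "D", "E", "F", "Y", "X"]
    if index == "eciaf":
        codes += ["G", "H"]
    rows = []
    for code in codes:
        est = weighted_prevalence(
            records, design, lambda f, c=code: (f[column] == c).to_numpy(dtype=float), **kwargs
        )
        rows.append(
            {
                "group_code": code,
                "label": ECIAF_LABELS[code],
                "estimate": est.estimate,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n": est.n,
            }
        )
    overall = weighted_prevalence(
        records, design, lambda f: (f[column] != "A").to_numpy(dtype=float), **kwargs
    )
    rows.append(
        {
            "group_code": "overall",
            "label": f"overall burden ({index})",
            "estimate": overall.estimate,
            "se": overall.se,
            "ci_low": overall.ci_low,
            "ci_high": overall.ci_high,
            "n": overall.n,
        }
    )
    return pd.DataFrame(rows)


def regional_prevalence(
    records: pd.DataFrame,
    design: SurveyDesignSpec,
    index: Literal["ciaf", "eciaf"] = "eciaf",
    **kwargs,
) -> pd.DataFrame:
    """Overall-burden estimate per region (domain estimation within stratum)."""
    column = f"{index}_group"
    rows = []
    for region in sorted(records[design.stratum_field].unique()):
        est = weighted_prevalence(
            records,
            design,
            lambda f: (f[column] != "A").to_numpy(dtype=float),
            domain=region,
            **kwargs,
        )
        rows.append(
            {
                "region": region,
                "estimate": est.estimate,
                "se": est.se,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n": est.n,
            }
        )
    return pd.DataFrame(rows)


def ci_overlap(a: PrevalenceEstimate, b: PrevalenceEstimate) -> bool:
    """True iff the two 95% intervals intersect (touching endpoints overlap)."""
    return a.ci_low <= b.ci_high and b.ci_low <= a.ci_high
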