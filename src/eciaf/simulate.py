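"""Two-stage stratified cluster survey simulator with known ground truth.

Emulates the structure of national household surveys of child
anthropometry: regions are design strata; a configurable number of
primary sampling units (clusters) is drawn without replacement from each
region's pool; households per cluster and children per household follow
the configured counts; each child carries the design weight
1 / (cluster inclusion probability), the within-cluster stage being taken
as certainty once a cluster is selected.

Anthropometry is generated on the latent z-score scale: a child's
(HAZ*, WHZ*) is region shift + cluster random effect + child effect,
where the cluster effect carries a share ``icc`` of the total variance
and HAZ*/WHZ* are correlated at ``corr_haz_whz`` at both levels.  Height
and weight are then produced by inverting the LMS reference (height from
HAZ* at the child's age and sex; weight from WHZ* at that height), so
re-running the z-scoring pipeline on the emitted raw measurements
recovers the latent scores, and WAZ and BMIZ emerge from the same single
height/weight pair exactly as in a real survey.  Because the shifts live
on the z scale, configured prevalences have closed-form normal-tail
targets (e.g. stunting ~ Phi(-2 - mean_shift_haz) at sd 1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .anthro import compute_zscores_frame, flag_implausible_frame, apply_exclusions
from .classify import classify_frame
from .reference import LMSTable, default_reference
from .anthro import lms_inverse

__all__ = ["RegionConfig", "SimConfig", "generate_survey", "generate_three_survey_scenario"]

GHANA_REGIONS = (
    "Ashanti",
    "Brong Ahafo",
    "Central",
    "Eastern",
    "Greater Accra",
    "Northern",
    "Volta",
    "Western",
    "Upper East",
    "Upper West",
)


@dataclass(frozen=True)
class RegionConfig:
    label: str
    mean_shift_haz: float
    mean_shift_whz: float
    n_psu: int
    psu_pool_size: int

    def __post_init__(self) -> None:
        if self.n_psu > self.psu_pool_size:
            raise ValueError(
                f"{self.label}: n_psu ({self.n_psu}) exceeds pool ({self.psu_pool_size})"
            )


@dataclass(frozen=True)
class SimConfig:
    seed: int
    regions: tuple[RegionConfig, ...]
    households_per_psu: int = 15
    children_per_household: float = 0.5  # Poisson mean
    icc: float = 0.03
    corr_haz_whz: float = 0.15
    sd_haz: float = 1.1
    sd_whz: float = 1.05
    age_range_months: tuple[int, int] = (6, 59)
    sex_ratio: float = 0.505  # proportion male
    survey_label: str = "SIM"

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if not -1.0 < self.corr_haz_whz < 1.0:
            raise ValueError("corr_haz_whz must lie in (-1, 1)")
        if self.sd_haz <= 0 or self.sd_whz <= 0:
            raise ValueError("latent SDs must be positive")

    def covariance(self) -> np.ndarray:
        """Total latent covariance of (HAZ*, WHZ*); must be positive-definite."""
        cov = np.array(
            [
                [self.sd_haz**2, self.corr_haz_whz * self.sd_haz * self.sd_whz],
                [self.corr_haz_whz * self.sd_haz * self.sd_whz, self.sd_whz**2],
            ]
        )
        if np.linalg.eigvalsh(cov).min() <= 0:
            raise ValueError("latent covariance is not positive-definite")
        return cov


def _draw_children(rng: np.random.Generator, config: SimConfig, region: RegionConfig):
    """Cluster/household structure and latent scores for one region."""
    psu_ids = rng.choice(region.psu_pool_size, size=region.n_psu, replace=False)
    psu_ids = np.sort(psu_ids)
    cov = config.covariance()
    chol = np.linalg.cholesky(cov)
    rows = []
    weight = region.psu_pool_size / region.n_psu  # certainty second stage
    for psu in psu_ids:
        psu_effect = chol @ rng.standard_normal(2) * np.sqrt(config.icc)
        n_children_by_hh = rng.poisson(config.children_per_household, config.households_per_psu)
        for hh, n_children in enumerate(n_children_by_hh):
            for _ in range(n_children):
                child_effect = chol @ rng.standard_normal(2) * np.sqrt(1.0 - config.icc)
                rows.append(
                    (
                        region.label,
                        f"{region.label}:{psu}",
                        f"{region.label}:{psu}:{hh}",
                        region.mean_shift_haz + psu_effect[0] + child_effect[0],
                        region.mean_shift_whz + psu_effect[1] + child_effect[1],
                        weight,
                    )
                )
    return rows


def generate_survey(
    config: SimConfig, ref: LMSTable | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate one survey and its ground-truth summary.

    Returns a child-record frame (``child_id, survey, region, psu,
    household, sex, age_months, weight_kg, height_cm, sampling_weight``)
    and a truth dict holding the latent scores' realized per-region and
    national (weighted) stunting/wasting/burden rates plus the latent
    HAZ*/WHZ* per child for roundtrip checks.
    """
    ref = ref or default_reference()
    rng = np.random.default_rng(config.seed)
    rows: list[tuple] = []
    for region in config.regions:
        rows.extend(_draw_children(rng, config, region))
    if not rows:
        raise ValueError("configuration generated no children")
    frame = pd.DataFrame(
        rows, columns=["region", "psu", "household", "latent_haz", "latent_whz", "sampling_weight"]
    )
    n = len(frame)
    lo, hi = config.age_range_months
    frame["age_months"] = rng.integers(lo, hi + 1, size=n)
    frame["sex"] = np.where(rng.random(n) < config.sex_ratio, "male", "female")
    frame["survey"] = config.survey_label
    frame["child_id"] = [f"{config.survey_label}-{i:06d}" for i in range(n)]

    height = np.empty(n)
    weight = np.empty(n)
    for sex in ("male", "female"):
        sel = (frame["sex"] == sex).to_numpy()
        if not sel.any():
            continue
        L, M, S = ref.lookup_many(
            "height_for_age", sex, frame.loc[sel, "age_months"].to_numpy(dtype=float)
        )
        height[sel] = lms_inverse(frame.loc[sel, "latent_haz"].to_numpy(), L, M, S)
        L, M, S = ref.lookup_many("weight_for_height", sex, height[sel])
        weight[sel] = lms_inverse(frame.loc[sel, "latent_whz"].to_numpy(), L, M, S)
    frame["height_cm"] = height
    frame["weight_kg"] = weight

    truth = _ground_truth(frame, ref)
    columns = [
        "child_id",
        "survey",
        "region",
        "psu",
        "household",
        "sex",
        "age_months",
        "weight_kg",
        "height_cm",
        "sampling_weight",
    ]
    truth["latent"] = frame[["child_id", "latent_haz", "latent_whz"]].copy()
    return frame[columns].copy(), truth


def _ground_truth(frame: pd.DataFrame, ref: LMSTable) -> dict:
    """Realized classification rates from the generated sample."""
    scored = classify_frame(compute_zscores_frame(frame, ref))
    failed = (scored["eciaf_group"] != "A").to_numpy(dtype=float)
    per_region = {}
    for region, sub in scored.groupby("region", sort=True):
        per_region[str(region)] = {
            "stunting": float(sub["stunted"].mean()),
            "wasting": float(sub["wasted"].mean()),
            "underweight": float(sub["underweight"].mean()),
            "burden_eciaf": float((sub["eciaf_group"] != "A").mean()),
            "n": int(len(sub)),
        }
    w = scored["sampling_weight"].to_numpy(dtype=float)
    national = {
        "stunting": float((w * scored["stunted"]).sum() / w.sum()),
        "wasting": float((w * scored["wasted"]).sum() / w.sum()),
        "underweight": float((w * scored["underweight"]).sum() / w.sum()),
        "burden_eciaf": float((w * failed).sum() / w.sum()),
        "n": int(len(scored)),
    }
    return {"regions": per_region, "national": national}


def _regions(
    haz_shifts: Sequence[float],
    whz_shifts: Sequence[float],
    n_psu: int,
    pool_factors: Sequence[int],
) -> tuple[RegionConfig, ...]:
    return tuple(
        RegionConfig(
            label=label,
            mean_shift_haz=hs,
            mean_shift_whz=ws,
            n_psu=n_psu,
            psu_pool_size=n_psu * pf,
        )
        for label, hs, ws, pf in zip(GHANA_REGIONS, haz_shifts, whz_shifts, pool_factors)
    )


# Regional latent mean shifts spanning light to heavy burden; pools of
# different sizes make the design weights informative.
_HAZ_SHIFTS = (-1.0, -0.8, -1.5, -1.2, -0.7, -1.8, -1.3, -1.1, -1.6, -2.0)
_WHZ_SHIFTS = (-0.3, -0.2, -0.6, -0.4, -0.1, -0.7, -0.5, -0.3, -0.6, -0.8)
_POOL_FACTORS = (8, 6, 5, 7, 9, 4, 6, 7, 3, 3)


def generate_three_survey_scenario(
    scale: float = 1.0, seed: int = 20111, ref: LMSTable | None = None
) -> dict[str, tuple[pd.DataFrame, dict]]:
    """Three packaged surveys mirroring the study's data-source contrasts.

    The MICS-like survey is the largest with the lightest burden; the
    DHS-like survey is intermediate; the panel-survey-like (GSPS-like)
    survey has matched median shifts but heavier latent tails (larger
    latent SDs), so it shows more wasting AND more overweight than the
    MICS-like survey — the configuration that makes the downstream CFA
    find discrimination types.  ``scale`` multiplies cluster counts.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")

    def n(base: int) -> int:
        return max(2, int(round(base * scale)))

    scenario = {
        "GMICS-like": SimConfig(
            seed=seed,
            regions=_regions(_HAZ_SHIFTS, _WHZ_SHIFTS, n(81), _POOL_FACTORS),
            households_per_psu=15,
            children_per_household=0.54,
            icc=0.03,
            corr_haz_whz=0.15,
            sd_haz=1.05,
            sd_whz=0.95,
            survey_label="GMICS-like",
        ),
        "GDHS-like": SimConfig(
            seed=seed + 1,
            regions=_regions(
                tuple(s - 0.05 for s in _HAZ_SHIFTS),
                tuple(s - 0.05 for s in _WHZ_SHIFTS),
                n(41),
                _POOL_FACTORS,
            ),
            households_per_psu=30,
            children_per_household=0.17,
            icc=0.03,
            corr_haz_whz=0.15,
            sd_haz=1.1,
            sd_whz=1.0,
            survey_label="GDHS-like",
        ),
        "GSPS-like": SimConfig(
            seed=seed + 2,
            regions=_regions(
                tuple(s - 0.05 for s in _HAZ_SHIFTS),
                tuple(s + 0.25 for s in _WHZ_SHIFTS),
                n(33),
                _POOL_FACTORS,
            ),
            households_per_psu=15,
            children_per_household=0.32,
            icc=0.03,
            corr_haz_whz=0.15,
            sd_haz=1.45,
            sd_whz=1.75,
            survey_label="GSPS-like",
        ),
    }
    return {label: generate_survey(cfg, ref) for label, cfg in scenario.items()}
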