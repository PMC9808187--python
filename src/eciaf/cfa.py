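"""Two-group configural frequency analysis (CFA) of failure configurations.

Children are cross-tabulated over the 2^3 stunting x wasting x underweight
configurations, separately for two survey groups.  Expected frequencies
come from the margin (independence) model E[c, g] = row_total_c * N_g /
(N_1 + N_2); each configuration is tested with a two-sided Fisher exact
test on the 2x2 table [this configuration vs all others] x [group 1,
group 2]; configurations significant after multiplicity adjustment are
the "discrimination types" — the failure subtypes on which the two
surveys genuinely disagree.  Counts are unweighted: the CFA is a test of
the sampled frequencies, not of the weighted population estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CONFIG_ORDER",
    "ConfigTable",
    "CFAResult",
    "build_config_table",
    "expected_frequencies",
    "config_test",
    "discrimination_types",
]

#: (stunting, wasting, underweight) triples in conventional table order
CONFIG_ORDER: tuple[tuple[bool, bool, bool], ...] = (
    (True, True, True),
    (True, True, False),
    (True, False, True),
    (True, False, False),
    (False, True, True),
    (False, True, False),
    (False, False, True),
    (False, False, False),
)


@dataclass
class ConfigTable:
    """Observed counts per configuration for two survey groups."""

    observed: np.ndarray  # shape (8, 2), nonnegative ints
    group_labels: tuple[str, str]
    configs: tuple[tuple[bool, bool, bool], ...] = CONFIG_ORDER

    def __post_init__(self) -> None:
        self.observed = np.asarray(self.observed, dtype=np.int64)
        if self.observed.shape != (len(self.configs), 2):
            raise ValueError(f"observed must have shape ({len(self.configs)}, 2)")
        if (self.observed < 0).any():
            raise ValueError("observed counts must be nonnegative")

    @property
    def group_totals(self) -> np.ndarray:
        return self.observed.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.observed.sum())


@dataclass
class CFAResult:
    table: ConfigTable
    expected: np.ndarray  # shape (8, 2)
    p_values: np.ndarray  # shape (8,)
    discrimination: np.ndarray  # shape (8,), bool
    alpha: float
    adjustment: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (s, w, u) in enumerate(self.table.configs):
            rows.append(
                {
                    "stunting": "Yes" if s else "No",
                    "wasting": "Yes" if w else "No",
                    "underweight": "Yes" if u else "No",
                    "obs_a": int(self.table.observed[i, 0]),
                    "exp_a": round(float(self.expected[i, 0]), 1),
                    "obs_b": int(self.table.observed[i, 1]),
                    "exp_b": round(float(self.expected[i, 1]), 1),
                    "p_value": round(float(self.p_values[i]), 3),
                    "discrimination": bool(self.discrimination[i]),
                }
            )
        return pd.DataFrame(rows)


def build_config_table(
    group_a: pd.DataFrame, group_b: pd.DataFrame, labels: tuple[str, str] = ("A", "B")
) -> ConfigTable:
    """Count each child into exactly one configuration, per group.

    Both frames must carry boolean ``stunted``, ``wasted``, ``underweight``
    columns (the classifier's output).
    """
    observed = np.zeros((8, 2), dtype=np.int64)
    for g, frame in enumerate((group_a, group_b)):
        if frame.empty:
            raise ValueError(f"group {labels[g]!r} is empty")
        s = frame["stunted"].to_numpy(dtype=bool)
        w = frame["wasted"].to_numpy(dtype=bool)
        u = frame["underweight"].to_numpy(dtype=bool)
        # index into CONFIG_ORDER: s,w,u big-endian with True first
        idx = (1 - s.astype(int)) * 4 + (1 - w.astype(int)) * 2 + (1 - u.astype(int))
        observed[:, g] = np.bincount(idx, minlength=8)
    return ConfigTable(observed=observed, group_labels=labels)


def expected_frequencies(table: ConfigTable) -> np.ndarray:
    """Margin-model expected counts E[c, g] = row_total_c * N_g / N.

    Conserves both margins exactly: expected column sums equal the group
    totals, and expected row sums equal the observed row sums.
    """
    totals = table.group_totals.astype(float)
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("empty table")
    row_totals = table.observed.sum(axis=1).astype(float)
    return np.outer(row_totals, totals) / grand


def config_test(table: ConfigTable, config: tuple[bool, bool, bool]) -> float:
    """Two-sided Fisher exact p for one configuration vs the rest, by group.

    Degenerate rows (configuration observed in neither group) return 1.
    """
    i = table.configs.index(tuple(config))
    in_cfg = table.observed[i]
    if in_cfg.sum() == 0:
        return 1.0
    rest = table.group_totals - in_cfg
    _, p = stats.fisher_exact([[in_cfg[0], in_cfg[1]], [rest[0], rest[1]]], alternative="two-sided")
    return float(min(p, 1.0))


def discrimination_types(
    table: ConfigTable,
    alpha: float = 0.05,
    adjustment: Literal["bonferroni", "holm", "none"] = "bonferroni",
) -> CFAResult:
    """Run the full two-group CFA and mark the discrimination types.

    Multiplicity is controlled over all K = 8 configurations; the default
    Bonferroni local level is alpha/8.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    expected = expected_frequencies(table)
    p_values = np.array([config_test(table, c) for c in table.configs])
    k = len(table.configs)
    if adjustment == "bonferroni":
        significant = p_values <= alpha / k
    elif adjustment == "holm":
        order = np.argsort(p_values)
        significant = np.zeros(k, dtype=bool)
        for rank, idx in enumerate(order):
            if p_values[idx] <= alpha / (k - rank):
                significant[idx] = True
            else:
                break
        # Holm significance respects the ordering: stop at the first failure
    elif adjustment == "none":
        significant = p_values <= alpha
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return CFAResult(
        table=table,
        expected=expected,
        p_values=p_values,
        discrimination=significant,
        alpha=alpha,
        adjustment=adjustment,
    )
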