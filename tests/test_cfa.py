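"""Two-group CFA: observed/expected tables, Fisher tests, discrimination types."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from eciaf.cfa import (
    CONFIG_ORDER,
    ConfigTable,
    build_config_table,
    config_test,
    discrimination_types,
    expected_frequencies,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by full hypergeometric enumeration.

    Conditions on all margins; sums P(k) over every table in the support
    whose probability does not exceed the observed table's (the
    minimum-likelihood two-sided rule).
    """
    row1, col1, n = a + b, a + c, a + b + c + d
    kmin, kmax = max(0, row1 + col1 - n), min(row1, col1)
    pmfs = {k: hypergeom.pmf(k, n, col1, row1) for k in range(kmin, kmax + 1)}
    p_obs = pmfs[a]
    return sum(p for p in pmfs.values() if p <= p_obs * (1 + 1e-9))


def table_from_counts(counts_a, counts_b, labels=("A", "B")):
    return ConfigTable(np.column_stack([counts_a, counts_b]), labels)


# Printed cross-survey observed counts in CONFIG_ORDER (YYY..NNN).
GDHS = [40, 0, 188, 415, 74, 74, 18, 1332]
GMICS = [164, 0, 693, 1042, 179, 106, 116, 4232]
GSPS = [103, 0, 135, 332, 148, 61, 14, 815]


def classified_frame(triples):
    rows = [
        {"stunted": s, "wasted": w, "underweight": u, "haz": 0.0} for s, w, u in triples
    ]
    return pd.DataFrame(rows)


class TestBuildConfigTable:
    def test_all_no_failure_column(self):
        table = build_config_table(
            classified_frame([(False, False, False)] * 3),
            classified_frame([(True, True, True)]),
        )
        assert table.observed[:, 0].tolist() == [0, 0, 0, 0, 0, 0, 0, 3]

    def test_enumeration(self):
        frame = classified_frame([(True, True, True), (True, False, False), (False, False, False)])
        table = build_config_table(frame, classified_frame([(False, False, False)]))
        counted = dict(zip(CONFIG_ORDER, table.observed[:, 0]))
        assert counted[(True, True, True)] == 1
        assert counted[(True, False, False)] == 1
        assert counted[(False, False, False)] == 1

    def test_totals_conserved(self):
        a = classified_frame([(True, False, True)] * 5)
        b = classified_frame([(False, True, False)] * 7)
        assert build_config_table(a, b).grand_total == 12

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            build_config_table(classified_frame([]), classified_frame([(True, True, True)]))


class TestExpectedFrequencies:
    def test_printed_cross_survey_tables(self):
        """Margin-model expected counts match the published two-group tables."""
        exp_a = expected_frequencies(table_from_counts(GDHS, GMICS))
        assert exp_a[0, 0] == pytest.approx(50.4, abs=0.05)  # YYY, first group
        assert exp_a[7, 0] == pytest.approx(1373.5, abs=0.05)  # NNN, first group
        exp_b = expected_frequencies(table_from_counts(GSPS, GDHS))
        assert exp_b[0, 0] == pytest.approx(61.3, abs=0.05)
        exp_c = expected_frequencies(table_from_counts(GSPS, GMICS))
        assert exp_c[4, 0] == pytest.approx(64.6, abs=0.05)  # NYY
        assert exp_c[6, 0] == pytest.approx(25.7, abs=0.05)  # NNY

    def test_zero_row_stays_zero(self):
        exp = expected_frequencies(table_from_counts(GDHS, GMICS))
        assert exp[1, 0] == 0.0 and exp[1, 1] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_margin_conservation_on_random_tables(self, seed):
        rng = np.random.default_rng(seed)
        table = ConfigTable(rng.integers(0, 50, size=(8, 2)), ("A", "B"))
        exp = expected_frequencies(table)
        assert exp.sum(axis=0) == pytest.approx(table.group_totals.astype(float))
        assert exp.sum(axis=1) == pytest.approx(table.observed.sum(axis=1).astype(float))
        assert exp.sum() == pytest.approx(table.grand_total)


class TestConfigTest:
    def test_zero_row_gives_p_one(self):
        assert config_test(table_from_counts(GDHS, GMICS), (True, True, False)) == 1.0

    def test_exact_small_table(self):
        # 2x2 (3,0 / 0,3): 2 of the 20 equiprobable-margin tables are as extreme
        table = table_from_counts([3, 0, 0, 0, 0, 0, 0, 0], [0, 0, 0, 0, 0, 0, 0, 3])
        assert config_test(table, (True, True, True)) == pytest.approx(0.1)

    def test_matches_enumeration_oracle_on_small_tables(self):
        """Fisher p equals brute-force hypergeometric enumeration (total <= 60)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 16, size=4)
            if a + b == 0 or a + b + c + d == 0:
                continue
            counts_a = [a, 0, 0, 0, 0, 0, 0, c]
            counts_b = [b, 0, 0, 0, 0, 0, 0, d]
            p = config_test(table_from_counts(counts_a, counts_b), (True, True, True))
            assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)

    def test_label_swap_symmetry(self):
        table = table_from_counts(GSPS, GMICS)
        swapped = table_from_counts(GMICS, GSPS)
        for config in CONFIG_ORDER:
            assert config_test(table, config) == pytest.approx(
                config_test(swapped, config), abs=1e-12
            )
        exp, exp_swapped = expected_frequencies(table), expected_frequencies(swapped)
        assert exp[:, 0] == pytest.approx(exp_swapped[:, 1])


class TestDiscriminationTypes:
    def test_all_p_one_gives_no_types(self):
        table = table_from_counts([5] * 8, [5] * 8)
        result = discrimination_types(table)
        # equal groups: every configuration is at its expected value
        assert not result.discrimination.any()

    def test_printed_p_vector_under_bonferroni(self):
        """Thresholding the published p-values at alpha/8 reproduces the
        published True/blank discrimination pattern."""
        p = np.array([0.015, 1.0, 0.002, 0.000, 0.014, 0.000, 0.001, 0.002])
        significant = p <= 0.05 / 8
        assert np.flatnonzero(significant).tolist() == [2, 3, 5, 6, 7]

    def test_no_adjustment_thresholds_directly(self):
        p = np.array([0.015, 1.0, 0.002, 0.000, 0.014, 0.000, 0.001, 0.002])
        assert np.flatnonzero(p <= 0.05).tolist() == [0, 2, 3, 4, 5, 6, 7]

    def test_monotone_in_alpha(self):
        table = table_from_counts(GSPS, GMICS)
        small = discrimination_types(table, alpha=0.01).discrimination
        large = discrimination_types(table, alpha=0.10).discrimination
        assert np.all(large[small])  # small-alpha set is a subset

    def test_holm_at_least_as_powerful_as_bonferroni(self):
        table = table_from_counts(GDHS, GMICS)
        bonf = discrimination_types(table, adjustment="bonferroni").discrimination
        holm = discrimination_types(table, adjustment="holm").discrimination
        assert np.all(holm[bonf])

    def test_result_frame_layout(self):
        frame = discrimination_types(table_from_counts(GDHS, GMICS)).to_frame()
        assert list(frame.columns) == [
            "stunting",
            "wasting",
            "underweight",
            "obs_a",
            "exp_a",
            "obs_b",
            "exp_b",
            "p_value",
            "discrimination",
        ]
        assert frame.loc[0, "exp_a"] == 50.4
        assert frame.loc[7, "exp_a"] == 1373.5
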