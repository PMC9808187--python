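"""LMS transform, restricted tail adjustment, flagging and exclusions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eciaf.anthro import (
    ChildRecord,
    InvalidMeasurementError,
    ZScoreSet,
    apply_exclusions,
    compute_zscores,
    compute_zscores_frame,
    flag_implausible,
    flag_implausible_frame,
    lms_inverse,
    lms_zscore,
    restricted_adjust,
)
from eciaf.reference import ReferenceCoverageError


class TestLMSZScore:
    @pytest.mark.parametrize("L,S", [(1.0, 0.1), (-0.5, 0.08), (0.0, 0.12)])
    def test_median_maps_to_zero(self, L, S):
        assert lms_zscore(16.0, L, 16.0, S) == pytest.approx(0.0, abs=1e-12)

    def test_linear_case_reduces_to_standardization(self):
        assert lms_zscore(11.0, 1.0, 10.0, 0.1) == pytest.approx(1.0)

    def test_boxcox_closed_form(self):
        # ((18/16)^-0.5 - 1) / (-0.5 * 0.08)
        assert lms_zscore(18.0, -0.5, 16.0, 0.08) == pytest.approx(1.4298, abs=5e-5)

    def test_log_form_at_l_zero(self):
        assert lms_zscore(16.0 * np.e**0.12, 0.0, 16.0, 0.12) == pytest.approx(1.0)

    @pytest.mark.parametrize("x,M,S", [(-1.0, 10.0, 0.1), (5.0, -1.0, 0.1), (5.0, 10.0, 0.0)])
    def test_nonpositive_arguments_rejected(self, x, M, S):
        with pytest.raises(InvalidMeasurementError):
            lms_zscore(x, 1.0, M, S)

    @given(
        L=st.floats(-2.0, 2.0),
        M=st.floats(1.0, 100.0),
        S=st.floats(0.01, 0.3),
        x1=st.floats(0.5, 200.0),
        x2=st.floats(0.5, 200.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_strictly_increasing_in_x(self, L, M, S, x1, x2):
        if x1 == x2:
            return
        lo, hi = sorted((x1, x2))
        assert lms_zscore(lo, L, M, S) < lms_zscore(hi, L, M, S)


class TestLMSInverse:
    def test_zero_returns_median(self):
        assert lms_inverse(0.0, -0.5, 16.0, 0.08) == pytest.approx(16.0)

    def test_linear_case(self):
        assert lms_inverse(1.0, 1.0, 10.0, 0.1) == pytest.approx(11.0)

    def test_inverts_the_derived_example(self):
        assert lms_inverse(1.4298, -0.5, 16.0, 0.08) == pytest.approx(18.0, abs=1e-3)

    def test_domain_error_outside_boxcox_support(self):
        with pytest.raises(InvalidMeasurementError):
            lms_inverse(-30.0, 1.0, 10.0, 0.1)  # 1 + L*S*z < 0

    @given(
        L=st.floats(-2.0, 2.0),
        M=st.floats(1.0, 100.0),
        S=st.floats(0.01, 0.2),
        z=st.floats(-4.0, 4.0),
    )
    @settings(max_examples=1000, deadline=None)
    def test_roundtrip(self, L, M, S, z):
        if L != 0 and 1 + L * S * z <= 1e-6:
            return
        x = lms_inverse(z, L, M, S)
        assert lms_zscore(x, L, M, S) == pytest.approx(z, abs=1e-9)


class TestRestrictedAdjust:
    sd_curve = staticmethod(lambda z: lms_inverse(z, 1.0, 10.0, 0.1))  # SD2=12, SD3=13

    def test_identity_inside_three_sd(self):
        assert restricted_adjust(1.7, 11.7, self.sd_curve) == 1.7

    def test_continuity_at_the_knot(self):
        assert restricted_adjust(3.0, 13.0, self.sd_curve) == 3.0

    def test_upper_tail_formula(self):
        # x=14: 3 + (14-13)/(13-12) = 4
        assert restricted_adjust(3.5, 14.0, self.sd_curve) == pytest.approx(4.0)

    def test_lower_tail_mirrored(self):
        # SD-3=7, SD-2=8; x=6.5 -> -3 + (6.5-7)/(8-7) = -3.5
        assert restricted_adjust(-3.2, 6.5, self.sd_curve) == pytest.approx(-3.5)

    def test_degenerate_reference_rejected(self):
        with pytest.raises(ReferenceCoverageError):
            restricted_adjust(4.0, 14.0, lambda z: 10.0)

    def test_preserves_order(self):
        xs = np.linspace(9.0, 16.0, 40)
        zs = [lms_zscore(x, 1.0, 10.0, 0.1) for x in xs]
        adj = [restricted_adjust(z, x, self.sd_curve) for z, x in zip(zs, xs)]
        assert np.all(np.diff(adj) > 0)


class TestComputeZScores:
    def test_child_at_reference_medians_scores_zero(self, reference):
        params_h = reference.lookup("height_for_age", "male", 24.0)
        params_w = reference.lookup("weight_for_age", "male", 24.0)
        child = ChildRecord("c1", "S", "R", "P", "H", "male", 24, params_w.M, params_h.M)
        zset = compute_zscores(child, reference)
        assert zset.haz == pytest.approx(0.0, abs=1e-9)
        assert zset.waz == pytest.approx(0.0, abs=1e-9)

    def test_latent_roundtrip_through_generated_measurements(self, small_survey, reference):
        records, truth = small_survey
        scored = compute_zscores_frame(records, reference)
        merged = scored.set_index("child_id").join(truth["latent"].set_index("child_id"))
        inside = merged[np.abs(merged["latent_haz"]) <= 3]
        assert np.abs(inside["haz"] - inside["latent_haz"]).max() < 1e-6
        inside_w = merged[np.abs(merged["latent_whz"]) <= 3]
        assert np.abs(inside_w["whz"] - inside_w["latent_whz"]).max() < 1e-6

    def test_under_six_months_flagged(self, reference):
        child = ChildRecord("c1", "S", "R", "P", "H", "female", 4, 6.0, 62.0)
        assert "under_6_months" in compute_zscores(child, reference).flags

    def test_out_of_coverage_key_names_indicator(self, reference):
        child = ChildRecord("c1", "S", "R", "P", "H", "male", 24, 12.0, 140.0)
        with pytest.raises(ReferenceCoverageError, match="weight_for_height"):
            compute_zscores(child, reference)

    def test_missing_measurement_gives_missing_components(self, reference):
        frame = pd.DataFrame(
            [
                {
                    "child_id": "c1",
                    "survey": "S",
                    "region": "R",
                    "psu": "P",
                    "household": "H",
                    "sex": "male",
                    "age_months": 24,
                    "weight_kg": np.nan,
                    "height_cm": 85.0,
                    "sampling_weight": 1.0,
                }
            ]
        )
        out = compute_zscores_frame(frame, reference)
        assert np.isfinite(out.loc[0, "haz"])
        assert np.isnan(out.loc[0, "waz"]) and np.isnan(out.loc[0, "whz"])


class TestFlagging:
    def test_typical_values_unflagged(self):
        zset = flag_implausible(ZScoreSet(haz=-1.4, waz=-1.0, whz=-0.4, bmiz=-0.2))
        assert zset.flags == set()

    @pytest.mark.parametrize(
        "component,value",
        [("haz", -6.5), ("haz", 6.2), ("waz", 5.5), ("whz", -5.2), ("bmiz", 5.1)],
    )
    def test_out_of_limit_values_flagged(self, component, value):
        zset = flag_implausible(ZScoreSet(**{component: value}))
        assert f"{component}_flag" in zset.flags

    def test_boundary_is_plausible(self):
        zset = flag_implausible(ZScoreSet(whz=-5.0, haz=6.0, waz=5.0))
        assert zset.flags == set()

    def test_missing_components_skipped(self):
        assert flag_implausible(ZScoreSet()).flags == set()


def _zscored_row(i, age=24, haz=-1.0, **over):
    row = {
        "child_id": f"c{i}",
        "survey": "S",
        "region": "R",
        "psu": "P",
        "household": f"H{i}",
        "sex": "male",
        "age_months": age,
        "haz": haz,
        "waz": -0.5,
        "whz": -0.2,
        "bmiz": 0.0,
        "under_6_months": age < 6,
        "sampling_weight": 1.0,
    }
    row.update(over)
    return row


class TestExclusions:
    def test_clean_records_all_kept(self):
        frame = pd.DataFrame([_zscored_row(i) for i in range(10)])
        included, tally = apply_exclusions(frame)
        assert len(included) == 10
        assert tally == {"under_6_months": 0, "flagged": 0}

    def test_reason_tally(self):
        rows = [_zscored_row(0, age=3)] + [_zscored_row(1, haz=7.0)]
        rows += [_zscored_row(i) for i in range(2, 10)]
        included, tally = apply_exclusions(pd.DataFrame(rows))
        assert len(included) == 8
        assert tally == {"under_6_months": 1, "flagged": 1}

    def test_age_rule_takes_precedence(self):
        frame = pd.DataFrame([_zscored_row(0, age=3, haz=7.0)])
        included, tally = apply_exclusions(frame)
        assert tally == {"under_6_months": 1, "flagged": 0}
        assert included.empty

    @given(st.lists(st.tuples(st.integers(0, 59), st.floats(-8, 8)), min_size=1, max_size=40))
    @settings(max_examples=50, deadline=None)
    def test_conservation(self, children):
        frame = pd.DataFrame(
            [_zscored_row(i, age=a, haz=h) for i, (a, h) in enumerate(children)]
        )
        included, tally = apply_exclusions(frame)
        assert len(included) + sum(tally.values()) == len(frame)
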