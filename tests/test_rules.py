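"""The decision tree: spec'd boundary semantics, precedence, and invariants."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from capiscore.errors import ContractError, ValidationError
from capiscore.model import FeatureVector
from capiscore.patterns import SSC_PATTERNS, Group, Pattern, group
from capiscore.rules import (
    DEFAULT_THRESHOLDS,
    Thresholds,
    capi_score,
    rule1_ssc_vs_nonssc,
    rule4_normal_vs_nonspecific,
    stage_ssc,
)

from _oracles import naive_capi

fv = FeatureVector.from_features


class TestRule1:
    @pytest.mark.parametrize(
        "density,giant,abnormal,expected",
        [
            (6.0, 0.0, 0.0, Group.SSC),      # density cut-off is inclusive
            (6.0 + 1e-9, 0.0, 0.0, Group.NON_SSC),
            (9.0, 0.5, 0.0, Group.SSC),      # any giant capillary
            (9.0, 0.0, 10.0, Group.NON_SSC),  # abnormal cut-off is strict
            (9.0, 0.0, 10.1, Group.SSC),
        ],
    )
    def test_disjuncts_and_boundaries(self, density, giant, abnormal, expected):
        grp, _ = rule1_ssc_vs_nonssc(fv(density, pct_giant=giant, pct_abnormal=abnormal))
        assert grp is expected

    def test_trace_lists_every_fired_disjunct(self):
        _, trace = rule1_ssc_vs_nonssc(fv(4.0, pct_giant=1.0, pct_abnormal=50.0))
        assert trace == ["R1_DENSITY_LE_6", "R1_GIANTS_DETECTED", "R1_ABNORMAL_GT_10"]


class TestStaging:
    @pytest.mark.parametrize(
        "density,giant,abnormal,expected",
        [
            (6.0, 0.0, 0.0, Pattern.SSC_EARLY),   # rule 2 default
            (6.0, 0.0, 5.0, Pattern.SSC_ACTIVE),  # abnormal >= 5 inclusive
            (6.0, 10.0, 0.0, Pattern.SSC_ACTIVE),  # giant >= 10 inclusive
            (4.0, 40.0, 10.0, Pattern.SSC_ACTIVE),  # active override, no late clause
            (4.0, 10.0, 10.0, Pattern.SSC_LATE),   # no override fires
            (4.0, 5.0, 5.0, Pattern.SSC_LATE),     # late clause beats active override
            (4.0, 40.0, 20.0, Pattern.SSC_LATE),   # late clause beats giant override
        ],
    )
    def test_staging_outcomes(self, density, giant, abnormal, expected):
        pattern, _ = stage_ssc(fv(density, pct_giant=giant, pct_abnormal=abnormal))
        assert pattern is expected

    def test_trace_records_default_then_overrides_in_order(self):
        _, trace = stage_ssc(fv(4.0, pct_giant=5.0, pct_abnormal=5.0))
        assert trace == ["R3_LATE_DEFAULT", "R3_ACTIVE_OVERRIDE", "R3_LATE_FINAL_OVERRIDE"]

    def test_non_ssc_vector_is_a_contract_error(self):
        with pytest.raises(ContractError):
            stage_ssc(fv(9.0))


class TestRule4:
    @pytest.mark.parametrize(
        "tortuous,abnormal,haem,expected",
        [
            (20.0, 0.0, False, Pattern.NON_SPECIFIC),  # >= 20 inclusive
            (0.0, 0.0, True, Pattern.NON_SPECIFIC),    # any haemorrhage
            (0.0, 2.0, False, Pattern.NON_SPECIFIC),   # >= 2 inclusive
            (19.9, 1.9, False, Pattern.NORMAL),
        ],
    )
    def test_split_outcomes(self, tortuous, abnormal, haem, expected):
        pattern, _ = rule4_normal_vs_nonspecific(
            fv(9.0, pct_abnormal=abnormal, pct_tortuous=tortuous, haemorrhages_present=haem)
        )
        assert pattern is expected

    def test_normal_default_is_traced(self):
        _, trace = rule4_normal_vs_nonspecific(fv(9.0))
        assert trace == ["R4_NORMAL_DEFAULT"]

    def test_ssc_vector_is_a_contract_error(self):
        with pytest.raises(ContractError):
            rule4_normal_vs_nonspecific(fv(4.0))


class TestCapiScore:
    @pytest.mark.parametrize(
        "kwargs,expected",
        [
            (dict(density=9.0), Pattern.NORMAL),
            (dict(density=3.0, pct_abnormal=20.0), Pattern.SSC_LATE),
            (dict(density=5.5, pct_giant=15.0), Pattern.SSC_ACTIVE),
        ],
    )
    def test_composed_tree(self, kwargs, expected):
        pattern, trace = capi_score(fv(**kwargs))
        assert pattern is expected
        assert trace  # never empty

    @given(
        density=st.floats(0, 15, allow_nan=False),
        giant=st.floats(0, 100, allow_nan=False),
        abnormal=st.floats(0, 100, allow_nan=False),
        tortuous=st.floats(0, 100, allow_nan=False),
        haem=st.booleans(),
    )
    def test_totality_group_consistency_and_oracle(self, density, giant, abnormal, tortuous, haem):
        vector = fv(density, giant, abnormal, tortuous, haem)
        pattern, trace = capi_score(vector)
        assert pattern in Pattern
        assert trace
        grp, _ = rule1_ssc_vs_nonssc(vector)
        assert (pattern in SSC_PATTERNS) == (grp is Group.SSC)
        assert group(pattern) is grp
        assert pattern is naive_capi(density, giant, abnormal, tortuous, haem)

    @given(
        density=st.floats(0, 15, allow_nan=False),
        lower=st.floats(0, 1, allow_nan=False),
        giant=st.floats(0, 100, allow_nan=False),
        abnormal=st.floats(0, 100, allow_nan=False),
    )
    def test_ssc_membership_monotone_in_density(self, density, lower, giant, abnormal):
        """Lowering density can never move an SSc exam to non-SSc."""
        grp_hi, _ = rule1_ssc_vs_nonssc(fv(density, giant, abnormal))
        grp_lo, _ = rule1_ssc_vs_nonssc(fv(density * lower, giant, abnormal))
        if grp_hi is Group.SSC:
            assert grp_lo is Group.SSC


class TestThresholds:
    def test_defaults_are_the_printed_cutoffs(self):
        assert DEFAULT_THRESHOLDS.as_dict() == {
            "r1_density_max": 6.0,
            "r1_abnormal_gt": 10.0,
            "r23_density_split": 5.0,
            "r2_giant_ge": 10.0,
            "r2_abnormal_ge": 5.0,
            "r3_giant_active_ge": 33.0,
            "r3_abnormal_active_le": 7.0,
            "r3_giant_late_le": 7.0,
            "r3_abnormal_late_ge": 15.0,
            "r4_tortuous_ge": 20.0,
            "r4_abnormal_ge": 2.0,
        }

    def test_unknown_keys_rejected(self):
        with pytest.raises(ValidationError, match="unknown threshold"):
            Thresholds.from_mapping({"r1_density_max": 6, "bogus": 1})

    def test_custom_thresholds_change_classification(self):
        vector = fv(6.5)
        assert capi_score(vector)[0] is Pattern.NORMAL
        relaxed = Thresholds.from_mapping({"r1_density_max": 7.0})
        assert capi_score(vector, relaxed)[0] in SSC_PATTERNS
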