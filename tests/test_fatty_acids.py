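"""Fatty-acid parsing, class sums and derived indexes."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oxidiet import tables
from oxidiet.fatty_acids import (
    FattyAcidNameError,
    FattyAcidProfile,
    class_sums,
    desaturase_indexes,
    diet_shift,
    inflammation_index,
    parse_fa_name,
    round_half_up,
)

# hand-built family lookup for the 22 acids of the study profile; independent
# oracle for the parser-driven class sums
FAMILY_LOOKUP = {
    "14:0": ("SAT", None), "15:0": ("SAT", None), "16:0": ("SAT", None),
    "17:0": ("SAT", None), "18:0": ("SAT", None), "20:0": ("SAT", None),
    "16:1ω7": ("MUFA", None), "18:1ω9": ("MUFA", None),
    "18:1ω7": ("MUFA", None), "20:1ω9": ("MUFA", None),
    "18:2ω6": ("PUFA", "ω6"), "18:3ω6": ("PUFA", "ω6"),
    "20:2ω6": ("PUFA", "ω6"), "20:3ω6": ("PUFA", "ω6"),
    "20:4ω6": ("PUFA", "ω6"), "22:4ω6": ("PUFA", "ω6"),
    "22:5ω6": ("PUFA", "ω6"),
    "18:3ω3": ("PUFA", "ω3"), "18:4ω3": ("PUFA", "ω3"),
    "20:5ω3": ("PUFA", "ω3"), "22:5ω3": ("PUFA", "ω3"),
    "22:6ω3": ("PUFA", "ω3"),
}


def brute_force_class_sums(values: dict) -> dict:
    out = {"SAT": 0.0, "MUFA": 0.0, "PUFA": 0.0, "omega3": 0.0, "omega6": 0.0}
    for fa, pct in values.items():
        cls, fam = FAMILY_LOOKUP[fa]
        out[cls] += pct
        if fam == "ω3":
            out["omega3"] += pct
        elif fam == "ω6":
            out["omega6"] += pct
    return out


class TestParse:
    @pytest.mark.parametrize(
        "name,carbons,bonds,family",
        [
            ("20:5ω3", 20, 5, "ω3"),
            ("16:0", 16, 0, "saturated"),
            ("18:1ω9", 18, 1, "ω9"),
            ("16:1 ω - 7", 16, 1, "ω7"),
            ("16:1ω − 7", 16, 1, "ω7"),
            ("18:3n-3", 18, 3, "ω3"),
            ("22:6w3", 22, 6, "ω3"),
        ],
    )
    def test_accepted_dialects(self, name, carbons, bonds, family):
        d = parse_fa_name(name)
        assert (d.carbons, d.double_bonds, d.family) == (carbons, bonds, family)

    @pytest.mark.parametrize(
        "bad", ["", "xx", "18", "18:", ":3ω6", "18:1", "16:0ω7", "18:1ω5", "1:1ω9"]
    )
    def test_malformed_names_raise(self, bad):
        with pytest.raises(FattyAcidNameError):
            parse_fa_name(bad)

    def test_error_names_offending_token(self):
        with pytest.raises(FattyAcidNameError, match="18:1ω5"):
            parse_fa_name("18:1ω5")

    def test_dialects_collapse_to_one_key(self):
        prof = FattyAcidProfile({"18:3n-3": 100.0})
        assert prof["18:3ω3"] == 100.0
        with pytest.raises(FattyAcidNameError):
            FattyAcidProfile({"18:3n-3": 50.0, "18:3ω3": 50.0})


class TestProfileValidation:
    def test_total_must_be_near_100(self):
        with pytest.raises(ValueError, match="total"):
            FattyAcidProfile({"16:0": 90.0})
        FattyAcidProfile({"16:0": 99.6})  # within default tol 0.5

    def test_negative_percentage_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            FattyAcidProfile({"16:0": 101.0, "18:0": -1.0})

    def test_renormalized_sums_to_100(self):
        prof = FattyAcidProfile({"16:0": 30.0, "18:0": 30.0}, validate=False)
        assert prof.renormalized().total() == pytest.approx(100.0)


class TestClassSums:
    def test_matches_brute_force_on_printed_profiles(self, group_profiles):
        for prof in group_profiles.values():
            expect = brute_force_class_sums(prof.values)
            cs = class_sums(prof)
            assert cs.SAT == pytest.approx(expect["SAT"])
            assert cs.MUFA == pytest.approx(expect["MUFA"])
            assert cs.PUFA == pytest.approx(expect["PUFA"])
            assert cs.omega3 == pytest.approx(expect["omega3"])
            assert cs.omega6 == pytest.approx(expect["omega6"])

    @pytest.mark.parametrize(
        "row,group,expected",
        [
            ("omega3", "STD", 7.02),
            ("MUFA", "STD", 13.46),
            ("PUFA", "STD", 55.32),
            ("omega6", "STD", 48.30),
            ("omega6", "HFHS", 29.28),
            ("omega6", "HFHS+ω3", 27.56),
            ("PUFA", "HFHS+ω3", 41.52),
            ("omega3", "HFHS+ω3", 13.96),
        ],
    )
    def test_reproduces_exactly_summing_printed_rows(
        self, group_profiles, row, group, expected
    ):
        cs = class_sums(group_profiles[group])
        assert round_half_up(getattr(cs, row), 2) == expected

    def test_all_zero_profile(self):
        prof = FattyAcidProfile({"16:0": 0.0, "20:5ω3": 0.0}, validate=False)
        cs = class_sums(prof)
        assert (cs.SAT, cs.MUFA, cs.PUFA, cs.omega3, cs.omega6) == (0,) * 5

    def test_classes_partition_total(self, group_profiles):
        for prof in group_profiles.values():
            cs = class_sums(prof)
            assert cs.SAT + cs.MUFA + cs.PUFA == pytest.approx(prof.total())
            assert cs.omega3 + cs.omega6 <= cs.PUFA + 1e-9


class TestDesaturaseIndexes:
    def test_printed_ratio_of_means_cells(self, group_profiles):
        idx_std = desaturase_indexes(group_profiles["STD"])
        assert round_half_up(idx_std.scd16, 2) == 0.07
        assert round_half_up(idx_std.epa_dha, 3) == 0.068
        idx_hfhs = desaturase_indexes(group_profiles["HFHS"])
        assert round_half_up(idx_hfhs.scd16, 2) == 0.10
        assert round_half_up(idx_hfhs.d6d_dgla, 2) == 0.06

    def test_zero_denominator_is_undefined_not_error(self):
        prof = FattyAcidProfile({"16:1ω7": 100.0})
        idx = desaturase_indexes(prof)
        assert idx.scd16 is None
        assert idx.scd18 is None

    @given(c=st.floats(min_value=0.01, max_value=100.0))
    @settings(max_examples=30, deadline=None)
    def test_scale_invariance(self, c):
        prof = tables.group_mean_profile("STD")
        base = desaturase_indexes(prof).as_dict()
        scaled = desaturase_indexes(prof.scaled(c)).as_dict()
        for k in base:
            if base[k] is None:
                assert scaled[k] is None
            else:
                assert scaled[k] == pytest.approx(base[k], rel=1e-9)


class TestInflammationIndex:
    def test_printed_group_ratios(self, group_profiles):
        assert inflammation_index(group_profiles["STD"]) == pytest.approx(
            48.30 / 7.02, abs=5e-3
        )
        assert inflammation_index(group_profiles["HFHS+ω3"]) == pytest.approx(
            27.56 / 13.96, abs=5e-3
        )

    def test_zero_omega6_gives_zero(self):
        prof = FattyAcidProfile({"22:6ω3": 100.0})
        assert inflammation_index(prof) == 0.0

    def test_zero_omega3_is_undefined(self):
        prof = FattyAcidProfile({"18:2ω6": 100.0})
        assert inflammation_index(prof) is None


class TestDietShift:
    def test_dha_epa_shifts_between_diets(self, group_profiles):
        a, b = group_profiles["HFHS"], group_profiles["HFHS+ω3"]
        assert diet_shift(a, b, ["22:6ω3"]) == pytest.approx(3.46)
        assert diet_shift(a, b, ["20:5ω3"]) == pytest.approx(0.74)
        assert diet_shift(a, b, ["20:5ω3", "22:6ω3"]) == pytest.approx(4.20)

    def test_identity_and_errors(self, group_profiles):
        p = group_profiles["STD"]
        assert diet_shift(p, p, ["22:6ω3"]) == 0.0
        with pytest.raises(KeyError):
            diet_shift(p, p, ["24:1ω9"])
        with pytest.raises(ValueError):
            diet_shift(p, p, [])


def test_round_half_up_ties_go_up():
    assert round_half_up(0.125, 2) == 0.13
    assert round_half_up(0.845, 2) == 0.85
    assert round_half_up(2.5, 0) == 3.0
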