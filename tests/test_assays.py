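import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tbitriage.assays import (
    analyze_plate,
    assay_points,
    compound_assay_points,
    dose_dependence,
    mann_whitney_vs_control,
    percent_of_control,
)
from tbitriage.simulate import simulate_coculture_plate


def oracle_mw_two_sided(a, b):
    """Independent exact Mann-Whitney oracle: count pairwise wins over all
    reassignments of the pooled values (no ranks involved)."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else 0.5 if x == y else 0.0
            for x in group_a for y in group_b
        )

    u_obs = u_stat(a, b)
    us = []
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        us.append(u_stat(ga, gb))
    us = np.asarray(us)
    le = np.mean(us <= u_obs + 1e-9)
    ge = np.mean(us >= u_obs - 1e-9)
    return min(1.0, 2.0 * min(le, ge))


class TestPercentOfControl:
    def test_control_vs_itself_is_100(self):
        assert percent_of_control([3, 4, 5], [3, 4, 5]) == pytest.approx(100.0)

    def test_hand_computed_ratio(self):
        assert percent_of_control([37, 37], [50, 50]) == pytest.approx(74.0)

    def test_zero_numerator(self):
        assert percent_of_control([0, 0], [10, 20]) == 0.0

    def test_zero_control_mean_rejected(self):
        with pytest.raises(ValueError):
            percent_of_control([1.0], [0.0, 0.0])


class TestMannWhitney:
    def test_full_separation_3v3(self):
        """U=0 has one-sided probability 1/20 over the C(6,3) assignments."""
        assert mann_whitney_vs_control([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_constant_samples(self):
        assert mann_whitney_vs_control([5, 5, 5], [5, 5, 5]) == 1.0

    def test_shuffled_copies_are_symmetric(self):
        a = [1.0, 2.5, 3.0, 4.0]
        assert mann_whitney_vs_control(a, [3.0, 1.0, 4.0, 2.5]) == 1.0

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            mann_whitney_vs_control([1], [2, 3])

    def test_exact_agrees_with_enumeration_oracle(self):
        """1000 random small-sample cases (with ties) against the
        independent pairwise-counting oracle."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            na = rng.integers(2, 6)
            nb = rng.integers(2, 11 - na)
            # coarse grid makes ties common
            a = rng.integers(0, 6, size=na).astype(float)
            b = rng.integers(0, 6, size=nb).astype(float)
            got = mann_whitney_vs_control(a, b)
            want = oracle_mw_two_sided(a, b)
            assert got == pytest.approx(want, abs=1e-12), (a, b)

    def test_large_sample_uses_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1.5, 1, 12)
        p = mann_whitney_vs_control(a, b)
        assert 0 < p < 0.05


class TestDoseDependence:
    def test_identical_groups_not_more_effective(self):
        p, flag = dose_dependence([5, 5, 6, 6], [5, 5, 6, 6], 0.01, 0.1)
        assert p == 1.0 and flag is False

    def test_full_separation_4v4_inhibition(self):
        p, flag = dose_dependence([10, 11, 12, 13], [1, 2, 3, 4], 0.01, 0.1)
        assert p == pytest.approx(2 / 70)
        assert flag is True

    def test_weaker_higher_concentration_fails_direction_gate(self):
        p, flag = dose_dependence([1, 2, 3, 4], [10, 11, 12, 13], 0.01, 0.1)
        assert p < 0.05 and flag is False

    def test_equal_concentration_labels_rejected(self):
        with pytest.raises(ValueError):
            dose_dependence([1, 2], [3, 4], 0.1, 0.1)


class TestAssayPoints:
    @pytest.mark.parametrize(
        "analyte, percent, significant, expected",
        [
            ("TNFa", 56.0, True, 2),
            ("TNFa", 70.0, True, 2),     # favourable-side inclusive edge
            ("TNFa", 120.0, True, -5),
            ("TNFa", 95.0, True, 0),
            ("TNFa", 5.0, False, 0),
            ("nitrite", 100.0, False, 0),
            ("nitrite", 8.0, True, 5),
            ("viability", 140.0, True, 1),
            ("viability", 90.0, True, -5),
            ("viability", 110.0, True, 0),
            ("viability", 320.0, True, 5),
            ("viability", 400.0, False, 0),
        ],
    )
    def test_band_table(self, analyte, percent, significant, expected):
        assert assay_points(analyte, percent, significant) == expected

    def test_unknown_analyte_rejected(self):
        with pytest.raises(ValueError):
            assay_points("LDH", 50.0, True)

    @given(st.floats(0, 100), st.floats(0, 100))
    @settings(max_examples=200, deadline=None)
    def test_inhibition_monotone_in_percent(self, p1, p2):
        lo, hi = sorted([p1, p2])
        assert assay_points("TNFa", lo, True) >= assay_points("TNFa", hi, True)


class TestPlateAnalysis:
    def test_planted_inhibition_detected_and_banded(self):
        effects = {
            ("drugA", 1.0, "TNFa"): 40.0,
            ("drugA", 0.1, "TNFa"): 80.0,
            ("drugA", 1.0, "viability"): 140.0,
        }
        plate = simulate_coculture_plate(effects, cv=0.05, seed=11)
        results = analyze_plate(plate)
        tnfa = results[(results["analyte"] == "TNFa") & (results["concentration"] == 1.0)]
        assert tnfa["significant"].all()
        assert tnfa["percent_of_control"].iloc[0] == pytest.approx(40.0, rel=0.15)
        points = compound_assay_points(results)
        tnfa_pts = points[(points["treatment"] == "drugA") & (points["analyte"] == "TNFa")]
        # strongest significant concentration (about 40% of control) sets
        # the band: within (30, 50] earns 3 points
        assert tnfa_pts["points"].iloc[0] == 3
        # a significant 140% viability falls in the (115, 150] band
        via = points[points["analyte"] == "viability"]
        assert via["points"].iloc[0] == 1

    def test_missing_control_wells_rejected(self):
        plate = simulate_coculture_plate({("d", 1.0, "TNFa"): 50.0}, cv=0.1, seed=1)
        plate = plate[plate["treatment"] != "control"]
        with pytest.raises(ValueError, match="control"):
            analyze_plate(plate)
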