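"""Exact contingency tests, lesion severity and the decision procedure."""

import math
from fractions import Fraction
from itertools import product

import numpy as np
import pytest
from scipy import stats

from adnet.cohort import (
    CohortTable,
    LesionRecord,
    SegmentProfile,
    fisher_2x2,
    fisher_rx2,
    fisher_rx2_counts,
    group_compare,
    incidence,
    lesion_length,
    summarize,
)

# Published cohort counts the exact tests are exercised against: a preventive
# arm (vehicle / gefitinib / rapamycin) and a therapeutic arm (day-7 baseline,
# day-14 vehicle, day-14 rapamycin).
PREVENTIVE = CohortTable(
    ("BA+DMSO", "BA+Gef", "BA+Rapa"), (11, 9, 2), (3, 0, 6)
)
THERAPEUTIC = CohortTable(
    ("day7", "day14_vehicle", "day14_rapa"), (13, 10, 9), (14, 0, 4)
)


def fisher_oracle(a, b, c, d):
    """Independent enumeration oracle via exact factorial Fractions."""
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    n = r1 + r2

    def prob(a_):
        b_, c_ = r1 - a_, c1 - a_
        d_ = r2 - c_
        if min(b_, c_, d_) < 0:
            return None
        f = math.factorial
        return Fraction(
            f(r1) * f(r2) * f(c1) * f(c2),
            f(n) * f(a_) * f(b_) * f(c_) * f(d_),
        )

    observed = prob(a)
    total = Fraction(0)
    for a_ in range(0, min(r1, c1) + 1):
        p = prob(a_)
        if p is not None and p <= observed:
            total += p
    return float(total)


class TestIncidence:
    def test_preventive_percentages(self):
        assert list(incidence(PREVENTIVE).values()) == [78.6, 100.0, 25.0]

    def test_therapeutic_percentages(self):
        assert list(incidence(THERAPEUTIC).values()) == [48.1, 100.0, 69.2]

    def test_zero_positive_group(self):
        t = CohortTable(("a",), (0,), (7,))
        assert incidence(t) == {"a": 0.0}

    def test_zero_total_rejected(self):
        t = CohortTable(("a",), (0,), (0,))
        with pytest.raises(ValueError):
            incidence(t)


class TestFisher2x2:
    def test_balanced_table_gives_one(self):
        assert fisher_2x2(5, 5, 5, 5) == 1.0

    def test_vehicle_vs_rapamycin_columns(self):
        # 11/3 AD+ vs 2/6 AD+: p ~ 0.026 by enumeration over a in {5..13}
        assert fisher_2x2(11, 3, 2, 6) == pytest.approx(0.0260, abs=5e-4)
        assert fisher_2x2(11, 3, 2, 6) == pytest.approx(
            fisher_oracle(11, 3, 2, 6), abs=1e-12
        )

    def test_exhaustive_oracle_equivalence_small_n(self):
        """Every 2x2 table with N <= 14 matches the Fraction oracle to 1e-12
        (the N <= 40 sweep runs in the acceptance suite)."""
        for a, b, c, d in product(range(8), repeat=4):
            if 0 < a + b + c + d <= 14 and (a + b) > 0 and (c + d) > 0:
                assert fisher_2x2(a, b, c, d) == pytest.approx(
                    fisher_oracle(a, b, c, d), abs=1e-12
                )

    def test_matches_scipy_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 15, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + b + c + d) == 0:
                continue
            ours = fisher_2x2(int(a), int(b), int(c), int(d))
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            # scipy applies a 1e-7 relative tie relief; stay just above it
            assert ours == pytest.approx(ref, rel=3e-7, abs=1e-12)


class TestFisherRx2:
    def test_full_preventive_table_significant(self):
        assert fisher_rx2(PREVENTIVE) < 0.01

    def test_modal_symmetric_table_gives_one(self):
        assert fisher_rx2_counts([(1, 1), (1, 1), (1, 1)]) == 1.0

    def test_reduces_to_2x2(self):
        for a, b, c, d in [(11, 3, 2, 6), (4, 0, 1, 5), (2, 2, 3, 3)]:
            assert fisher_rx2_counts([(a, b), (c, d)]) == pytest.approx(
                fisher_2x2(a, b, c, d), abs=1e-12
            )

    def test_group_permutation_invariance(self):
        rows = [(11, 3), (9, 0), (2, 6)]
        p0 = fisher_rx2_counts(rows)
        assert fisher_rx2_counts(rows[::-1]) == pytest.approx(p0, abs=1e-12)
        assert fisher_rx2_counts([rows[1], rows[0], rows[2]]) == pytest.approx(
            p0, abs=1e-12
        )

    def test_p_in_unit_interval(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            rows = [(int(a), int(b)) for a, b in rng.integers(0, 8, size=(3, 2))]
            if any(sum(r) == 0 for r in rows):
                continue
            p = fisher_rx2_counts(rows)
            assert 0.0 < p <= 1.0

    def test_oversized_table_rejected_not_approximated(self):
        with pytest.raises(ValueError, match="too large"):
            fisher_rx2_counts([(150, 0), (0, 150)])


def profile(diam_factors, ref=1.0, spacing=1.0, name="seg"):
    return SegmentProfile(
        name=name,
        reference_diameter=ref,
        spacing=spacing,
        diameters=np.asarray(diam_factors, dtype=float) * ref,
    )


class TestLesionLength:
    def test_uniform_reference_diameter_gives_zero(self):
        rec = LesionRecord("m1", "g", [profile([1.0] * 20)])
        assert lesion_length(rec)["total"] == 0.0

    def test_inclusive_boundary_at_exactly_1_5(self):
        # 10 mm run exactly at 1.5x reference counts in full
        rec = LesionRecord(
            "m1", "g", [profile([1.0] * 5 + [1.5] * 10 + [1.0] * 5)]
        )
        assert lesion_length(rec)["total"] == pytest.approx(10.0)

    def test_only_qualifying_run_counts(self):
        # 4 mm at 1.6x qualifies, 3 mm at 1.2x does not
        rec = LesionRecord(
            "m1", "g",
            [profile([1.0] * 3 + [1.6] * 4 + [1.0] * 2 + [1.2] * 3 + [1.0] * 3)],
        )
        assert lesion_length(rec)["total"] == pytest.approx(4.0)

    def test_per_segment_and_total(self):
        rec = LesionRecord(
            "m1", "g",
            [
                profile([1.6] * 4 + [1.0] * 6, name="arch"),
                profile([1.0] * 10, name="thoracic"),
            ],
        )
        out = lesion_length(rec)
        assert out["arch"] == pytest.approx(4.0)
        assert out["thoracic"] == 0.0
        assert out["total"] == pytest.approx(4.0)

    def test_monotone_under_dilation(self):
        rng = np.random.default_rng(1)
        factors = rng.uniform(0.9, 1.7, size=40)
        rec = LesionRecord("m1", "g", [profile(factors)])
        base = lesion_length(rec)["total"]
        for i in range(0, 40, 7):
            bumped = factors.copy()
            bumped[i] *= 1.3
            rec2 = LesionRecord("m1", "g", [profile(bumped)])
            assert lesion_length(rec2)["total"] >= base


class TestGroupCompare:
    def test_normal_equal_groups_take_parametric_path(self):
        rng = np.random.default_rng(100)
        groups = [rng.normal(5, 1, 40) for _ in range(3)]
        rep = group_compare(groups)
        assert rep.path == "parametric"
        assert rep.omnibus_p > 0.05
        assert not rep.pairwise.significant.any()

    def test_heavy_tailed_group_routes_nonparametric(self):
        rng = np.random.default_rng(11)
        groups = [rng.normal(0, 1, 50), rng.normal(0, 1, 50), rng.standard_cauchy(50)]
        rep = group_compare(groups)
        assert rep.path == "nonparametric"

    def test_small_group_routes_nonparametric_with_note(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(0, 1, 5), rng.normal(0, 1, 30)]
        rep = group_compare(groups)
        assert rep.path == "nonparametric"
        assert any("n = 5" in note for note in rep.notes)

    def test_large_shift_detected_in_pairwise(self):
        rng = np.random.default_rng(13)
        groups = [rng.normal(0, 1, 20), rng.normal(5, 1, 20)]
        rep = group_compare(groups)
        assert rep.pairwise.p_adjusted.min() < 1e-3
        assert rep.pairwise.significant.any()

    def test_dunn_matches_kruskal_direction(self):
        rng = np.random.default_rng(14)
        groups = [np.round(rng.normal(0, 1, 30), 1),
                  np.round(rng.normal(2, 1, 30), 1),
                  np.round(rng.standard_cauchy(30), 1)]
        rep = group_compare(groups)
        assert rep.path == "nonparametric"
        row = rep.pairwise.iloc[0]
        assert row.group_a == "group1" and row.group_b == "group2"
        assert row.p_adjusted < 0.05

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 3"):
            group_compare([[1.0, 2.0], [1.0, 2.0, 3.0]])


class TestSummarize:
    def test_hand_computed_sem(self):
        mean, sem, n = summarize([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / math.sqrt(3))
        assert n == 3

    def test_constant_vector_zero_sem(self):
        _, sem, _ = summarize([4.0, 4.0, 4.0, 4.0])
        assert sem == 0.0

    def test_scaling_linearity(self):
        vals = [1.0, 3.0, 7.0, 2.0]
        m1, s1, _ = summarize(vals)
        m2, s2, _ = summarize([v * 3 for v in vals])
        assert m2 == pytest.approx(3 * m1)
        assert s2 == pytest.approx(3 * s1)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            summarize([1.0])
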