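"""Presence/absence analysis: occupancy classes, Venn partitions, count RSD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from evrepro import (
    AbundanceTable,
    Flavor,
    GroupingScheme,
    PresenceMatrix,
    count_rsd,
    occupancy_profile,
    presence_matrix,
    venn_partition,
)
from evrepro.qualitative import Interpretation


def make_table(values, flavor=Flavor.LFQ):
    values = np.asarray(values, dtype=float)
    return AbundanceTable(
        protein_ids=tuple(f"P{i}" for i in range(values.shape[0])),
        replicate_ids=tuple(f"R{j + 1}" for j in range(values.shape[1])),
        values=values,
        flavor=flavor,
    )


def make_presence(mat):
    mat = np.asarray(mat, dtype=bool)
    return PresenceMatrix(
        protein_ids=tuple(f"P{i}" for i in range(mat.shape[0])),
        replicate_ids=tuple(f"R{j + 1}" for j in range(mat.shape[1])),
        present=mat,
    )


def grouping33():
    return GroupingScheme(
        scheme="TR", groups=(("R1", "R2", "R3"), ("R4", "R5", "R6"), ("R7", "R8", "R9"))
    )


class TestPresenceMatrix:
    def test_zero_absent_positive_present(self):
        t = make_table([[0.0, 1.0], [2.0, 0.0]])
        p = presence_matrix(t)
        assert p.present.tolist() == [[False, True], [True, False]]
        assert p.threshold == 0.0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            presence_matrix(make_table([[1.0, 2.0]]), threshold=-1)

    def test_raising_threshold_is_monotone(self):
        rng = np.random.default_rng(0)
        t = make_table(rng.uniform(0, 10, (30, 5)))
        low = presence_matrix(t, threshold=1.0).present
        high = presence_matrix(t, threshold=5.0).present
        assert not (high & ~low).any()

    def test_threshold_agrees_with_brute_force(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 10, (50, 9))
        vals[rng.random((50, 9)) < 0.3] = 0.0
        t = make_table(vals)
        thr = float(np.median(vals[vals > 0]))
        p = presence_matrix(t, threshold=thr)
        for i in range(50):
            for j in range(9):
                assert p.present[i, j] == (vals[i, j] > thr)


class TestOccupancyProfile:
    def test_all_true_matrix_is_saturated(self):
        occ = occupancy_profile(make_presence(np.ones((7, 9))))
        assert (occ.n_total, occ.n_all, occ.n_intermediate, occ.n_singleton) == (7, 7, 0, 0)

    def test_hand_built_classes(self):
        mat = np.zeros((4, 9), dtype=bool)
        mat[0] = True  # all 9
        mat[1, :4] = True  # intermediate
        mat[2, 3] = True  # singleton
        # row 3 never detected -> excluded
        occ = occupancy_profile(make_presence(mat))
        assert (occ.n_total, occ.n_all, occ.n_intermediate, occ.n_singleton) == (3, 1, 1, 1)
        assert occ.occupancy["P3"] == 0

    @given(
        arrays(np.bool_, st.tuples(st.integers(1, 20), st.integers(2, 9)))
    )
    def test_conservation_property(self, mat):
        occ = occupancy_profile(make_presence(mat))
        assert occ.n_all + occ.n_intermediate + occ.n_singleton == occ.n_total
        assert occ.n_total == int((mat.sum(axis=1) >= 1).sum())

    def test_matches_exhaustive_enumeration_small(self):
        rng = np.random.default_rng(3)
        mat = rng.random((10, 4)) < 0.5
        occ = occupancy_profile(make_presence(mat))
        counts = [int(row.sum()) for row in mat]
        assert occ.n_all == sum(c == 4 for c in counts)
        assert occ.n_singleton == sum(c == 1 for c in counts)
        assert occ.n_intermediate == sum(1 < c < 4 for c in counts)


class TestVennPartition:
    def test_identical_columns_all_common(self):
        mat = np.zeros((6, 9), dtype=bool)
        mat[:4, :3] = True
        v = venn_partition(make_presence(mat), grouping33())
        t0 = v.per_triad[0]
        assert (t0["unique_to_one"], t0["shared_by_exactly_two"], t0["common_to_three"]) == (0, 0, 4)

    def test_disjoint_single_member_columns(self):
        mat = np.zeros((5, 9), dtype=bool)
        mat[0, 0] = True  # only R1
        mat[1, 1] = True  # only R2; R3 empty
        v = venn_partition(make_presence(mat), grouping33())
        t0 = v.per_triad[0]
        assert (t0["unique_to_one"], t0["shared_by_exactly_two"], t0["common_to_three"]) == (2, 0, 0)

    def test_brute_force_region_enumeration(self):
        rng = np.random.default_rng(11)
        mat = rng.random((40, 9)) < 0.5
        presence = make_presence(mat)
        v = venn_partition(presence, grouping33())
        for triad, cols in zip(v.per_triad, [(0, 1, 2), (3, 4, 5), (6, 7, 8)]):
            region = {1: 0, 2: 0, 3: 0}
            for row in mat:
                k = int(row[list(cols)].sum())
                if k:
                    region[k] += 1
            assert triad["unique_to_one"] == region[1]
            assert triad["shared_by_exactly_two"] == region[2]
            assert triad["common_to_three"] == region[3]
            assert sum(region.values()) == int(mat[:, list(cols)].any(axis=1).sum())

    def test_percentages_relative_to_total(self):
        mat = np.zeros((10, 9), dtype=bool)
        mat[:8, 0] = True
        v = venn_partition(make_presence(mat), grouping33())
        assert v.n_total == 8
        assert v.percentages["unique_to_one"] == pytest.approx(100.0 * (8 / 3) / 8)

    def test_non_triad_group_rejected(self):
        mat = np.ones((3, 4), dtype=bool)
        g = GroupingScheme(scheme="TR", groups=(("R1", "R2"), ("R3", "R4")))
        with pytest.raises(ValueError, match="triads"):
            venn_partition(make_presence(mat), g)


class TestCountRSD:
    def test_zero_variance_counts(self):
        mat = np.zeros((100, 9), dtype=bool)
        mat[:50] = True  # every replicate sees exactly 50
        p = make_presence(mat)
        for interp in Interpretation:
            assert count_rsd(p, grouping33(), interp).scheme_rsd_percent == 0.0

    def test_closed_form_80_100_120(self):
        # counts 80/100/120 in one triad: SD 20, mean 100 -> RSD 20%
        mat = np.zeros((120, 3), dtype=bool)
        mat[:80, 0] = True
        mat[:100, 1] = True
        mat[:120, 2] = True
        g = GroupingScheme(scheme="TR", groups=(("R1", "R2", "R3"),))
        r = count_rsd(make_presence(mat), g)
        assert r.per_group[0].rsd_percent == pytest.approx(20.0)
        assert r.per_group[0].sample_sd == pytest.approx(20.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(5)
        mat = rng.random((60, 9)) < 0.6
        p = make_presence(mat)
        g1 = grouping33()
        g2 = GroupingScheme(  # members shuffled within groups, groups reordered
            scheme="TR",
            groups=(("R9", "R7", "R8"), ("R3", "R1", "R2"), ("R6", "R5", "R4")),
        )
        for interp in Interpretation:
            assert count_rsd(p, g1, interp).scheme_rsd_percent == pytest.approx(
                count_rsd(p, g2, interp).scheme_rsd_percent
            )

    def test_scale_irrelevance(self):
        rng = np.random.default_rng(6)
        vals = rng.lognormal(3, 1, (40, 9))
        vals[rng.random((40, 9)) < 0.4] = 0.0
        a = presence_matrix(make_table(vals))
        b = presence_matrix(make_table(vals * 1e6))
        assert count_rsd(a, grouping33()).scheme_rsd_percent == pytest.approx(
            count_rsd(b, grouping33()).scheme_rsd_percent
        )

    def test_between_group_sums_interpretation(self):
        # triad counts sum to 300/303/306 -> RSD over the three totals
        mat = np.zeros((110, 9), dtype=bool)
        counts = [99, 100, 101, 100, 101, 102, 101, 102, 103]
        for j, c in enumerate(counts):
            mat[:c, j] = True
        r = count_rsd(make_presence(mat), grouping33(), "between_group_sums")
        totals = np.array([300.0, 303.0, 306.0])
        expected = 100 * totals.std(ddof=1) / totals.mean()
        assert r.scheme_rsd_percent == pytest.approx(expected)

    def test_zero_mean_group_errors(self):
        mat = np.zeros((5, 9), dtype=bool)
        mat[:, 3:] = True  # first triad sees nothing
        with pytest.raises(ValueError, match="zero mean"):
            count_rsd(make_presence(mat), grouping33())

    def test_singleton_group_errors(self):
        mat = np.ones((5, 2), dtype=bool)
        g = GroupingScheme(scheme="TR", groups=(("R1",), ("R2",)))
        with pytest.raises(ValueError, match="fewer than 2"):
            count_rsd(make_presence(mat), g)
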