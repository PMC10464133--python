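"""Point-estimation tests: table building, weights, Cohen's and weighted kappa."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kappakit import (
    ContingencyTable,
    PairedRatings,
    RatingScale,
    ScaleError,
    TableError,
    UndefinedKappaError,
    WeightMatrix,
    brute_force_kappa,
    build_table,
    cohen_kappa,
    identity_weights,
    power_weights,
    weighted_kappa,
)
from kappakit.datasets import recist_comparisons, recist_table

from .conftest import TABLE1_EXPECTED, random_ratings


class TestRatingScale:
    def test_rejects_duplicate_and_short_scales(self):
        with pytest.raises(ScaleError):
            RatingScale(("a", "a", "b"))
        with pytest.raises(ScaleError):
            RatingScale(("only",))

    def test_index_and_membership(self, recist_scale):
        assert recist_scale.index("SD") == 1
        assert "PD" in recist_scale
        with pytest.raises(ScaleError):
            recist_scale.index("CR")


class TestBuildTable:
    def test_tally_matches_published_counts(self, recist_scale, testing_r1_counts):
        # expand the known matrix to subject-level pairs and re-tally
        sids, ra, rb = [], [], []
        for i, row_lab in enumerate(recist_scale.labels):
            for j, col_lab in enumerate(recist_scale.labels):
                for _ in range(testing_r1_counts[i, j]):
                    sids.append(len(sids))
                    ra.append(row_lab)
                    rb.append(col_lab)
        table = build_table(PairedRatings(sids, ra, rb), recist_scale)
        assert np.array_equal(table.counts, testing_r1_counts)
        assert table.n_subjects == 31

    def test_single_subject(self, recist_scale):
        table = build_table(PairedRatings((0,), ("PR",), ("PR",)), recist_scale)
        assert table.counts[0, 0] == 1
        assert table.counts.sum() == 1

    def test_order_invariance(self, recist_scale):
        rng = np.random.default_rng(7)
        sids, ra, rb, _ = random_ratings(rng, 40, 3)
        ra = ["PR SD PD".split()[int(x[1])] for x in ra]
        rb = ["PR SD PD".split()[int(x[1])] for x in rb]
        perm = rng.permutation(40)
        t1 = build_table(PairedRatings(sids, ra, rb), recist_scale)
        t2 = build_table(
            PairedRatings(
                [sids[i] for i in perm], [ra[i] for i in perm], [rb[i] for i in perm]
            ),
            recist_scale,
        )
        assert np.array_equal(t1.counts, t2.counts)

    def test_unknown_label_names_subject(self, recist_scale):
        with pytest.raises(ScaleError, match=r"subject 's2'.*'CR'"):
            build_table(
                PairedRatings(("s1", "s2"), ("PR", "CR"), ("SD", "PD")), recist_scale
            )

    def test_empty_input_rejected(self, recist_scale):
        with pytest.raises(TableError):
            build_table(PairedRatings((), (), ()), recist_scale)

    def test_unused_category_keeps_zero_margin(self):
        scale = RatingScale(("a", "b", "c"))
        table = build_table(PairedRatings((0, 1), ("a", "b"), ("a", "b")), scale)
        assert table.counts[2].sum() == 0 and table.counts[:, 2].sum() == 0
        assert table.counts.shape == (3, 3)


class TestPowerWeights:
    def test_linear_3x3(self, recist_scale):
        w = power_weights(recist_scale, 1)
        assert np.allclose(w.weights, [[1, 0.5, 0], [0.5, 1, 0.5], [0, 0.5, 1]])

    def test_quadratic_3x3_off_by_one(self, recist_scale):
        w = power_weights(recist_scale, 2)
        assert w.weights[0, 1] == pytest.approx(0.75)
        assert w.weights[0, 2] == 0.0

    @pytest.mark.parametrize("m", [1, 2, 7, 3.5])
    def test_two_categories_collapse_to_identity(self, m):
        w = power_weights(RatingScale(("no", "yes")), m)
        assert np.array_equal(w.weights, np.eye(2))

    def test_nominal_scale_rejected_without_override(self):
        nominal = RatingScale(("blue", "green", "brown"), is_ordinal=False)
        with pytest.raises(ScaleError):
            power_weights(nominal, 1)
        assert power_weights(nominal, 1, force=True).weights[0, 1] == 0.5

    def test_exponent_below_one_rejected(self, recist_scale):
        with pytest.raises(Exception):
            power_weights(recist_scale, 0.5)

    def test_custom_weights_validated(self):
        with pytest.raises(Exception):
            WeightMatrix(np.array([[1.0, 0.3], [0.6, 1.0]]))  # asymmetric
        with pytest.raises(Exception):
            WeightMatrix(np.array([[0.9, 0.3], [0.3, 1.0]]))  # diagonal != 1


class TestKappaPoints:
    @pytest.mark.parametrize("dataset,rater", sorted(TABLE1_EXPECTED))
    @pytest.mark.parametrize("stat", ["cohen", "linear", "quadratic"])
    def test_published_reanalysis_points(self, dataset, rater, stat):
        """All 18 published point estimates reproduce at 2 decimals."""
        table = recist_table(dataset, rater)
        if stat == "cohen":
            est = cohen_kappa(table)
        else:
            m = 1 if stat == "linear" else 2
            est = weighted_kappa(table, power_weights(table.scale, m))
        expected = TABLE1_EXPECTED[(dataset, rater)][stat][0]
        assert round(est.point + 1e-12, 2) == pytest.approx(expected)

    def test_perfect_agreement(self):
        table = ContingencyTable(np.diag([5, 7]), RatingScale(("a", "b")))
        assert cohen_kappa(table).point == pytest.approx(1.0)

    def test_exact_independence(self):
        table = ContingencyTable(np.full((2, 2), 5), RatingScale(("a", "b")))
        assert cohen_kappa(table).point == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_single_cell_undefined(self):
        table = ContingencyTable(np.diag([9, 0]), RatingScale(("a", "b")))
        with pytest.raises(UndefinedKappaError):
            cohen_kappa(table)

    def test_dimension_mismatch_rejected(self, recist_scale):
        table = recist_table("testing", "R1")
        with pytest.raises(TableError):
            weighted_kappa(table, identity_weights(4))

    def test_estimate_components_consistent(self):
        est = cohen_kappa(recist_table("validation", "R1"))
        recomputed = (est.observed_agreement - est.expected_agreement) / (
            1 - est.expected_agreement
        )
        assert est.point == pytest.approx(recomputed, abs=1e-15)


class TestInvariants:
    @pytest.mark.parametrize("m", [None, 1, 2, 3.0])
    def test_transpose_symmetry(self, m):
        for comp in recist_comparisons():
            w = None if m is None else power_weights(comp.table.scale, m)
            k1 = (cohen_kappa(comp.table) if w is None else weighted_kappa(comp.table, w)).point
            t2 = comp.table.transpose()
            k2 = (cohen_kappa(t2) if w is None else weighted_kappa(t2, w)).point
            assert k1 == pytest.approx(k2, abs=1e-12)

    def test_identity_weights_equal_cohen(self):
        for comp in recist_comparisons():
            kc = cohen_kappa(comp.table).point
            kw = weighted_kappa(comp.table, identity_weights(3)).point
            assert kc == pytest.approx(kw, abs=1e-12)

    def test_2x2_power_weights_equal_cohen(self):
        rng = np.random.default_rng(11)
        scale = RatingScale(("no", "yes"))
        for _ in range(20):
            counts = rng.integers(0, 20, size=(2, 2))
            if counts.sum() == 0 or counts.diagonal().sum() == counts.sum():
                continue
            table = ContingencyTable(counts, scale)
            kc = cohen_kappa(table).point
            for m in (1, 2, 5.5):
                kw = weighted_kappa(table, power_weights(scale, m)).point
                assert kw == pytest.approx(kc, abs=1e-12)

    def test_cohen_invariant_under_any_label_permutation(self):
        rng = np.random.default_rng(3)
        table = recist_table("testing", "auto")
        k0 = cohen_kappa(table).point
        for _ in range(5):
            perm = rng.permutation(3)
            assert cohen_kappa(table.permute_categories(perm)).point == pytest.approx(
                k0, abs=1e-12
            )

    def test_power_weighted_invariant_under_order_reversal_only(self):
        table = recist_table("testing", "R1")
        w = power_weights(table.scale, 2)
        k0 = weighted_kappa(table, w).point
        reversed_table = table.permute_categories([2, 1, 0])
        k_rev = weighted_kappa(
            reversed_table, power_weights(reversed_table.scale, 2)
        ).point
        assert k_rev == pytest.approx(k0, abs=1e-12)
        swapped = table.permute_categories([1, 0, 2])  # not an order reversal
        k_swap = weighted_kappa(swapped, power_weights(swapped.scale, 2)).point
        assert abs(k_swap - k0) > 1e-6

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 30), min_size=3, max_size=3),
            min_size=3,
            max_size=3,
        ),
        m=st.sampled_from([1.0, 2.0, 4.0]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_kappa_never_exceeds_one(self, counts, m):
        counts = np.array(counts)
        if counts.sum() == 0:
            return
        scale = RatingScale(("a", "b", "c"))
        table = ContingencyTable(counts, scale)
        w = power_weights(scale, m)
        try:
            k = weighted_kappa(table, w).point
        except UndefinedKappaError:
            return
        assert k <= 1.0 + 1e-12
        # kappa = 1 exactly when no disagreement mass sits on weight < 1 cells
        off_mass = (counts * (w.weights < 1)).sum()
        assert (abs(k - 1.0) < 1e-12) == (off_mass == 0)


class TestBruteForceOracle:
    def test_matrix_kappa_matches_per_subject_tally(self):
        """Matrix algebra equals the direct per-subject-pair tally exactly."""
        rng = np.random.default_rng(2024)
        checked = 0
        while checked < 200:
            n_cat = int(rng.integers(2, 5))
            n_sub = int(rng.integers(2, 51))
            sids, ra, rb, labels = random_ratings(rng, n_sub, n_cat)
            scale = RatingScale(tuple(labels))
            table = build_table(PairedRatings(sids, ra, rb), scale)
            m = float(rng.choice([1, 2, 3]))
            w = power_weights(scale, m)
            try:
                k_matrix = weighted_kappa(table, w).point
            except UndefinedKappaError:
                with pytest.raises(UndefinedKappaError):
                    brute_force_kappa(ra, rb, scale, w)
                continue
            k_brute = brute_force_kappa(ra, rb, scale, w)
            assert k_matrix == pytest.approx(k_brute, abs=1e-12)
            checked += 1


class TestAgainstStatsmodels:
    """Independent cross-check against statsmodels' kappa implementation."""

    @pytest.mark.parametrize("dataset,rater", sorted(TABLE1_EXPECTED))
    def test_points_match_statsmodels(self, dataset, rater):
        sm_inter = pytest.importorskip("statsmodels.stats.inter_rater")
        table = recist_table(dataset, rater)
        assert cohen_kappa(table).point == pytest.approx(
            sm_inter.cohens_kappa(table.counts).kappa, abs=1e-12
        )
        for m, wt in ((1, "linear"), (2, "quadratic")):
            ours = weighted_kappa(table, power_weights(table.scale, m)).point
            theirs = sm_inter.cohens_kappa(table.counts, wt=wt).kappa
            assert ours == pytest.approx(theirs, abs=1e-12)
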