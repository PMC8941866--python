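import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trophnet as tn
from trophnet.errors import DegenerateInputError, InvalidInputError, SchemaError

from nodf_oracle import nodf_oracle


class TestCallGrowth:
    @pytest.mark.parametrize("readings, expected", [
        ([0.10, 0.12, 0.11], 1),            # clear growth
        ([0.05, 0.05, 0.05], 0),            # mean equals threshold: strict >
        ([0.02, 0.09, 0.04], 0),            # mean 0.05 exactly, fails strict >
        ([0.0], 0),
        ([0.051], 1),
    ])
    def test_threshold_call(self, readings, expected):
        assert tn.call_growth(readings) == expected

    def test_custom_threshold(self):
        assert tn.call_growth([0.2, 0.2], threshold=0.3) == 0

    @pytest.mark.parametrize("readings, threshold", [
        ([], 0.05), ([0.1], -0.01), ([np.nan], 0.05), ([-0.1], 0.05),
    ])
    def test_invalid_inputs(self, readings, threshold):
        with pytest.raises(InvalidInputError):
            tn.call_growth(readings, threshold)


class TestProfileMatrix:
    @staticmethod
    def _long(cells):
        return pd.DataFrame([{"strain_id": s, "resource_id": r, "od600": v}
                             for (s, r), vals in cells.items() for v in vals])

    def test_all_growth(self):
        cells = {(s, r): [0.2] for s in ("a", "b") for r in ("r1", "r2", "r3")}
        mat = tn.build_profile_matrix(self._long(cells))
        assert mat.shape == (2, 3) and (mat.to_numpy() == 1).all()

    def test_single_cell_zero(self):
        mat = tn.build_profile_matrix(self._long({("a", "r1"): [0.0]}))
        assert mat.to_numpy().tolist() == [[0]]

    def test_missing_cell_named_in_error(self):
        cells = {("a", "r1"): [0.2], ("a", "r2"): [0.2], ("b", "r1"): [0.2]}
        with pytest.raises(SchemaError, match="strain='b'.*resource='r2'"):
            tn.build_profile_matrix(self._long(cells))

    def test_duplicate_strain_ids_rejected(self):
        with pytest.raises(SchemaError, match="duplicate"):
            tn.build_profile_matrix(self._long({("a", "r1"): [0.2]}),
                                    strain_ids=["a", "a"], resource_ids=["r1"])

    def test_matches_generator_truth(self):
        config = tn.GeneratorConfig(
            cell_counts={("CK", "macroaggregates"): 3})
        community = tn.generate_community(config, 11)
        mat = tn.build_profile_matrix(community.resource_assays,
                                      strain_ids=list(community.metadata["strain_id"]))
        assert np.array_equal(mat.to_numpy(), community.truth_profiles.to_numpy())


class TestBreadthClasses:
    @pytest.mark.parametrize("n_used, label", [
        (11, "specialist"),      # 23.9% < 25%
        (24, "generalist"),      # 52.2% > 50%
        (15, "intermediate"),    # 32.6%
        (12, "intermediate"),    # 26.1%: boundary band is closed
        (23, "intermediate"),    # exactly 50%
        (0, "specialist"),
        (46, "generalist"),
    ])
    def test_class_labels(self, n_used, label):
        row = [1] * n_used + [0] * (46 - n_used)
        res = tn.classify_trophic_breadth(row, "s1")
        assert res.class_label == label
        assert res.n_used == n_used

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            tn.classify_trophic_breadth([1, 0], n_resources=3)

    def test_labels_partition_strains(self, small_run):
        _, community, _ = small_run
        table = tn.breadth_table(community.truth_profiles)
        assert len(table) == len(community.metadata)
        assert set(table["class_label"]) <= {"specialist", "intermediate", "generalist"}


class TestNicheOverlap:
    def test_spec_worked_example(self):
        a = [1, 1, 1] + [0] * 43
        b = [0, 1, 1, 1] + [0] * 42
        jac = tn.niche_overlap(a, b, "jaccard")
        tot = tn.niche_overlap(a, b, "total")
        assert jac.shared_count == 2 and jac.union_count == 4
        assert jac.niche_overlap_pct == pytest.approx(50.0)
        assert tot.niche_overlap_pct == pytest.approx(100.0 * 2 / 46)

    def test_identical_and_disjoint(self):
        row = [1, 0, 1, 0]
        assert tn.niche_overlap(row, row).niche_overlap_pct == 100.0
        assert tn.niche_overlap([1, 1, 0, 0], [0, 0, 1, 1]).niche_overlap_pct == 0.0
        assert tn.niche_overlap([1, 1, 0, 0], [0, 0, 1, 1], "total").niche_overlap_pct == 0.0

    def test_both_empty_is_zero_under_jaccard(self):
        assert tn.niche_overlap([0, 0], [0, 0]).niche_overlap_pct == 0.0

    def test_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            tn.niche_overlap([1, 0], [1, 0, 1])

    @given(st.lists(st.booleans(), min_size=1, max_size=30),
           st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_identity(self, row_a, data):
        row_b = data.draw(st.lists(st.booleans(), min_size=len(row_a),
                                   max_size=len(row_a)))
        ab = tn.niche_overlap(row_a, row_b)
        ba = tn.niche_overlap(row_b, row_a)
        assert ab.niche_overlap_pct == pytest.approx(ba.niche_overlap_pct)
        assert 0 <= ab.niche_overlap_pct <= 100
        if ab.niche_overlap_pct == 100.0:
            assert row_a == row_b and any(row_a)

    def test_table_matches_pairwise_calls(self, small_run):
        _, community, _ = small_run
        profile = community.truth_profiles.iloc[:8]
        table = tn.pairwise_overlap_table(profile)
        for row in table.itertuples(index=False):
            direct = tn.niche_overlap(profile.loc[row.strain_a],
                                      profile.loc[row.strain_b])
            assert row.overlap_jaccard_pct == pytest.approx(direct.niche_overlap_pct)
            assert row.shared_count == direct.shared_count


class TestConnectance:
    def test_single_species_identity(self):
        profile = pd.DataFrame([np.ones(46, dtype=int)], index=["s1"])
        res = tn.connectance(profile)
        assert (res.S, res.L, res.connectance) == (1, 46, 46.0)

    def test_two_species_link_count(self):
        rows = [[1, 1, 1] + [0] * 5, [1, 1, 1, 1, 1] + [0] * 3]
        res = tn.connectance(pd.DataFrame(rows, index=["a", "b"]))
        assert (res.S, res.L, res.connectance) == (2, 8, 2.0)

    def test_all_zero_rows(self):
        res = tn.connectance(pd.DataFrame(np.zeros((3, 4), int)))
        assert res.connectance == 0.0

    def test_empty_community_rejected(self):
        with pytest.raises(InvalidInputError):
            tn.connectance(pd.DataFrame(columns=range(4)))

    def test_permutation_invariance_and_monotonicity(self, small_run):
        _, community, _ = small_run
        profile = community.truth_profiles.iloc[:6].copy()
        shuffled = profile.sample(frac=1.0, random_state=3)
        assert tn.connectance(profile).connectance == \
            tn.connectance(shuffled).connectance
        zero_cells = np.argwhere(profile.to_numpy() == 0)
        i, j = zero_cells[0]
        bumped = profile.copy()
        bumped.iloc[i, j] = 1
        assert tn.connectance(bumped).L == tn.connectance(profile).L + 1
        assert tn.connectance(bumped).connectance > tn.connectance(profile).connectance


class TestNodf:
    def test_perfectly_nested(self):
        m = [[1, 1, 1], [1, 1, 0], [1, 0, 0]]
        assert tn.nestedness_nodf(np.array(m)) == pytest.approx(100.0)

    def test_empty_column_counts_as_zero_pairs(self):
        # matches vegan::nestednodf: the empty 4th column stays in the
        # denominator, pulling the score below the 3-column perfect nest
        m = [[1, 1, 1, 0], [1, 1, 0, 0], [1, 0, 0, 0]]
        assert tn.nestedness_nodf(np.array(m)) == pytest.approx(200.0 / 3)

    def test_identical_rows_all_ties(self):
        m = np.array([[1, 1, 0], [1, 1, 0], [1, 1, 0]])
        assert tn.nestedness_nodf(m) == pytest.approx(0.0)

    def test_three_by_three_hand_enumeration(self):
        # only the (r1, r3) row pair and (c2, c3) column pair contribute
        m = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
        assert tn.nestedness_nodf(m) == pytest.approx(200.0 / 6)

    @pytest.mark.parametrize("matrix, expected", [
        # frozen from R vegan::nestednodf (order=TRUE) on the same matrices
        ([[1, 1, 1, 1, 0], [1, 1, 1, 0, 0], [1, 1, 0, 0, 0], [1, 0, 1, 0, 0]], 62.5),
        ([[1, 1, 1, 0, 0, 1, 0, 0], [1, 0, 0, 1, 1, 1, 0, 1],
          [0, 1, 0, 1, 0, 0, 1, 0], [1, 1, 1, 0, 1, 1, 1, 1],
          [1, 0, 1, 1, 0, 0, 0, 1], [1, 1, 0, 1, 1, 1, 0, 1]], 57.2868217054),
    ])
    def test_matches_vegan_reference(self, matrix, expected):
        assert tn.nestedness_nodf(np.array(matrix)) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("matrix", [
        np.zeros((3, 3), int),
        np.array([[1, 1, 1], [0, 0, 0], [0, 0, 0]]),   # one non-empty row
        np.array([[1, 0, 0], [1, 0, 0], [1, 0, 0]]),   # one non-empty column
    ])
    def test_degenerate_matrices_rejected(self, matrix):
        with pytest.raises(DegenerateInputError):
            tn.nestedness_nodf(matrix)

    def test_non_binary_rejected(self):
        with pytest.raises(InvalidInputError):
            tn.nestedness_nodf(np.array([[2, 0], [1, 1]]))

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            m = (rng.random((5, 6)) < rng.uniform(0.2, 0.8)).astype(int)
            if (m.sum(axis=1) > 0).sum() < 2 or (m.sum(axis=0) > 0).sum() < 2:
                continue
            assert tn.nestedness_nodf(m) == pytest.approx(nodf_oracle(m))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        m = (rng.random((5, 7)) < 0.5).astype(int)
        if (m.sum(axis=1) > 0).sum() < 2 or (m.sum(axis=0) > 0).sum() < 2:
            return
        shuffled = m[rng.permutation(5)][:, rng.permutation(7)]
        assert tn.nestedness_nodf(m) == pytest.approx(tn.nestedness_nodf(shuffled))


class TestCommunitySummary:
    def test_summary_combines_connectance_and_nodf(self, small_run):
        _, community, _ = small_run
        profile = community.truth_profiles
        res = tn.community_summary(profile, "all")
        assert res.community_id == "all"
        assert res.connectance == pytest.approx(profile.to_numpy().sum() / len(profile) ** 2)
        assert res.nestedness == pytest.approx(tn.nestedness_nodf(profile))

    def test_degenerate_nodf_reported_as_none(self):
        profile = pd.DataFrame([[1, 0, 0]], index=["s1"])
        res = tn.community_summary(profile, "tiny")
        assert res.nestedness is None and res.S == 1
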