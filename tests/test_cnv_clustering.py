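import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from helpers import oracle_identical_row_groups

from cnvarray.cnv_clustering import (
    carrier_matrix,
    complete_linkage,
    cut_dendrogram,
    extract_blocks,
    hamming,
    pairwise_hamming,
    to_newick,
)
from cnvarray.core import CnvRegion


class TestHamming:
    @pytest.mark.parametrize(
        "u,v,expected",
        [
            ([0, 1, 0, 1], [0, 1, 0, 1], 0),
            ([0, 1, 0, 1], [1, 0, 1, 0], 4),
            ([0, 0, 1, 1, 0], [0, 1, 1, 0, 0], 2),
        ],
    )
    def test_known_distances(self, u, v, expected):
        assert hamming(u, v) == expected

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError):
            hamming([0, 1], [0, 1, 0])

    def test_pairwise_matches_scalar(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 2, size=(12, 9))
        d = pairwise_hamming(x)
        for i in range(12):
            for j in range(12):
                assert d[i, j] == hamming(x[i], x[j])


class TestCompleteLinkage:
    def test_two_identical_rows_merge_at_zero(self):
        z = complete_linkage(np.array([[0, 1, 1], [0, 1, 1]]))
        assert z.shape == (1, 4)
        assert z[0, 2] == 0.0

    def test_three_row_hand_agglomeration(self):
        # d(A,B)=1, d(A,C)=4, d(B,C)=5 -> {A,B}@1 then {AB,C}@5
        x = np.array(
            [
                [1, 1, 1, 1, 0, 0],
                [1, 1, 1, 1, 1, 0],
                [0, 0, 0, 0, 0, 0],
            ]
        )
        assert hamming(x[0], x[1]) == 1
        assert hamming(x[0], x[2]) == 4
        assert hamming(x[1], x[2]) == 5
        z = complete_linkage(x)
        assert (z[0, 0], z[0, 1], z[0, 2]) == (0.0, 1.0, 1.0)
        assert (z[1, 0], z[1, 1], z[1, 2]) == (2.0, 3.0, 5.0)

    def test_duplicate_rows_merge_before_distinct(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 2, size=(8, 10))
        x[5] = x[2]  # one duplicated pair
        z = complete_linkage(x)
        assert z[0, 2] == 0.0
        assert {int(z[0, 0]), int(z[0, 1])} == {2, 5}

    def test_merge_sequence_satisfies_complete_linkage_definition(self):
        # replay each merge from raw member sets: the height must equal the
        # max cross-pair Hamming distance, heights must be monotone, and no
        # other active pair may sit strictly closer at merge time
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.integers(0, 2, size=(rng.integers(3, 15), rng.integers(4, 12)))
            n = x.shape[0]
            z = complete_linkage(x)
            assert np.all(np.diff(z[:, 2]) >= 0)
            members = {i: {i} for i in range(n)}
            active = set(range(n))

            def linkage_dist(ca, cb):
                return max(hamming(x[i], x[j]) for i in members[ca] for j in members[cb])

            for step, (a, b, height, size) in enumerate(z):
                a, b = int(a), int(b)
                assert linkage_dist(a, b) == height
                best = min(
                    linkage_dist(p, q)
                    for p in active
                    for q in active
                    if p < q
                )
                assert height == best
                members[n + step] = members[a] | members[b]
                assert size == len(members[n + step])
                active -= {a, b}
                active.add(n + step)

    def test_matches_scipy_on_tie_free_instance(self):
        # distances 1, 4, 5 admit a unique agglomeration shared with scipy
        x = np.array(
            [
                [1, 1, 1, 1, 0, 0],
                [1, 1, 1, 1, 1, 0],
                [0, 0, 0, 0, 0, 0],
            ]
        )
        z = complete_linkage(x)
        z_scipy = hierarchy.linkage(
            pdist(x, metric="hamming") * x.shape[1], method="complete"
        )
        np.testing.assert_allclose(z[:, 2], z_scipy[:, 2])

    def test_single_row_is_error(self):
        with pytest.raises(ValueError):
            complete_linkage(np.array([[0, 1]]))


class TestExtractBlocks:
    def _matrix(self, rows, n_samples=6, prefix="r"):
        return pd.DataFrame(
            np.array(rows),
            index=[f"{prefix}{i}" for i in range(len(rows))],
            columns=[f"s{j}" for j in range(n_samples)],
        )

    def test_identical_rows_form_single_block_with_support(self):
        # mirrors the headline co-occurrence cluster: 29 regions carried by
        # exactly the same 5 samples
        carrier = np.zeros(72, dtype=int)
        carrier[[3, 11, 40, 41, 65]] = 1
        rows = [carrier] * 29 + [np.roll(carrier, 7)]
        m = pd.DataFrame(
            rows,
            index=[f"r{i}" for i in range(30)],
            columns=[f"s{j}" for j in range(72)],
        )
        z = complete_linkage(m)
        blocks = extract_blocks(z, m, max_height=0, min_regions=2)
        assert len(blocks) == 1
        assert blocks[0].n_regions == 29
        assert len(blocks[0].supporting_samples) == 5
        assert blocks[0].max_hamming == 0

    def test_all_distinct_rows_yield_no_blocks(self):
        m = self._matrix(np.eye(5, 6, dtype=int))
        z = complete_linkage(m)
        assert extract_blocks(z, m, max_height=0) == []

    def test_one_identical_pair_among_ten(self):
        rng = np.random.default_rng(8)
        rows = [rng.integers(0, 2, 8) for _ in range(9)]
        while len({tuple(r) for r in rows}) < 9:  # ensure distinct
            rows = [rng.integers(0, 2, 8) for _ in range(9)]
        rows.append(rows[4].copy())
        m = self._matrix(rows, n_samples=8)
        z = complete_linkage(m)
        blocks = extract_blocks(z, m, max_height=0)
        assert len(blocks) == 1
        assert set(blocks[0].regions) == {"r4", "r9"}

    def test_height_zero_equals_identical_row_grouping_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(15):
            x = rng.integers(0, 2, size=(rng.integers(4, 20), 5))
            m = self._matrix(x, n_samples=5)
            z = complete_linkage(m)
            groups = [g for g in cut_dendrogram(z, len(m), 0.0)]
            assert groups == oracle_identical_row_groups(x)

    def test_row_permutation_changes_labels_only(self):
        rng = np.random.default_rng(13)
        x = rng.integers(0, 2, size=(10, 7))
        x[7] = x[1]
        x[9] = x[1]
        m = self._matrix(x, n_samples=7)
        perm = rng.permutation(10)
        mp = m.iloc[perm]
        b1 = extract_blocks(complete_linkage(m), m)
        b2 = extract_blocks(complete_linkage(mp), mp)
        assert [set(b.regions) for b in b1] == [set(b.regions) for b in b2]

    def test_supporting_samples_carry_every_member(self):
        regions = [
            CnvRegion("chr1", 0, 1_000, "loss", {"case": frozenset({"a", "b"})}),
            CnvRegion("chr1", 5_000, 6_000, "loss", {"case": frozenset({"a", "b"})}),
            CnvRegion("chr1", 9_000, 10_000, "loss", {"case": frozenset({"a", "c"})}),
        ]
        m = carrier_matrix(regions, ["a", "b", "c"])
        z = complete_linkage(m)
        blocks = extract_blocks(z, m, max_height=0)
        assert len(blocks) == 1
        assert set(blocks[0].supporting_samples) == {"a", "b"}


def test_newick_export_parses_and_keeps_leaves():
    import dendropy

    rng = np.random.default_rng(3)
    x = rng.integers(0, 2, size=(6, 8))
    z = complete_linkage(x)
    labels = [f"cnv{i}" for i in range(6)]
    tree = dendropy.Tree.get(data=to_newick(z, labels), schema="newick")
    assert sorted(t.label for t in tree.taxon_namespace) == sorted(labels)
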