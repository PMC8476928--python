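"""Clonotype keys, organ sharing, entropy indices vs brute force."""

import math
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bregtools.repertoire import (
    assign_clonotypes,
    clonal_index_table,
    expansion_index,
    migration_index,
    pairwise_sharing,
    top_clonotypes,
    transition_between,
    transition_index,
)

from conftest import make_counts


def contig_table(rows):
    return pd.DataFrame(
        [
            {"barcode": bc, "chain": ch, "v_gene": v, "cdr3": aa,
             "cdr3_nt": "GCT" * len(aa), "productive": True}
            for bc, ch, v, aa in rows
        ]
    )


class TestAssign:
    def test_record_order_does_not_matter(self):
        a = contig_table([("c1", "IGH", "Ighv1-55", "CARW"), ("c1", "IGK", "Igkv4-55", "CQQF")])
        b = contig_table([("c2", "IGK", "Igkv4-55", "CQQF"), ("c2", "IGH", "Ighv1-55", "CARW")])
        assign = assign_clonotypes(pd.concat([a, b], ignore_index=True))
        assert assign.loc["c1", "clonotype"] == assign.loc["c2", "clonotype"]

    def test_v_gene_distinguishes_clonotypes(self):
        t = contig_table(
            [
                ("c1", "IGH", "Ighv1-55", "CARW"), ("c1", "IGK", "Igkv4-55", "CQQF"),
                ("c2", "IGH", "Ighv11-2", "CARW"), ("c2", "IGK", "Igkv4-55", "CQQF"),
            ]
        )
        assign = assign_clonotypes(t)
        assert assign.loc["c1", "clonotype"] != assign.loc["c2", "clonotype"]

    def test_five_cell_toy_sizes(self):
        # 2 cells share both chains; 3 singletons -> 4 clonotypes, sizes (2,1,1,1)
        rows = [
            ("c1", "IGH", "Ighv1-55", "CARW"), ("c1", "IGK", "Igkv4-55", "CQQF"),
            ("c2", "IGH", "Ighv1-55", "CARW"), ("c2", "IGK", "Igkv4-55", "CQQF"),
            ("c3", "IGH", "Ighv11-2", "CMRW"), ("c3", "IGK", "Igkv4-55", "CQQF"),
            ("c4", "IGH", "Ighv1-72", "CASF"), ("c4", "IGL", "Iglv1", "CQAF"),
            ("c5", "IGH", "Ighv5-6", "CTTW"), ("c5", "IGK", "Igkv12-89", "CQNF"),
        ]
        assign = assign_clonotypes(contig_table(rows))
        assert assign["clonotype"].nunique() == 4
        assert sorted(assign["clone_size"]) == [1, 1, 1, 2, 2]

    def test_nt_mode_splits_synonymous(self):
        t = contig_table([("c1", "IGH", "Ighv1-55", "CARW"), ("c2", "IGH", "Ighv1-55", "CARW")])
        t.loc[1, "cdr3_nt"] = "TGTGCTCGTTGG"  # same aa, different codons
        aa_assign = assign_clonotypes(t, key_mode="aa")
        nt_assign = assign_clonotypes(t, key_mode="nt")
        assert aa_assign["clonotype"].nunique() == 1
        assert nt_assign["clonotype"].nunique() == 2


class TestExpansion:
    def test_all_singletons_zero(self):
        assert expansion_index(["a", "b", "c", "d"]) == 0.0

    def test_monoclonal_is_one(self):
        assert expansion_index(["a", "a", "a", "a"]) == 1.0

    def test_single_cell_is_zero(self):
        assert expansion_index(["a"]) == 0.0

    def test_sizes_two_one(self):
        # H = -(2/3 log2 2/3 + 1/3 log2 1/3) = 0.9183; 1 - H/log2(2)
        expect = 1 - (-(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3))
        assert expansion_index(["a", "a", "b"]) == pytest.approx(expect, abs=1e-12)
        assert expansion_index(["a", "a", "b"]) == pytest.approx(0.0817, abs=5e-5)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            expansion_index([])

    def test_merging_singletons_never_decreases(self):
        base = ["a", "b", "c", "d"]
        merged = ["a", "a", "c", "d"]
        assert expansion_index(merged) >= expansion_index(base)


class TestMigration:
    def test_one_tissue_zero(self):
        assert migration_index(["a", "a", "b"], ["PC", "PC", "PC"]) == 0.0

    def test_symmetric_split_is_one(self):
        assert migration_index(["a"] * 4, ["PC", "PC", "liver", "liver"]) == pytest.approx(1.0)

    def test_weighted_example(self):
        # clone A: 3 cells (2 PC, 1 liver), clone B: 1 cell PC
        # w_A = 0.75, H_A = 0.9183; w_B = 0.25, H_B = 0 -> 0.6887
        idx = migration_index(["A", "A", "A", "B"], ["PC", "PC", "liver", "PC"])
        expect = 0.75 * (-(2 / 3) * math.log2(2 / 3) - (1 / 3) * math.log2(1 / 3))
        assert idx == pytest.approx(expect, abs=1e-12)
        assert idx == pytest.approx(0.6887, abs=5e-5)


class TestTransition:
    def test_disjoint_clonotypes_zero(self):
        assert transition_index(["a", "b"], ["c", "d"]) == 0.0

    def test_even_split_is_one(self):
        assert transition_index(["a", "a"], ["a", "a"]) == pytest.approx(1.0)

    def test_weighted_example(self):
        # clone x split 1/1 (w 0.5, H 1), clone y both in a (w 0.5, H 0) -> 0.5
        assert transition_index(["x", "y", "y"], ["x"]) == pytest.approx(0.5, abs=1e-12)

    def test_symmetry(self):
        a = ["x", "y", "y", "z"]
        b = ["x", "x", "z"]
        assert transition_index(a, b) == pytest.approx(transition_index(b, a), abs=1e-15)

    def test_identical_cluster_arguments_raise(self):
        assign = pd.DataFrame({"clonotype": ["x", "x"]}, index=["c1", "c2"])
        clusters = pd.Series(["0", "1"], index=["c1", "c2"])
        with pytest.raises(ValueError, match="distinct"):
            transition_between(assign, clusters, "0", "0")


def brute_force_indices(cells):
    """First-principles recomputation on a list of (clone, tissue, cluster)."""
    def entropy(counts):
        tot = sum(counts)
        return -sum(c / tot * math.log2(c / tot) for c in counts if c)

    by_cluster = {}
    for clone, tissue, cluster in cells:
        by_cluster.setdefault(cluster, []).append((clone, tissue))
    out = {}
    for cl, members in by_cluster.items():
        clones = Counter(c for c, _ in members)
        n = len(members)
        if len(clones) == 1:
            exp = 1.0 if n >= 2 else 0.0
        else:
            exp = 1 - entropy(clones.values()) / math.log2(len(clones))
        mig = 0.0
        for clone, size in clones.items():
            tissues = Counter(t for c, t in members if c == clone)
            mig += size / n * entropy(tissues.values())
        out[cl] = (exp, mig)
    return out


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    cells=st.lists(
        st.tuples(
            st.sampled_from(["cl1", "cl2", "cl3"]),
            st.sampled_from(["PC", "liver", "spleen"]),
            st.sampled_from(["A", "B"]),
        ),
        min_size=1,
        max_size=8,
    )
)
def test_indices_match_brute_force(cells):
    """On instances <= 8 cells, indices equal explicit probability tables."""
    expected = brute_force_indices(cells)
    assign = pd.DataFrame(
        {"clonotype": [c for c, _, _ in cells]},
        index=[f"c{i}" for i in range(len(cells))],
    )
    clusters = pd.Series([k for _, _, k in cells], index=assign.index)
    tissues = pd.Series([t for _, t, t2 in cells], index=assign.index)
    per_cluster, trans = clonal_index_table(assign, clusters, tissues)
    for cl, (exp, mig) in expected.items():
        assert per_cluster.loc[cl, "expansion"] == pytest.approx(exp, abs=1e-12)
        assert per_cluster.loc[cl, "migration"] == pytest.approx(mig, abs=1e-12)
    # transition vs brute force over the union
    if {"A", "B"} <= set(per_cluster.index):
        a = [c for c, _, k in cells if k == "A"]
        b = [c for c, _, k in cells if k == "B"]
        n = len(a) + len(b)
        expect_t = 0.0
        for clone in set(a) | set(b):
            na, nb = a.count(clone), b.count(clone)
            tot = na + nb
            h = 0.0
            for x in (na, nb):
                if x:
                    h -= x / tot * math.log2(x / tot)
            expect_t += tot / n * h
        assert trans.loc["A", "B"] == pytest.approx(expect_t, abs=1e-12)
        assert trans.loc["B", "A"] == trans.loc["A", "B"]


class TestSharing:
    def test_disjoint_repertoires_zero(self):
        assign = pd.DataFrame(
            {"clonotype": ["a", "b", "c", "d"]}, index=["c1", "c2", "c3", "c4"]
        )
        organs = pd.Series(["PC", "PC", "liver", "liver"], index=assign.index)
        clono, cells = pairwise_sharing(assign, organs)
        assert clono.to_numpy().sum() == 0
        assert cells.to_numpy().sum() == 0

    def test_hand_counted_union(self):
        # organ A clones {x(2), y(1)}, organ B {y(3), z(1)}:
        # shared = {y}; shared cells = 1 (A) + 3 (B) = 4
        assign = pd.DataFrame(
            {"clonotype": ["x", "x", "y", "y", "y", "y", "z"]},
            index=[f"c{i}" for i in range(7)],
        )
        organs = pd.Series(["A", "A", "A", "B", "B", "B", "B"], index=assign.index)
        clono, cells = pairwise_sharing(assign, organs)
        assert clono.loc["A", "B"] == 1
        assert cells.loc["A", "B"] == 4
        assert clono.loc["B", "A"] == 1
        assert clono.loc["A", "A"] == 0  # diagonal left empty by convention

    def test_recovers_planted_shared_clones(self, small_config):
        from bregtools.simulate import generate_dataset

        counts, truth, contigs = generate_dataset(small_config)
        assign = assign_clonotypes(contigs)
        breg = truth.cells.index[truth.cells["is_breg"]]
        clono, _ = pairwise_sharing(assign, truth.cells["organ"], scope=breg)
        for a, b, n in small_config.shared_clone_pairs:
            assert clono.loc[a, b] >= n


class TestTopClonotypes:
    def test_n_larger_than_count_returns_all(self):
        assign = pd.DataFrame({"clonotype": ["a", "a", "b"]}, index=["c1", "c2", "c3"])
        top = top_clonotypes(assign, n=10)
        assert len(top) == 2

    def test_deterministic_tie_break(self):
        assign = pd.DataFrame(
            {"clonotype": ["q"] * 5 + ["m"] * 3 + ["a"] * 3 + ["z"]},
            index=[f"c{i}" for i in range(12)],
        )
        top = top_clonotypes(assign, n=2)
        assert list(top.index) == ["q", "a"]  # size 5, then the tie (3,3) by key
        assert list(top["size"]) == [5, 3]

    def test_planted_expanded_clones_top_ranked(self, small_config):
        from bregtools.simulate import generate_dataset

        counts, truth, contigs = generate_dataset(small_config)
        assign = assign_clonotypes(contigs)
        top = top_clonotypes(assign, n=small_config.expanded_clone_count)
        assert (top["size"] == small_config.expanded_clone_size).all()
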