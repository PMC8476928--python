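"""Module scores, thresholded calls, composition tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from bregtools.containers import GeneSignature
from bregtools.scoring import (
    BregCall,
    calibrate_threshold,
    call_b10,
    call_breg,
    composition_table,
    compute_module_score,
)

from conftest import make_expr


def naive_score(values, genes, signature):
    """Independent two-loop recomputation of the module score."""
    idx = [i for i, g in enumerate(genes) if g in set(signature)]
    scores = []
    for row in values:
        total = 0.0
        for i in idx:
            total += row[i]
        m = total / len(idx)
        scores.append(math.log1p(m) if m > -1 else -math.inf)
    return np.array(scores)


SIG3 = GeneSignature("sig", ("g000", "g001", "g002"))


class TestModuleScore:
    def test_worked_example(self):
        # scaled values (0.5, 0.3, -0.2): m = 0.2 -> ln(1.2)
        em = make_expr([[0.5, 0.3, -0.2]])
        sv = compute_module_score(em, SIG3)
        assert sv.scores.iloc[0] == pytest.approx(math.log(1.2), abs=1e-12)
        assert sv.n_genes_used == 3

    def test_all_zero_scores_zero(self):
        sv = compute_module_score(make_expr(np.zeros((2, 3))), SIG3)
        assert (sv.scores == 0).all()

    def test_pathological_mean_gives_sentinel(self):
        em = make_expr([[-1.2, -1.2, -1.2]])
        sv = compute_module_score(em, SIG3)
        assert sv.scores.iloc[0] == -np.inf
        assert not call_breg(sv, threshold=-1e9).is_breg.iloc[0]

    def test_missing_genes_dropped_with_count(self):
        em = make_expr([[0.4, 0.2]], genes=["g000", "g001"])
        sig = GeneSignature("sig", ("g000", "g001", "absent"))
        sv = compute_module_score(em, sig)
        assert sv.n_genes_used == 2
        assert sv.scores.iloc[0] == pytest.approx(math.log1p(0.3), abs=1e-12)

    def test_no_genes_present_raises(self):
        em = make_expr([[0.4]], genes=["g000"])
        with pytest.raises(ValueError, match="mysig"):
            compute_module_score(em, GeneSignature("mysig", ("absent",)))

    def test_oracle_equivalence_on_random_matrices(self):
        """50 random small matrices match a naive two-loop recomputation."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(2, 21))
            g = int(rng.integers(3, 21))
            vals = rng.normal(0, 1.5, size=(n, g))
            genes = [f"g{j:03d}" for j in range(g)]
            k = int(rng.integers(1, g + 1))
            sig_genes = list(rng.choice(genes, size=k, replace=False))
            em = make_expr(vals, genes=genes)
            sv = compute_module_score(em, GeneSignature("s", tuple(sig_genes)))
            expected = naive_score(vals, genes, sig_genes)
            np.testing.assert_allclose(sv.scores.to_numpy(), expected, atol=1e-12)

    def test_order_invariance(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(5, 6))
        genes = [f"g{j:03d}" for j in range(6)]
        em = make_expr(vals, genes=genes)
        a = compute_module_score(em, GeneSignature("s", ("g002", "g000", "g004")))
        b = compute_module_score(em, GeneSignature("s", ("g004", "g002", "g000")))
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-15)
        # genes outside the signature are irrelevant
        em2 = make_expr(np.column_stack([vals, rng.normal(size=(5, 2))]),
                        genes=genes + ["x1", "x2"])
        c = compute_module_score(em2, GeneSignature("s", ("g002", "g000", "g004")))
        np.testing.assert_allclose(a.scores, c.scores.to_numpy(), atol=1e-15)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        base=st.lists(st.floats(-0.9, 5), min_size=3, max_size=3),
        bump=st.floats(0, 3),
    )
    def test_monotone_in_signature_values(self, base, bump):
        em1 = make_expr([base])
        raised = list(base)
        raised[1] += bump
        em2 = make_expr([raised])
        s1 = compute_module_score(em1, SIG3).scores.iloc[0]
        s2 = compute_module_score(em2, SIG3).scores.iloc[0]
        assert s2 >= s1


class TestCalls:
    def test_breg_threshold_is_strict(self):
        scores = compute_module_score(make_expr([[0.16, 0.16, 0.16]]), SIG3)
        # m = 0.16 -> score = ln(1.16) ~ 0.148 < 0.16 -> non-Breg; check strictness directly
        sv = scores
        sv.scores.iloc[0] = 0.16
        assert not call_breg(sv, threshold=0.16).is_breg.iloc[0]
        sv.scores.iloc[0] = 0.16 + 1e-12
        assert call_breg(sv, threshold=0.16).is_breg.iloc[0]

    def test_worked_score_is_breg_at_default_threshold(self):
        em = make_expr([[0.5, 0.3, -0.2]])
        sv = compute_module_score(em, SIG3)
        assert call_breg(sv).is_breg.iloc[0]  # 0.1823 > 0.16

    def test_minus_inf_threshold_calls_all_finite_cells(self):
        em = make_expr([[-0.5, 0.0, 0.1], [0.2, 0.2, 0.2]])
        sv = compute_module_score(em, SIG3)
        calls = call_breg(sv, threshold=-np.inf)
        assert calls.is_breg.all()

    def test_b10_on_nonbreg_cell_raises(self):
        em = make_expr([[0.5, 0.5, 0.5], [-0.5, -0.5, -0.5]])
        sv = compute_module_score(em, SIG3)
        calls = call_breg(sv)
        bad_scores = compute_module_score(em, SIG3)  # covers both cells
        with pytest.raises(ValueError, match="non-Breg"):
            call_b10(calls, bad_scores)

    def test_b10_limits(self):
        em = make_expr([[0.5, 0.5, 0.5], [0.6, 0.6, 0.6]])
        sv = compute_module_score(em, SIG3)
        calls = call_breg(sv)
        b10_scores = compute_module_score(em, SIG3, cells=calls.breg_barcodes)
        all_b10 = call_b10(calls, b10_scores, threshold=-np.inf)
        assert all_b10.is_b10.fillna(False).sum() == 2
        none_b10 = call_b10(calls, b10_scores, threshold=np.inf)
        assert none_b10.is_b10.fillna(False).sum() == 0

    def test_b10_implies_breg_enforced(self):
        is_breg = pd.Series([True, False], index=["a", "b"])
        is_b10 = pd.Series([True, True], index=["a", "b"], dtype="boolean")
        with pytest.raises(ValueError, match="implies"):
            BregCall(is_breg=is_breg, is_b10=is_b10)


def test_calibrate_threshold_splits_bimodal():
    rng = np.random.default_rng(0)
    lo = rng.normal(0.0, 0.05, 300)
    hi = rng.normal(0.5, 0.05, 200)
    s = pd.Series(np.concatenate([lo, hi]))
    thr = calibrate_threshold(s)
    assert 0.1 < thr < 0.4
    assert (s > thr).mean() == pytest.approx(0.4, abs=0.02)


class TestComposition:
    def test_single_organ_all_breg(self):
        calls = BregCall(is_breg=pd.Series([True, True], index=["a", "b"]))
        organs = pd.Series(["PC", "PC"], index=["a", "b"])
        tab = composition_table(calls, organs)["organ_breg"]
        assert tab.loc["PC", "breg_fraction"] == 1.0

    def test_hand_counted_proportions(self):
        # 10 cells: PC 6 with 3 Breg -> 0.5; spleen 4 with 1 Breg -> 0.25
        idx = [f"c{i}" for i in range(10)]
        organs = pd.Series(["PC"] * 6 + ["spleen"] * 4, index=idx)
        is_breg = pd.Series([True, True, True, False, False, False,
                             True, False, False, False], index=idx)
        tab = composition_table(BregCall(is_breg=is_breg), organs)["organ_breg"]
        assert tab.loc["PC", "breg_fraction"] == 0.5
        assert tab.loc["spleen", "breg_fraction"] == 0.25
        np.testing.assert_allclose(
            tab[["breg_fraction", "nonbreg_fraction"]].sum(axis=1), 1.0, atol=1e-12
        )

    def test_cluster_blocks_sum_to_one(self):
        idx = [f"c{i}" for i in range(6)]
        organs = pd.Series(["PC", "PC", "liver", "liver", "PC", "liver"], index=idx)
        is_breg = pd.Series(True, index=idx)
        is_b10 = pd.Series([True, False, True, True, False, False],
                           index=idx, dtype="boolean")
        calls = BregCall(is_breg=is_breg, is_b10=is_b10)
        clusters = pd.Series(["0", "0", "0", "1", "1", "1"], index=idx)
        tabs = composition_table(calls, organs, clusters=clusters)
        np.testing.assert_allclose(tabs["cluster_organ"].sum(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(
            tabs["cluster_b10"][["b10_fraction", "non_b10_fraction"]].sum(axis=1),
            1.0, atol=1e-12,
        )
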