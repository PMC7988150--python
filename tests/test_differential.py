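"""Quantile normalization, Welch testing, BH-FDR and ranked selection."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmikit import (
    DEResult,
    SynthConfig,
    bh_adjust,
    generate_grouped,
    quantile_normalize,
    select_top_downregulated,
    significant_genes,
)
from pmikit.differential import test_two_group as welch_two_group
from pmikit.simulate import NEURONAL

from conftest import make_grouped


def bh_bruteforce(p):
    """Textbook step-up definition: q_i = min_{j >= i} (m * p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestQuantileNormalize:
    def test_two_column_hand_example(self):
        gm = make_grouped([[1.0, 2.0], [3.0, 6.0]], ["G1", "G2"], n_a=1, n_b=1,
                          levels=("a", "b"))
        out = quantile_normalize(gm)
        assert np.allclose(out.values, [[1.5, 1.5], [4.5, 4.5]])

    def test_tie_rule_mean_of_tied_reference_values(self):
        # sorted columns: [2,2,5] and [1,3,4]; reference = [1.5, 2.5, 4.5];
        # the tied pair shares mean(1.5, 2.5) = 2.0
        gm = make_grouped([[2.0, 1.0], [2.0, 3.0], [5.0, 4.0]],
                          ["G1", "G2", "G3"], n_a=1, n_b=1, levels=("a", "b"))
        out = quantile_normalize(gm)
        assert np.allclose(out.values[:, 0], [2.0, 2.0, 4.5])
        assert np.allclose(out.values[:, 1], [1.5, 2.5, 4.5])

    def test_identical_columns_are_fixed_point(self):
        col = [4.0, 1.0, 7.0]
        gm = make_grouped(np.column_stack([col, col, col, col]),
                          ["G1", "G2", "G3"], n_a=2, n_b=2)
        out = quantile_normalize(gm)
        assert np.allclose(out.values, gm.values)

    def test_idempotent(self, small_cfg):
        gm, _ = generate_grouped(small_cfg, mode="fresh_vs_postmortem")
        once = quantile_normalize(gm)
        twice = quantile_normalize(once)
        assert np.allclose(once.values, twice.values, rtol=1e-12)

    def test_single_sample_matrix_cannot_exist(self):
        # a two-level grouped matrix needs >= 2 samples by construction
        gm = make_grouped([[1.0, 2.0]], ["G1"], n_a=1, n_b=1, levels=("a", "b"))
        with pytest.raises(ValueError):
            type(gm)(gm.data.iloc[:, :1], group_of={"a_1": "a"})

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        st.lists(
            st.lists(st.floats(0.0, 1e4, allow_nan=False), min_size=4, max_size=4),
            min_size=2,
            max_size=40,
        )
    )
    def test_columns_share_sorted_multiset_and_sum(self, rows):
        # tie-free columns take on exactly the reference multiset; a tied
        # run is replaced by the mean of its reference values, which
        # preserves the column sum but not the multiset
        genes = [f"G{i}" for i in range(len(rows))]
        gm = make_grouped(rows, genes, n_a=2, n_b=2)
        out = quantile_normalize(gm)
        ref = np.sort(gm.values, axis=0).mean(axis=1)
        for j in range(4):
            col_in = gm.values[:, j]
            if np.unique(col_in).size == col_in.size:
                assert np.allclose(np.sort(out.values[:, j]), ref, rtol=1e-9, atol=1e-9)
        sums = out.values.sum(axis=0)
        assert np.allclose(sums, sums[0], rtol=1e-9, atol=1e-6)


class TestBenjaminiHochberg:
    def test_hand_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0.0, 1.0, allow_nan=False), min_size=1, max_size=400))
    def test_matches_bruteforce_definition(self, p):
        assert np.allclose(bh_adjust(p), bh_bruteforce(p), rtol=1e-12, atol=1e-12)

    def test_q_never_below_p(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=300)
        assert (bh_adjust(p) >= p - 1e-15).all()


class TestTwoGroupTest:
    def test_identical_groups_null(self):
        vals = np.tile([[4.0], [9.0], [1.0]], (1, 4))
        gm = make_grouped(vals, ["G1", "G2", "G3"])
        res = welch_two_group(gm)
        for r in res:
            assert r.log2fc == pytest.approx(0.0)
            assert r.p == pytest.approx(1.0)
            assert r.q == pytest.approx(1.0)

    def test_gene_expressed_in_neither_group_excluded(self):
        vals = [[0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0]]
        gm = make_grouped(vals, ["G0", "G1"])
        res = welch_two_group(gm)
        assert [r.gene_id for r in res] == ["G1"]

    def test_gene_expressed_in_one_group_only_excluded(self):
        vals = [[5.0, 6.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0]]
        gm = make_grouped(vals, ["G0", "G1"])
        res = welch_two_group(gm)
        assert [r.gene_id for r in res] == ["G1"]

    def test_single_replicate_group_rejected(self):
        gm = make_grouped([[1.0, 2.0, 3.0]], ["G1"], n_a=1, n_b=2)
        with pytest.raises(ValueError, match="replicates"):
            welch_two_group(gm)

    def test_fc_sign_encoding_consistent_with_log2fc(self, small_cfg):
        gm, _ = generate_grouped(small_cfg, mode="fresh_vs_postmortem")
        res = welch_two_group(quantile_normalize(gm))
        for r in res[:200]:
            assert r.fc >= 1.0 or r.fc <= -1.0
            expected = r.ratio if r.ratio >= 1 else -1.0 / r.ratio
            assert r.fc == pytest.approx(expected, rel=1e-12)
            assert r.log2fc == pytest.approx(math.log2(r.ratio), rel=1e-12)

    def test_universe_on_noisy_synthetic_equals_expressed_in_both(self, small_cfg):
        gm, _ = generate_grouped(small_cfg, mode="fresh_vs_postmortem")
        res = welch_two_group(gm)
        expressed = (
            (gm.group_values("fresh") > 0).any(axis=1)
            & (gm.group_values("postmortem") > 0).any(axis=1)
        )
        assert len(res) == int(expressed.sum())


def _fake_result(gene, ratio, p, q=0.001):
    return DEResult(
        gene_id=gene, mean_a=ratio, mean_b=1.0, ratio=ratio,
        fc=ratio if ratio >= 1 else -1 / ratio, log2fc=math.log2(ratio), p=p, q=q,
    )


class TestSelectTopDownregulated:
    def test_filter_and_order(self):
        res = [
            _fake_result("G1", 3.0, 0.01),
            _fake_result("G2", 2.7, 0.01),
            _fake_result("G3", 2.0, 0.01),
        ]
        assert select_top_downregulated(res, n_top=2, p_max=0.05, min_ratio=2.6) == [
            "G1", "G2",
        ]

    def test_all_nonsignificant_gives_empty(self):
        res = [_fake_result(f"G{i}", 5.0, 0.5) for i in range(5)]
        assert select_top_downregulated(res, n_top=3) == []

    def test_tie_break_by_gene_id(self):
        res = [_fake_result(g, 3.0, 0.01) for g in ("GB", "GA", "GC")]
        assert select_top_downregulated(res, n_top=3) == ["GA", "GB", "GC"]

    def test_planted_decays_beyond_ratio_cutoff_are_selected(self):
        """Well-expressed neuronal genes whose expected fresh/postmortem
        ratio clears the 2.6 cutoff appear in the selection.

        Low-expression genes are excluded from the oracle: quantile
        normalization maps their decayed postmortem values onto the
        reference distribution's bottom quantiles, which legitimately
        compresses the measured ratio.
        """
        cfg = SynthConfig(noise_sd_log2=0.25, seed=7, n_genes=1500, n_neuronal=120,
                          n_glial=130, n_housekeeping=20)
        gm, truth = generate_grouped(cfg, mode="fresh_vs_postmortem")
        res = welch_two_group(quantile_normalize(gm))
        selected = set(select_top_downregulated(res, n_top=cfg.n_genes))
        must, should = [], []
        for g in truth:
            if g.planted_class != NEURONAL:
                continue
            x0 = float(gm.data.loc[g.gene_id].iloc[:4].mean())
            if x0 < 20.0:
                continue
            decayed = x0 * math.exp(-g.planted_lambda * cfg.pm_interval_h)
            expected_ratio = (x0 + 1.0) / (decayed + 1.0)
            if expected_ratio > 2.6 * 1.25:
                must.append(g.gene_id)
            elif expected_ratio > 2.6:
                should.append(g.gene_id)
        assert must, "scenario should produce strongly decayed genes"
        assert set(must) <= selected
        if should:
            hit = sum(1 for g in should if g in selected)
            assert hit / len(should) >= 0.5  # boundary genes: noise may flip a few


def test_significant_genes_preset(small_cfg):
    gm, truth = generate_grouped(small_cfg, mode="fresh_vs_postmortem")
    res = welch_two_group(quantile_normalize(gm))
    hits = set(significant_genes(res, min_abs_fc=1.5, fdr_max=0.12))
    planted = {g.gene_id for g in truth if g.planted_class in (NEURONAL, "glial_rise")}
    assert len(hits & planted) / len(planted) > 0.9
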