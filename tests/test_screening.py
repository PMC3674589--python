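"""Per-gene screening statistics and cross-species concordant selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from coexnet.datasets import load_concordance_reference
from coexnet.modulestats import adjust_pvalues
from coexnet.screening import (
    auroc,
    concordance_auroc,
    screen_binary_trait,
    screen_numeric_trait,
    select_concordant_genes,
    sex_confounding_check,
    signed_fold_change,
)


class TestSignedFoldChange:
    def test_stated_rules(self):
        assert signed_fold_change(4.0, 2.0) == pytest.approx(2.0)
        assert signed_fold_change(2.0, 4.0) == pytest.approx(-2.0)
        assert signed_fold_change(3.0, 3.0) == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(
        a=st.floats(min_value=0.01, max_value=100),
        b=st.floats(min_value=0.01, max_value=100),
    )
    def test_antisymmetry(self, a, b):
        if a == b:
            return
        assert signed_fold_change(a, b) == pytest.approx(-signed_fold_change(b, a))

    def test_nonpositive_mean_flagged_missing(self):
        assert np.isnan(signed_fold_change(-1.0, 2.0))


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([1, 2, 3, 4], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_all_tied_values_give_half(self):
        assert auroc([5, 5, 5, 5], [0, 1, 0, 1]) == pytest.approx(0.5)

    def test_matches_pair_counting_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 15))
            v = rng.integers(0, 5, size=n).astype(float)  # ties likely
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            pos, neg = v[y == 1], v[y == 0]
            pairs = [(1.0 if p > q else 0.5 if p == q else 0.0)
                     for p in pos for q in neg]
            assert auroc(v, y) == pytest.approx(np.mean(pairs))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([1, 2], [1, 1])

    def test_concordance_reduces_to_auroc_for_binary_trait(self, rng):
        v = rng.standard_normal(20)
        y = rng.integers(0, 2, size=20)
        if y.min() != y.max():
            assert concordance_auroc(v, y.astype(float)) == pytest.approx(auroc(v, y))


def _two_group_expr(rng, n_genes=50, n1=6, n2=6, shift=0.0):
    x = rng.standard_normal((n_genes, n1 + n2))
    x[:, :n1] += shift
    expr = pd.DataFrame(x, index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n1 + n2)])
    groups = pd.Series(["A"] * n1 + ["B"] * n2, index=expr.columns)
    return expr, groups


class TestBinaryScreen:
    def test_welch_statistic_matches_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 3.0, 4.0])
        expr = pd.DataFrame([np.concatenate([a, b])], index=["g"],
                            columns=[f"s{j}" for j in range(6)])
        groups = pd.Series(["x"] * 3 + ["y"] * 3, index=expr.columns)
        out = screen_binary_trait(expr, groups, first_group="x")
        se2 = a.var(ddof=1) / 3 + b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(se2)
        df = se2 ** 2 / ((a.var(ddof=1) / 3) ** 2 / 2 + (b.var(ddof=1) / 3) ** 2 / 2)
        p = 2 * stats.t.sf(abs(t), df)
        assert out.loc["g", "t.Student"] == pytest.approx(t, rel=1e-12)
        assert out.loc["g", "pvalueStudent"] == pytest.approx(p, rel=1e-9)
        assert out.loc["g", "meanFirstGroup"] == pytest.approx(2.0)
        assert out.loc["g", "FoldChange"] == pytest.approx(-3.0 / 2.0)

    def test_perfectly_separated_gene_has_auroc_one(self, rng):
        expr, groups = _two_group_expr(rng, n_genes=1)
        expr.iloc[0] = np.concatenate([np.arange(6) + 10, np.arange(6)])
        out = screen_binary_trait(expr, groups, first_group="A")
        assert out["AreaUnderROC"].iloc[0] == pytest.approx(1.0)

    def test_null_type_one_error_calibrated(self, rng):
        expr, groups = _two_group_expr(rng, n_genes=2000, n1=25, n2=24)
        out = screen_binary_trait(expr, groups)
        rate = (out["pvalueStudent"] < 0.05).mean()
        assert 0.03 < rate < 0.07
        ks = stats.kstest(out["pvalueStudent"].to_numpy(), "uniform")
        assert ks.pvalue > 0.01

    def test_small_group_errors(self, rng):
        expr, _ = _two_group_expr(rng, n_genes=5)
        groups = pd.Series(["A"] + ["B"] * 11, index=expr.columns)
        with pytest.raises(ValueError):
            screen_binary_trait(expr, groups)

    def test_constant_gene_flagged_missing(self, rng):
        expr, groups = _two_group_expr(rng, n_genes=3)
        expr.iloc[0] = 1.0
        out = screen_binary_trait(expr, groups)
        assert np.isnan(out["t.Student"].iloc[0])
        assert out["nPresentSamples"].iloc[0] == 12

    def test_missing_values_counted(self, rng):
        expr, groups = _two_group_expr(rng, n_genes=3)
        expr.iloc[1, 0] = np.nan
        out = screen_binary_trait(expr, groups)
        assert out["nPresentSamples"].iloc[1] == 11


class TestNumericScreen:
    def test_gene_equal_to_trait(self):
        trait = pd.Series([4.0, 8.0, 12.0, 16.0, 20.0],
                          index=[f"s{j}" for j in range(5)])
        expr = pd.DataFrame([trait.to_numpy()], index=["g"], columns=trait.index)
        out = screen_numeric_trait(expr, trait)
        assert out.loc["g", "corPearson"] == pytest.approx(1.0)

    def test_matches_hand_pearson(self):
        weeks = np.array([4.0, 8.0, 12.0, 16.0, 20.0])
        vals = np.array([1.0, 1.5, 1.2, 2.5, 2.0])
        expr = pd.DataFrame([vals], index=["g"],
                            columns=[f"s{j}" for j in range(5)])
        out = screen_numeric_trait(expr, pd.Series(weeks, index=expr.columns))
        vc, wc = vals - vals.mean(), weeks - weeks.mean()
        r = (vc @ wc) / np.sqrt((vc @ vc) * (wc @ wc))
        assert out.loc["g", "corPearson"] == pytest.approx(r, rel=1e-12)
        t = r * np.sqrt(3 / (1 - r ** 2))
        assert out.loc["g", "t.Student"] == pytest.approx(t, rel=1e-12)

    def test_planted_trend_module_exceeds_background(self, species_pair):
        human, mouse, _ = species_pair
        trait = mouse["meta"]["week"].astype(float)
        out = screen_numeric_trait(mouse["expr"], trait)
        truth = mouse["truth"]
        trend = out.loc[truth.assignment == "M1", "corPearson"].abs().mean()
        background = out.loc[truth.assignment == "background", "corPearson"].abs().mean()
        assert trend > background

    def test_same_ranking_as_binary_screen_for_01_trait(self, rng):
        expr, groups = _two_group_expr(rng, n_genes=40, n1=8, n2=8)
        binary = screen_binary_trait(expr, groups, first_group="A")
        numeric = screen_numeric_trait(
            expr, (groups == "A").astype(float)
        )
        rank_b = binary["t.Student"].abs().rank()
        rank_n = numeric["corPearson"].abs().rank()
        assert (rank_b - rank_n).abs().max() < 1e-8

    def test_constant_trait_errors(self, random_expression):
        trait = pd.Series(1.0, index=random_expression.columns)
        with pytest.raises(ValueError):
            screen_numeric_trait(random_expression, trait)


class TestBHQvalues:
    def test_q_dominates_p_and_matches_sort_scan_oracle(self, rng):
        p = rng.random(200)
        q = adjust_pvalues(p, "bh")
        assert (q >= p - 1e-15).all()
        # sort-and-scan oracle
        order = np.argsort(p)
        expected = np.empty_like(p)
        running = 1.0
        for rank in range(len(p) - 1, -1, -1):
            running = min(running, p[order[rank]] * len(p) / (rank + 1))
            expected[order[rank]] = running
        np.testing.assert_allclose(q, expected)


class TestConcordantSelection:
    @staticmethod
    def _screen_frame(cors, genes):
        return pd.DataFrame(
            {"corPearson": cors, "pvalueStudent": [0.001] * len(cors)},
            index=pd.Index(genes, name="gene_id"),
        )

    def test_concordant_gene_selected_positive(self):
        human = self._screen_frame([0.57], ["ADA"])
        mouse = self._screen_frame([0.62], ["Ada"])
        ortho = pd.DataFrame({"human_gene": ["ADA"], "mouse_gene": ["Ada"]})
        out = select_concordant_genes(human, mouse, ortho, threshold=0.5)
        assert out.shape[0] == 1
        assert out.loc[0, "Progression"] == "+"

    def test_discordant_gene_rejected(self):
        human = self._screen_frame([0.6], ["X"])
        mouse = self._screen_frame([0.3], ["x"])
        ortho = pd.DataFrame({"human_gene": ["X"], "mouse_gene": ["x"]})
        out = select_concordant_genes(human, mouse, ortho, threshold=0.5)
        assert out.empty

    def test_impossible_threshold_gives_empty_table(self, rng):
        genes = [f"g{i}" for i in range(20)]
        human = self._screen_frame(rng.uniform(-0.99, 0.99, 20), genes)
        mouse = self._screen_frame(rng.uniform(-0.99, 0.99, 20),
                                   [g + "m" for g in genes])
        ortho = pd.DataFrame({"human_gene": genes,
                              "mouse_gene": [g + "m" for g in genes]})
        out = select_concordant_genes(human, mouse, ortho, threshold=1.0)
        assert out.empty

    def test_published_reference_rows_all_retained_with_directions(self):
        ref = load_concordance_reference()
        human = self._screen_frame(ref["corHuman"].to_numpy(), ref["GeneSymbol"])
        mouse = self._screen_frame(ref["corMouse"].to_numpy(),
                                   [g.lower() for g in ref["GeneSymbol"]])
        ortho = pd.DataFrame({"human_gene": ref["GeneSymbol"],
                              "mouse_gene": [g.lower() for g in ref["GeneSymbol"]]})
        out = select_concordant_genes(human, mouse, ortho, threshold=0.5)
        assert out.shape[0] == 25
        expected = ref.set_index("GeneSymbol")["Progression"]
        got = out.set_index("GeneSymbol")["Progression"]
        assert (got == expected.loc[got.index]).all()

    def test_empty_intersection_errors(self):
        human = self._screen_frame([0.6], ["X"])
        mouse = self._screen_frame([0.6], ["y"])
        ortho = pd.DataFrame({"human_gene": ["Z"], "mouse_gene": ["z"]})
        with pytest.raises(ValueError):
            select_concordant_genes(human, mouse, ortho)


class TestSexCheck:
    @staticmethod
    def _dataset(rng, sex_effect=0.0, n_genes=100):
        n = 30
        expr = pd.DataFrame(
            rng.standard_normal((n_genes, n)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{j}" for j in range(n)],
        )
        meta = pd.DataFrame(
            {"group": ["control"] * 20 + ["pSS"] * 10,
             "sex": (["F", "M"] * 15)},
            index=expr.columns,
        )
        if sex_effect:
            females = meta.index[(meta["sex"] == "F") & (meta["group"] == "control")]
            expr.loc["g0", females] += sex_effect
        return expr, meta

    def test_no_sex_effect_finds_nothing(self, rng):
        hits = 0
        for _ in range(10):
            expr, meta = self._dataset(rng)
            out = sex_confounding_check(expr, meta)
            hits += out["n_sex_associated"] == 0
        assert hits >= 9

    def test_planted_sex_linked_gene_detected(self, rng):
        expr, meta = self._dataset(rng, sex_effect=5.0)
        out = sex_confounding_check(expr, meta, disease_genes=["g0", "g1"])
        assert "g0" in out["sex_associated_genes"]
        assert out["n_overlap_with_disease"] == 1

    def test_empty_disease_list_gives_zero_overlap(self, rng):
        expr, meta = self._dataset(rng, sex_effect=5.0)
        out = sex_confounding_check(expr, meta, disease_genes=[])
        assert out["n_overlap_with_disease"] == 0

    def test_single_sex_errors(self, rng):
        expr, meta = self._dataset(rng)
        meta["sex"] = "F"
        with pytest.raises(ValueError):
            sex_confounding_check(expr, meta)
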