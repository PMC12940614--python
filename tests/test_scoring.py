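"""Scoring layer: z-scoring, single-sample enrichment, COX-IS, TMB, median split."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from tlsmeta.datatypes import GeneSet, MutationTable
from tlsmeta.scoring import (
    coxis_score,
    gsva_like_score,
    median_stratify,
    tmb,
    zscore_expression,
)


def brute_force_es(z_col: pd.Series, members: set, tau: float = 1.0) -> float:
    """Independent scalar running-sum enrichment score for one sample.

    Walks every position of the descending-z gene list (ties by gene
    symbol), accumulating |z|^tau / sum_in for in-set genes and -1/(G-m)
    otherwise; returns max positive plus min negative deviation.
    """
    genes = list(z_col.index)
    order = sorted(range(len(genes)), key=lambda i: (-z_col.iloc[i], genes[i]))
    in_set = [genes[i] in members for i in order]
    m = sum(in_set)
    G = len(genes)
    denom = sum(abs(z_col.iloc[i]) ** tau for i in order if genes[i] in members)
    running, best_pos, best_neg = 0.0, 0.0, 0.0
    for idx, flag in zip(order, in_set):
        if flag:
            running += (abs(z_col.iloc[idx]) ** tau) / denom if denom > 0 else 1.0 / m
        else:
            running -= 1.0 / (G - m)
        best_pos = max(best_pos, running)
        best_neg = min(best_neg, running)
    return best_pos + best_neg


class TestZscore:
    def test_hand_computed_row(self):
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["A"], columns=list("xyz"))
        z = zscore_expression(expr)
        np.testing.assert_allclose(
            z.loc["A"].to_numpy(), [-1.224744871, 0.0, 1.224744871], atol=1e-8
        )

    def test_constant_row_zeroed_and_flagged(self):
        expr = pd.DataFrame(
            [[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]], index=["A", "B"], columns=list("xyz")
        )
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_expression(expr)
        assert (z.loc["B"] == 0).all()
        assert z.attrs["constant_genes"] == ["B"]

    def test_row_means_vanish(self, rng):
        expr = pd.DataFrame(rng.uniform(0, 12, size=(30, 9)))
        z = zscore_expression(expr)
        assert np.abs(z.mean(axis=1)).max() < 1e-12
        assert np.abs(z.std(axis=1, ddof=0) - 1).max() < 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            zscore_expression(pd.DataFrame([[1.0]], index=["A"], columns=["s"]))


class TestEnrichmentScore:
    def test_matches_exhaustive_oracle(self, rng):
        for trial in range(25):
            G = 10
            z = pd.DataFrame(
                np.round(rng.normal(size=(G, 3)), 2),  # rounding makes ties likely
                index=[f"g{i}" for i in range(G)],
                columns=["a", "b", "c"],
            )
            members = tuple(
                rng.choice(z.index, size=rng.integers(1, G), replace=False)
            )
            es = gsva_like_score(z, GeneSet("t", members))
            for sample in z.columns:
                expected = brute_force_es(z[sample], set(members))
                assert es[sample] == pytest.approx(expected, abs=1e-12)

    def test_top_genes_attain_maximum(self, rng):
        z = pd.DataFrame(
            rng.normal(size=(12, 1)), index=[f"g{i}" for i in range(12)], columns=["s"]
        )
        m = 4
        top = z["s"].sort_values(ascending=False).index[:m]
        es = gsva_like_score(z, GeneSet("top", tuple(top)))["s"]
        # brute force over all size-m subsets confirms the top-z set maximizes ES
        from itertools import combinations

        best = max(
            brute_force_es(z["s"], set(c)) for c in combinations(z.index, m)
        )
        assert es == pytest.approx(best, abs=1e-12)

    def test_all_genes_degenerate_case(self, toy_zmatrix):
        es = gsva_like_score(toy_zmatrix, GeneSet("all", tuple(toy_zmatrix.index)))
        assert (es == 1.0).all()

    def test_gene_order_invariance(self, toy_zmatrix, toy_geneset, rng):
        es = gsva_like_score(toy_zmatrix, toy_geneset)
        perm = rng.permutation(len(toy_zmatrix))
        es_perm = gsva_like_score(toy_zmatrix.iloc[perm], toy_geneset)
        np.testing.assert_allclose(es.to_numpy(), es_perm.to_numpy(), atol=1e-12)

    def test_bounded_in_unit_interval(self, rng):
        z = pd.DataFrame(rng.normal(size=(40, 8)))
        z.index = [f"g{i}" for i in range(40)]
        es = gsva_like_score(z, GeneSet("s", ("g0", "g5", "g11", "g39")))
        assert ((es >= -1) & (es <= 1)).all()

    def test_absent_members_dropped_with_warning(self, toy_zmatrix):
        with pytest.warns(UserWarning, match="absent"):
            es = gsva_like_score(toy_zmatrix, GeneSet("s", ("g1", "nope")))
        np.testing.assert_allclose(
            es.to_numpy(),
            gsva_like_score(toy_zmatrix, GeneSet("s", ("g1",))).to_numpy(),
        )

    def test_no_member_present_raises(self, toy_zmatrix):
        with pytest.raises(ValueError):
            gsva_like_score(toy_zmatrix, GeneSet("s", ("absent",)))


class TestCoxis:
    def _matrix(self, cp_value, ci_value):
        from tlsmeta.signatures import coxis_ci_genes, coxis_cp_genes

        genes = list(coxis_cp_genes().members) + list(coxis_ci_genes().members)
        values = [[cp_value] * 2] * 9 + [[ci_value] * 2] * 15
        return pd.DataFrame(values, index=genes, columns=["s1", "s2"])

    def test_symmetry_equal_expression(self):
        scores = coxis_score(self._matrix(3.0, 3.0))
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-9)

    def test_direct_evaluation(self):
        # CP at log2-expr 2 (linear 3), CI at 1 (linear 1): log2(3/1)
        scores = coxis_score(self._matrix(2.0, 1.0))
        np.testing.assert_allclose(scores.to_numpy(), math.log2(3.0), atol=1e-5)

    def test_scale_invariance(self, rng):
        expr = self._matrix(2.5, 1.5) + rng.uniform(0, 1, size=(24, 2))
        doubled = np.log2(2.0 * (np.power(2.0, expr) - 1.0) + 1.0)
        np.testing.assert_allclose(
            coxis_score(expr).to_numpy(), coxis_score(doubled).to_numpy(), atol=1e-5
        )

    def test_il8_alias_resolves_to_cxcl8(self):
        expr = self._matrix(2.0, 1.0).rename(index={"IL8": "CXCL8"})
        scores = coxis_score(expr)
        np.testing.assert_allclose(scores.to_numpy(), math.log2(3.0), atol=1e-5)

    def test_all_cp_absent_raises(self):
        from tlsmeta.signatures import coxis_ci_genes

        expr = self._matrix(2.0, 1.0).loc[list(coxis_ci_genes().members)]
        with pytest.raises(ValueError):
            coxis_score(expr)


class TestTmb:
    def _table(self, **counts):
        full = {c: 0 for c in ("missense", "frameshift_indel", "stop_codon", "synonymous", "other")}
        full.update(counts)
        return MutationTable(samples=["s1"], counts={"s1": full})

    def test_division_rule(self):
        t = self._table(missense=60, frameshift_indel=10, stop_codon=6, synonymous=99)
        assert tmb(t, territory_mb=38.0)["s1"] == pytest.approx(2.0)

    def test_synonymous_excluded(self):
        assert tmb(self._table(synonymous=500, other=10))["s1"] == 0.0

    def test_zero_mutations(self):
        assert tmb(self._table())["s1"] == 0.0

    def test_additive_in_counts(self):
        a = self._table(missense=10)
        b = self._table(missense=25, stop_codon=3)
        combined = self._table(missense=35, stop_codon=3)
        assert tmb(a)["s1"] + tmb(b)["s1"] == pytest.approx(tmb(combined)["s1"])


class TestMedianStratify:
    def test_even_split(self):
        labels = median_stratify(pd.Series([1.0, 2.0, 3.0, 4.0]))
        assert labels.tolist() == ["low", "low", "high", "high"]

    def test_all_equal_warns_all_low(self):
        with pytest.warns(UserWarning, match="identical"):
            labels = median_stratify(pd.Series([5.0] * 4))
        assert labels.tolist() == ["low"] * 4

    def test_ties_assigned_low(self):
        labels = median_stratify(pd.Series([1.0, 2.0, 2.0, 9.0]))
        assert labels.tolist() == ["low", "low", "low", "high"]
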