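"""Spearman association, ranked lists, overlap, and volcano data."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coclin import (
    ExpressionMatrix,
    InvalidInputError,
    cohort_overlap,
    delta_feature,
    spearman_associate,
    volcano_data,
)


def _expr(values, genes=None, samples=None, **kw):
    arr = np.asarray(values, float)
    genes = genes or [f"G{i:03d}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(pd.DataFrame(arr, index=genes, columns=samples), **kw)


def _feature(values, samples=None):
    samples = samples or [f"S{j}" for j in range(len(values))]
    return pd.Series(np.asarray(values, float), index=samples, name="feat")


def rank_pearson_oracle(x: np.ndarray, f: np.ndarray) -> float:
    """Explicit ranking followed by Pearson on the ranks."""
    rx = stats.rankdata(x)
    rf = stats.rankdata(f)
    return float(np.corrcoef(rx, rf)[0, 1])


class TestDeltaFeature:
    def test_no_change(self):
        t0 = _feature([1.0, 2.0, 3.0])
        delta, excl = delta_feature(t0, t0, mode="absolute")
        assert (delta == 0).all() and excl == []

    def test_percent_matches_response_arithmetic(self):
        delta, _ = delta_feature(_feature([40.0]), _feature([20.0]), mode="percent")
        assert delta.iloc[0] == pytest.approx(-50.0)

    def test_percent_excludes_zero_baseline(self):
        delta, excl = delta_feature(
            _feature([0.0, 10.0]), _feature([5.0, 20.0]), mode="percent"
        )
        assert excl == ["S0"] and list(delta.index) == ["S1"]

    def test_no_shared_subjects_rejected(self):
        with pytest.raises(InvalidInputError):
            delta_feature(_feature([1.0], ["A"]), _feature([1.0], ["B"]))


class TestSpearmanAssociate:
    def test_perfect_monotone(self):
        expr = _expr([[1, 4, 9, 16, 25]])
        res = spearman_associate(expr, _feature([1, 2, 3, 4, 5]))
        assert res.table["rho"].iloc[0] == pytest.approx(1.0)

    def test_perfect_anti_monotone(self):
        expr = _expr([[25, 16, 9, 4, 1]])
        res = spearman_associate(expr, _feature([1, 2, 3, 4, 5]))
        assert res.table["rho"].iloc[0] == pytest.approx(-1.0)

    def test_worked_five_sample_example(self):
        # gene (2,1,4,3,5) vs feature (1,2,3,4,5): d^2 = 4, rho = 1 - 24/120 = 0.8,
        # confirmed by the explicit rank-then-Pearson oracle
        gene = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
        feat = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        assert rank_pearson_oracle(gene, feat) == pytest.approx(0.8)
        res = spearman_associate(_expr([gene]), _feature(feat))
        assert res.table["rho"].iloc[0] == pytest.approx(0.8, abs=1e-12)

    def test_matches_rank_oracle_on_random_matrix(self, rng):
        x = rng.normal(size=(50, 8))
        # inject ties to exercise average-rank handling
        x[:10] = np.round(x[:10])
        f = rng.normal(size=8)
        expr = _expr(np.abs(x) + 1.0)
        res = spearman_associate(expr, _feature(f))
        for i in range(50):
            expected = rank_pearson_oracle(np.abs(x[i]) + 1.0, f)
            assert abs(res.table["rho"].iloc[i] - expected) < 1e-12

    def test_exact_permutation_p_matches_enumeration_at_n5(self, rng):
        """n = 5: compare against a direct 5! = 120 permutation enumeration."""
        import itertools

        x = rng.lognormal(size=(6, 5))
        f = rng.normal(size=5)
        res = spearman_associate(_expr(x), _feature(f))
        for i in range(6):
            obs = abs(rank_pearson_oracle(x[i], f))
            count = sum(
                abs(rank_pearson_oracle(x[i], np.asarray(perm))) >= obs - 1e-12
                for perm in itertools.permutations(f)
            )
            assert res.table["p_value"].iloc[i] == pytest.approx(count / 120)

    def test_t_approximation_used_for_larger_n(self, rng):
        x = rng.lognormal(size=(4, 15))
        f = rng.normal(size=15)
        res = spearman_associate(_expr(x), _feature(f))
        for i in range(4):
            rho = res.table["rho"].iloc[i]
            t = rho * np.sqrt(13 / (1 - rho**2))
            assert res.table["p_value"].iloc[i] == pytest.approx(
                2 * stats.t.sf(abs(t), df=13)
            )

    def test_negating_feature_swaps_lists_and_negates_rho(self, rng):
        x = rng.lognormal(size=(40, 12))
        f = _feature(rng.normal(size=12))
        a = spearman_associate(_expr(x), f, n_top=10)
        b = spearman_associate(_expr(x), -f, n_top=10)
        np.testing.assert_allclose(
            a.table["rho"].to_numpy(), -b.table["rho"].to_numpy(), atol=1e-12
        )
        assert a.top_list == b.bottom_list
        assert a.bottom_list == b.top_list

    def test_lists_disjoint_truncated_and_sign_pure(self, rng):
        x = rng.lognormal(size=(200, 10))
        res = spearman_associate(_expr(x), _feature(rng.normal(size=10)), n_top=30)
        assert not set(res.top_list) & set(res.bottom_list)
        assert len(res.top_list) <= 30 and len(res.bottom_list) <= 30
        assert all(res.table.loc[g, "rho"] > 0 for g in res.top_list)
        assert all(res.table.loc[g, "rho"] < 0 for g in res.bottom_list)

    def test_constant_gene_rows_get_nan_and_are_excluded(self):
        x = np.array([[5.0] * 5, [1, 2, 3, 4, 5.0]])
        res = spearman_associate(_expr(x), _feature([1, 2, 3, 4, 5]))
        assert np.isnan(res.table["rho"].iloc[0])
        assert res.table.index[0] not in res.top_list + res.bottom_list

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman_associate(_expr(np.ones((2, 2))), _feature([1, 2]))

    def test_constant_feature_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman_associate(_expr(np.ones((2, 4))), _feature([3, 3, 3, 3]))

    def test_accepts_signed_delta_frame(self, rng):
        frame = pd.DataFrame(
            rng.normal(size=(20, 8)),
            index=[f"G{i}" for i in range(20)],
            columns=[f"S{j}" for j in range(8)],
        )
        res = spearman_associate(frame, _feature(rng.normal(size=8)), cohort="PDX")
        assert res.cohort == "PDX" and len(res.table) == 20

    def test_type_one_error_calibrated_under_global_null(self, rng):
        # feature independent of expression: p < 0.05 in ~5% of 1000 genes
        x = rng.lognormal(size=(1000, 20))
        res = spearman_associate(_expr(x), _feature(rng.normal(size=20)))
        frac = float((res.table["p_value"] < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) < 3 * se


class TestOverlapAndVolcano:
    def _result(self, genes, top, bottom):
        table = pd.DataFrame(
            {"rho": 0.1, "p_value": 0.5, "q_value": 0.8, "n": 5},
            index=pd.Index(genes, name="gene_symbol"),
        )
        from coclin import AssociationResult

        return AssociationResult(table=table, top_list=top, bottom_list=bottom)

    def test_identical_lists(self):
        r = self._result(list("ABC"), list("ABC"), [])
        o = cohort_overlap(r, r, region="top")
        assert o.counts == {"patient_only": 0, "pdx_only": 0, "shared": 3}

    def test_disjoint_lists(self):
        a = self._result(list("ABCD"), ["A", "B"], [])
        b = self._result(list("ABCD"), ["C", "D"], [])
        assert cohort_overlap(a, b, region="top").counts["shared"] == 0

    def test_partial_overlap_counts(self):
        a = self._result(list("ABCD"), ["A", "B", "C"], [])
        b = self._result(list("ABCD"), ["B", "C", "D"], [])
        o = cohort_overlap(a, b, region="top")
        assert o.counts == {"patient_only": 1, "pdx_only": 1, "shared": 2}
        assert o.genes["shared"] == ["B", "C"]

    def test_mismatched_universes_warn_and_restrict(self):
        a = self._result(list("ABC"), ["A", "B"], [])
        b = self._result(list("BCD"), ["B", "D"], [])
        with pytest.warns(UserWarning):
            o = cohort_overlap(a, b, region="top")
        assert o.counts["shared"] == 1          # only B lies in both universes

    def test_volcano_rows_and_log(self, rng):
        x = rng.lognormal(size=(30, 10))
        x[0] = 7.0                               # one constant row
        res = spearman_associate(_expr(x), _feature(rng.normal(size=10)))
        table = volcano_data(res)
        assert len(table) == 29                  # constant gene dropped
        gene = table.index[0]
        assert table.loc[gene, "neg_log10_p"] == pytest.approx(
            -np.log10(res.table.loc[gene, "p_value"])
        )

    def test_minus_log10_of_percent_p(self):
        assert -np.log10(0.01) == pytest.approx(2.0)
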