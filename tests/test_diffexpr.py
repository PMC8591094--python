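import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from subnetmark.data_io import ExpressionMatrix, GeneList, ValidationError
from subnetmark.diffexpr import (
    bh_adjust,
    differential_expression,
    intersect_seeds,
    select_degs,
)
from subnetmark.synthetic import SyntheticSpec, gen_expression

from _oracles import bh_stepup_bruteforce


def _expr(case_rows, control_rows, genes=None):
    case_rows = np.asarray(case_rows, float)
    control_rows = np.asarray(control_rows, float)
    values = np.hstack([case_rows, control_rows])
    n_case, n_control = case_rows.shape[1], control_rows.shape[1]
    samples = [f"T{i}" for i in range(n_case)] + [f"N{i}" for i in range(n_control)]
    labels = {s: ("case" if s.startswith("T") else "control") for s in samples}
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(genes, samples, values, labels)


class TestDifferentialExpression:
    def test_signed_fc_up(self):
        expr = _expr([[5.0, 5.0, 5.0]], [[3.0, 3.0, 3.1]])
        row = differential_expression(expr).table.iloc[0]
        assert row["signed_fc"] == pytest.approx(2 ** (5.0 - row["mean_control"]))
        assert row["direction"] == "up"
        assert row["signed_fc"] > 3.5

    def test_signed_fc_symmetry_on_label_swap(self):
        rng = np.random.default_rng(0)
        case = rng.normal(5, 1, (20, 6))
        control = rng.normal(4, 1, (20, 5))
        a = differential_expression(_expr(case, control)).table
        # swap roles: controls become cases
        swapped = differential_expression(_expr(control, case)).table
        assert np.allclose(a["signed_fc"], -swapped["signed_fc"], atol=1e-12)
        assert np.allclose(a["p_value"], swapped["p_value"], atol=1e-12)

    def test_identical_groups_null(self):
        block = [[3.0, 4.0, 5.0]]
        expr = _expr(block, block)
        row = differential_expression(expr).table.iloc[0]
        assert row["p_value"] == pytest.approx(1.0, abs=1e-9)
        assert abs(row["signed_fc"]) == pytest.approx(1.0)

    def test_zero_variance_gene_handled(self):
        expr = _expr([[5.0, 5.0]], [[3.0, 3.0]])
        with pytest.warns(UserWarning, match="zero within-group variance"):
            row = differential_expression(expr).table.iloc[0]
        assert row["p_value"] == 0.0

    def test_small_class_rejected(self):
        expr = _expr([[1.0]], [[2.0, 3.0]])
        with pytest.raises(ValidationError, match=">=2 samples"):
            differential_expression(expr)

    def test_matches_scipy_pooled_ttest(self):
        from scipy import stats

        rng = np.random.default_rng(3)
        case = rng.normal(0, 1, (50, 8))
        control = rng.normal(0, 1, (50, 7))
        table = differential_expression(_expr(case, control)).table
        _, p_ref = stats.ttest_ind(case, control, axis=1, equal_var=True)
        assert np.allclose(table["p_value"], p_ref, atol=1e-12)

    def test_invariants_hold(self):
        rng = np.random.default_rng(4)
        table = differential_expression(
            _expr(rng.normal(5, 1, (100, 5)), rng.normal(5, 1, (100, 5)))
        ).table
        assert (np.abs(table["signed_fc"]) >= 1).all()
        assert (table["adj_p"] >= table["p_value"] - 1e-15).all()
        up = table["direction"] == "up"
        assert (table.loc[up, "mean_case"] > table.loc[up, "mean_control"]).all()


class TestBHAdjust:
    def test_derived_example(self):
        # brute-force step-up on [0.005, 0.01, 0.03, 0.04]:
        # ranks 1..4, scaled (0.02, 0.02, 0.04, 0.04), running min from top
        assert np.allclose(
            bh_adjust([0.005, 0.01, 0.03, 0.04]), [0.02, 0.02, 0.04, 0.04]
        )

    def test_cap_at_one(self):
        assert np.allclose(bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.123]) == pytest.approx([0.123])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.2, 1.2])

    @settings(derandomize=True, max_examples=200)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=60))
    def test_matches_bruteforce_definition(self, pvals):
        assert np.allclose(bh_adjust(pvals), bh_stepup_bruteforce(pvals), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        for _ in range(20):
            p = rng.random(rng.integers(1, 100))
            _, ref, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), ref, atol=1e-12)

    def test_monotone_in_sorted_order(self):
        rng = np.random.default_rng(6)
        p = rng.random(80)
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-15).all()
        assert ((adj >= 0) & (adj <= 1)).all()


class TestSelectDegs:
    def _result(self, fcs, qs):
        import pandas as pd
        from subnetmark.diffexpr import DifferentialResult

        table = pd.DataFrame(
            {
                "mean_case": 0.0, "mean_control": 0.0,
                "signed_fc": fcs, "p_value": qs, "adj_p": qs,
                "direction": ["up" if f > 0 else "down" for f in fcs],
            },
            index=[f"g{i}" for i in range(len(fcs))],
        )
        return DifferentialResult(table)

    def test_strict_boundaries(self):
        res = self._result([2.0, 4.0, -8.0, 3.0], [0.01, 0.049, 0.05, 0.2])
        selected = select_degs(res).symbols
        assert selected == ["g1"]  # g0 fails |fc| > 2 strict; g2 fails q < 0.05

    def test_empty_selection_warns(self):
        res = self._result([1.5], [0.9])
        with pytest.warns(UserWarning, match="no genes pass"):
            assert len(select_degs(res)) == 0

    def test_count_monotone_in_cutoffs(self):
        rng = np.random.default_rng(7)
        fcs = rng.uniform(-10, 10, 200)
        fcs = np.sign(fcs) * np.maximum(np.abs(fcs), 1)
        qs = rng.random(200)
        res = self._result(fcs, qs)
        counts = [
            len(select_degs(res, fc_cut=fc, q_cut=q))
            for fc, q in [(1.0, 0.2), (2.0, 0.2), (4.0, 0.2), (4.0, 0.1), (4.0, 0.01)]
        ]
        assert counts == sorted(counts, reverse=True)


class TestIntersectSeeds:
    def test_set_algebra(self):
        out = intersect_seeds(GeneList(["A", "B", "C"]), GeneList(["B", "C", "D"]))
        assert out.symbols == {"B", "C"}

    def test_disjoint_warns_empty(self):
        with pytest.warns(UserWarning, match="disjoint"):
            out = intersect_seeds(GeneList(["A"]), GeneList(["B"]))
        assert out.symbols == set()

    def test_identity(self):
        out = intersect_seeds(GeneList(["A", "B"]), GeneList(["A", "B"]))
        assert out.symbols == {"A", "B"}


def test_recovery_on_synthetic_defaults():
    """True DE genes at log2 effect 2.0, sd 0.5, n=20+20: recall >= 0.9 and
    empirical FDR <= 0.1 at q < 0.05."""
    spec = SyntheticSpec(n_case=20, n_control=20, rng_seed=42)
    expr, truth = gen_expression(spec)
    degs = set(select_degs(differential_expression(expr)).symbols)
    true_de = {g for g, t in truth.items() if t != 0}
    recall = len(degs & true_de) / len(true_de)
    fdr = len(degs - true_de) / max(len(degs), 1)
    assert recall >= 0.9
    assert fdr <= 0.1
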