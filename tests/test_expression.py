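import numpy as np
import pandas as pd
import pytest

from herbnet.errors import DegenerateInputError, ValidationError
from herbnet.expression import (
    delta_delta_ct,
    fold_direction_report,
    group_summary,
    welch_compare,
    welch_table,
)
from herbnet.synthetic import SimConfig, gen_expression_matrix
from oracles import welch_oracle


def matrix_of(rows: dict, n_ctrl: int, n_case: int):
    samples = [f"c{i}" for i in range(n_ctrl)] + [f"t{i}" for i in range(n_case)]
    m = pd.DataFrame(rows, index=samples).T
    groups = pd.Series(["control"] * n_ctrl + ["case"] * n_case, index=samples)
    return m, groups


class TestWelch:
    def test_equal_means_give_t_zero(self):
        m, g = matrix_of({"G": [1, 2, 3, 3, 2, 1]}, 3, 3)
        r = welch_compare(m, g, "G")
        assert r.t == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_strong_shift_matches_closed_form_oracle(self):
        a, b = [0, 0.1, -0.1, 0.05], [4, 4.1, 3.9, 4.05]
        m, g = matrix_of({"G": a + b}, 4, 4)
        r = welch_compare(m, g, "G")
        t_ref, p_ref = welch_oracle(a, b)
        assert r.t == pytest.approx(t_ref, rel=1e-10)
        assert r.p == pytest.approx(p_ref, rel=1e-10)
        assert r.p < 0.001 and r.diff > 0

    def test_zero_variance_both_groups_is_degenerate(self):
        m, g = matrix_of({"G": [2, 2, 2, 2, 2, 2]}, 3, 3)
        with pytest.raises(DegenerateInputError):
            welch_compare(m, g, "G")

    def test_unknown_gene_rejected(self):
        m, g = matrix_of({"G": [1, 2, 3, 4]}, 2, 2)
        with pytest.raises(ValidationError):
            welch_compare(m, g, "NOPE")

    def test_shift_invariance_and_label_swap(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 10)
        m, g = matrix_of({"G": list(vals)}, 5, 5)
        r = welch_compare(m, g, "G")
        m2, _ = matrix_of({"G": list(vals + 100.0)}, 5, 5)
        r2 = welch_compare(m2, g, "G")
        assert r2.t == pytest.approx(r.t, rel=1e-9)
        swapped = g.map({"control": "case", "case": "control"})
        r3 = welch_compare(m, swapped, "G")
        assert r3.t == pytest.approx(-r.t, rel=1e-9)
        assert r3.p == pytest.approx(r.p, rel=1e-9)

    def test_vectorised_table_matches_per_gene_calls(self):
        cfg = SimConfig(seed=2, n_genes=30, n_per_group=4)
        m, groups, _ = gen_expression_matrix(cfg)
        table = welch_table(m, groups)
        for gene in list(m.index)[:10]:
            r = welch_compare(m, groups, gene)
            assert table.at[gene, "t"] == pytest.approx(r.t, rel=1e-9)
            assert table.at[gene, "p"] == pytest.approx(r.p, rel=1e-9)


class TestDeltaDeltaCt:
    @staticmethod
    def ct_frame(wells):
        return pd.DataFrame(wells, columns=["sample", "group", "gene", "ct"])

    def test_worked_example_doubling(self):
        """Control Ct 25/20, treated 24/20: one cycle less for the same
        reference means exactly twofold relative expression."""
        ct = self.ct_frame(
            [
                ("s1", "control", "target", 25.0),
                ("s1", "control", "reference", 20.0),
                ("s2", "treated", "target", 24.0),
                ("s2", "treated", "reference", 20.0),
            ]
        )
        rel = delta_delta_ct(ct)
        assert rel.at["s2", "rel_expr"] == pytest.approx(2.0)
        assert rel.at["s1", "rel_expr"] == pytest.approx(1.0)

    def test_sample_at_calibrator_is_one(self):
        ct = self.ct_frame(
            [
                ("a", "control", "target", 26.0),
                ("a", "control", "reference", 20.0),
                ("b", "treated", "target", 27.0),
                ("b", "treated", "reference", 21.0),
            ]
        )
        rel = delta_delta_ct(ct)
        assert rel.at["b", "rel_expr"] == pytest.approx(1.0)

    def test_single_control_sample_is_its_own_calibrator(self):
        ct = self.ct_frame(
            [("only", "control", "target", 30.0), ("only", "control", "reference", 18.0)]
        )
        assert delta_delta_ct(ct).at["only", "rel_expr"] == pytest.approx(1.0)

    def test_control_geometric_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        wells = []
        for i in range(6):
            grp = "control" if i < 3 else "treated"
            wells.append((f"s{i}", grp, "target", float(rng.uniform(22, 30))))
            wells.append((f"s{i}", grp, "reference", float(rng.uniform(15, 20))))
        rel = delta_delta_ct(self.ct_frame(wells))
        ctrl = rel[rel["group"] == "control"]["rel_expr"]
        assert np.exp(np.log(ctrl).mean()) == pytest.approx(1.0, abs=1e-12)
        summary = group_summary(rel)
        assert set(summary.index) == {"control", "treated"}

    def test_missing_reference_names_sample(self):
        ct = self.ct_frame(
            [
                ("s1", "control", "target", 25.0),
                ("s1", "control", "reference", 20.0),
                ("s2", "treated", "target", 24.0),
            ]
        )
        with pytest.raises(ValidationError, match="s2"):
            delta_delta_ct(ct)


class TestDirectionCalls:
    def test_planted_genes_called_correctly(self):
        cfg = SimConfig(seed=9, n_genes=100, n_per_group=5, effect_log2=4.0, noise_sd=0.5)
        m, groups, truth = gen_expression_matrix(cfg)
        table, skipped = fold_direction_report(
            m, groups, sorted(truth.planted_up | truth.planted_down)
        )
        assert not skipped
        for g in truth.planted_up:
            assert table.at[g, "direction"] == "up"
        for g in truth.planted_down:
            assert table.at[g, "direction"] == "down"

    def test_unknown_genes_skipped_not_fatal(self):
        m, groups = matrix_of({"G": [1, 2, 3, 4, 2, 3]}, 3, 3)
        table, skipped = fold_direction_report(m, groups, ["G", "MISSING"])
        assert skipped == ["MISSING"]
        assert list(table.index) == ["G"]

    def test_empty_gene_list(self):
        m, groups = matrix_of({"G": [1, 2, 3, 4]}, 2, 2)
        table, skipped = fold_direction_report(m, groups, [])
        assert table.empty and skipped == []
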