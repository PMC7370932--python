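"""Expression thresholding, tissue specificity, DE calls, and 2^-ddCt."""

import math

import numpy as np
import pandas as pd
import pytest

from erf_survey import expression_profiles as ep, synthetic_data as sd


def _matrix(values: dict[str, list[float]], conditions: list[str], n_reps: int):
    cols = {}
    mapping = {}
    for ci, cond in enumerate(conditions):
        for rep in range(1, n_reps + 1):
            s = f"{cond}_r{rep}"
            cols[s] = [values[g][ci] for g in values]
            mapping[s] = (cond, rep)
    return ep.ExpressionMatrix(
        values=pd.DataFrame(cols, index=list(values)), condition_of_sample=mapping
    )


class TestExpressedCalls:
    def test_below_one_not_expressed_and_boundary_expressed(self):
        m = _matrix({"g1": [0.5, 1.0], "g2": [0.0, 3.0]}, ["root", "leaf"], 2)
        table = ep.call_expressed(m)
        assert not table.at["g1", "root"] and table.at["g1", "leaf"]
        assert not table.at["g2", "root"] and table.at["g2", "leaf"]

    def test_all_zero_gene(self):
        m = _matrix({"g": [0.0, 0.0]}, ["root", "leaf"], 2)
        assert not ep.call_expressed(m).loc["g"].any()

    def test_replicate_permutation_invariance(self):
        m, _ = sd.generate_expression(50, seed=1)
        shuffled = ep.ExpressionMatrix(
            values=m.values[list(m.values.columns)[::-1]],
            condition_of_sample=dict(m.condition_of_sample),
        )
        pd.testing.assert_frame_equal(
            ep.call_expressed(m).sort_index(axis=1),
            ep.call_expressed(shuffled).sort_index(axis=1),
        )


class TestTissueSpecificity:
    def test_rule_application(self):
        m = _matrix(
            {"g1": [50.0, 5.0, 2.0], "g2": [3.0, 2.9, 0.1]}, ["root", "leaf", "ear"], 2
        )
        out = ep.tissue_specificity(m)
        assert out.at["g1", "top_tissue"] == "root" and out.at["g1", "specific"]
        assert out.at["g2", "top_tissue"] == "root" and not out.at["g2", "specific"]

    def test_single_condition_rejected(self):
        m = _matrix({"g": [1.0]}, ["root"], 2)
        with pytest.raises(ValueError):
            ep.tissue_specificity(m)

    def test_planted_specific_genes_recovered(self):
        m, truth = sd.generate_expression(
            400, specific_fraction=0.15, specific_fold=10.0, seed=6
        )
        out = ep.tissue_specificity(m)
        planted = {g: t for g, t in truth.specific_tissue.items() if t}
        recovered = sum(
            1
            for g, t in planted.items()
            if out.at[g, "specific"] and out.at[g, "top_tissue"] == t
        )
        assert recovered / len(planted) >= 0.99


class TestLogTransform:
    def test_values(self):
        m = _matrix({"g": [0.0, 99.0]}, ["a", "b"], 2)
        out = ep.log_transform(m)
        assert out.values.iloc[0, 0] == pytest.approx(0.0)
        assert out.condition_means().at["g", "b"] == pytest.approx(2.0)

    def test_monotone(self):
        m = _matrix({"g1": [1.0, 5.0], "g2": [4.0, 2.0]}, ["a", "b"], 2)
        out = ep.log_transform(m)
        assert (out.values.iloc[0] < out.values.iloc[1]).tolist() == (
            m.values.iloc[0] < m.values.iloc[1]
        ).tolist()


class TestDeCalls:
    def test_arithmetic_and_threshold(self):
        m = _matrix({"g": [40.0, 10.0]}, ["salt", "control"], 2)
        (call,) = ep.call_de(m, "salt", "control")
        assert call.log10_ratio == pytest.approx(math.log10(41 / 11))
        assert call.direction == "up"

    def test_equal_means_none(self):
        m = _matrix({"g": [10.0, 10.0]}, ["salt", "control"], 2)
        assert ep.call_de(m, "salt", "control")[0].direction == "none"

    def test_contrast_swap_antisymmetry(self):
        m, _ = sd.generate_expression(
            100, de_spec={("salt", "control"): (0.1, 0.1, 4.0)}, seed=2
        )
        fwd = {c.gene_id: c for c in ep.call_de(m, "salt", "control")}
        rev = {c.gene_id: c for c in ep.call_de(m, "control", "salt")}
        flip = {"up": "down", "down": "up", "none": "none"}
        for g in fwd:
            assert rev[g].direction == flip[fwd[g].direction]
            assert rev[g].log10_ratio == pytest.approx(-fwd[g].log10_ratio)

    def test_planted_de_recovery(self):
        m, truth = sd.generate_expression(
            500, de_spec={("salt", "control"): (0.1, 0.1, 4.0)}, seed=3
        )
        got = {c.gene_id: c.direction for c in ep.call_de(m, "salt", "control")}
        tr = truth.de_direction[("salt", "control")]
        planted = [g for g, d in tr.items() if d != "none"]
        nulls = [g for g, d in tr.items() if d == "none"]
        sens = sum(1 for g in planted if got[g] == tr[g]) / len(planted)
        fpr = sum(1 for g in nulls if got[g] != "none") / len(nulls)
        assert sens >= 0.95 and fpr <= 0.02

    def test_noiseless_recovery_exact(self):
        m, truth = sd.generate_expression(
            200, de_spec={("salt", "control"): (0.1, 0.1, 4.0)}, noise_sd=0.0, seed=4
        )
        got = {c.gene_id: c.direction for c in ep.call_de(m, "salt", "control")}
        tr = truth.de_direction[("salt", "control")]
        planted = [g for g, d in tr.items() if d != "none"]
        assert all(got[g] == tr[g] for g in planted)


class TestDdct:
    def test_fold_identities(self):
        table, _ = sd.generate_ct_table(
            ["g"], {"g": {"3h": 4.0, "6h": 1.0}}, noise_sd=0.0, seed=0
        )
        res = {r.timepoint: r for r in ep.ddct(table, "g", "reference", "0h")}
        assert res["0h"].relative_quantity == pytest.approx(1.0)
        assert res["3h"].relative_quantity == pytest.approx(4.0)
        assert res["6h"].relative_quantity == pytest.approx(1.0)

    def test_noiseless_eightfold_exact(self):
        table, _ = sd.generate_ct_table(["g"], {"g": {"3h": 8.0}}, noise_sd=0.0, seed=0)
        res = {r.timepoint: r for r in ep.ddct(table, "g", "reference", "0h")}
        assert res["3h"].relative_quantity == 8.0

    def test_planted_induction_significant(self):
        table, _ = sd.generate_ct_table(
            ["g"], {"g": {"3h": 8.0}}, n_reps=6, noise_sd=0.1, seed=5
        )
        res = {r.timepoint: r for r in ep.ddct(table, "g", "reference", "0h")}
        assert 6.0 <= res["3h"].relative_quantity <= 10.7
        assert res["3h"].p_value < 0.01 and res["3h"].significance == "**"

    def test_target_equals_reference_rq_one(self):
        table, _ = sd.generate_ct_table(["g"], {"g": {"3h": 8.0}}, seed=6)
        for r in ep.ddct(table, "reference", "reference", "0h"):
            assert r.relative_quantity == pytest.approx(1.0)

    def test_missing_reference_rejected(self):
        table, _ = sd.generate_ct_table(["g"], {"g": {"3h": 2.0}}, seed=7)
        with pytest.raises(ValueError, match="missing"):
            ep.ddct(table, "g", "nope", "0h")

    def test_significance_stars_consistent(self):
        table, _ = sd.generate_ct_table(
            ["g"], {"g": {"3h": 8.0, "6h": 1.0}}, n_reps=6, noise_sd=0.1, seed=8
        )
        for r in ep.ddct(table, "g", "reference", "0h"):
            if r.p_value is None:
                assert r.significance == "ns"
            elif r.p_value < 0.01:
                assert r.significance == "**"
            elif r.p_value < 0.05:
                assert r.significance == "*"
            else:
                assert r.significance == "ns"
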