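"""CMA network weighting and the activation score."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmakit import (
    CmaNetwork,
    CmaNetworkElement,
    assign_weights,
    compare_scores,
    compute_cma_score,
    generate_network_expression,
)
from cmakit.io import ExpressionTable


def make_network(rows):
    return CmaNetwork(
        [
            CmaNetworkElement(
                gene_id=g, functional_group=grp, direction=d, paralog_family=fam
            )
            for g, grp, d, fam in rows
        ]
    )


def expr_table(data, samples, genes):
    return ExpressionTable(pd.DataFrame(data, index=samples, columns=genes, dtype=float))


class TestAssignWeights:
    def test_singleton_gene_gets_weight_one(self):
        net = assign_weights(make_network([("g1", "effector", +1, "f1")]))
        assert net["g1"].weight == 1.0

    def test_lamp2a_pair_splits_family_weight_of_two(self):
        net = assign_weights(
            make_network(
                [
                    ("lamp2a_c31", "effector", +1, "lamp2a"),
                    ("lamp2a_c14", "effector", +1, "lamp2a"),
                ]
            )
        )
        assert net["lamp2a_c31"].weight == 1.0
        assert net["lamp2a_c14"].weight == 1.0

    def test_three_member_family_each_one_third(self):
        net = assign_weights(
            make_network([(f"g{i}", "effector", +1, "fam") for i in range(3)])
        )
        for i in range(3):
            assert net[f"g{i}"].weight == pytest.approx(1 / 3)

    def test_measured_lamp2a_contributions_respected(self):
        net = assign_weights(
            make_network(
                [
                    ("lamp2a_c31", "effector", +1, "lamp2a"),
                    ("lamp2a_c14", "effector", +1, "lamp2a"),
                ]
            ),
            lamp2a_contributions={"lamp2a_c31": 0.8, "lamp2a_c14": 0.2},
        )
        assert net["lamp2a_c31"].weight == pytest.approx(1.6)
        assert net["lamp2a_c14"].weight == pytest.approx(0.4)

    def test_contributions_must_sum_to_one(self):
        base = make_network(
            [
                ("lamp2a_c31", "effector", +1, "lamp2a"),
                ("lamp2a_c14", "effector", +1, "lamp2a"),
            ]
        )
        with pytest.raises(ValueError, match="sum to 1"):
            assign_weights(
                base, lamp2a_contributions={"lamp2a_c31": 0.8, "lamp2a_c14": 0.3}
            )

    def test_explicit_weight_overrides_derived(self):
        net = CmaNetwork(
            [
                CmaNetworkElement("g1", "effector", +1, "f1", explicit_weight=0.7),
                CmaNetworkElement("g2", "effector", +1, "f1"),
            ]
        )
        weighted = assign_weights(net)
        assert weighted["g1"].weight == 0.7
        assert weighted["g2"].weight == 0.5

    @settings(max_examples=100, deadline=None)
    @given(
        st.dictionaries(
            st.sampled_from(["lamp2a", "fam_a", "fam_b", "fam_c"]),
            st.integers(min_value=1, max_value=5),
            min_size=1,
        )
    )
    def test_family_weight_conservation(self, family_sizes):
        """Σ weights in every family is 1, or 2 for the lamp2a family."""
        rows = []
        for fam, size in family_sizes.items():
            for i in range(size):
                rows.append((f"{fam}_{i}", "effector", +1, fam))
        net = assign_weights(make_network(rows))
        for fam, members in net.families.items():
            total = sum(el.weight for el in members)
            expected = 2.0 if fam == "lamp2a" else 1.0
            assert total == pytest.approx(expected, abs=1e-12)


class TestComputeCmaScore:
    def test_single_positive_gene_score_equals_log2fc(self):
        net = assign_weights(make_network([("g1", "effector", +1, "f1")]))
        table = expr_table([[1.0], [8.0]], ["ref", "s1"], ["g1"])
        results = compute_cma_score(table, net, reference_sample_ids=["ref"])
        by_id = {r.sample_id: r.score for r in results}
        assert by_id["s1"] == pytest.approx(3.0)
        assert by_id["ref"] == pytest.approx(0.0)

    def test_negative_modulator_subtracts(self):
        net = assign_weights(
            make_network(
                [("g1", "effector", +1, "f1"), ("g2", "negative_modulator", -1, "f2")]
            )
        )
        table = expr_table([[1.0, 1.0], [8.0, 4.0]], ["ref", "s1"], ["g1", "g2"])
        results = compute_cma_score(table, net, reference_sample_ids=["ref"])
        by_id = {r.sample_id: r.score for r in results}
        assert by_id["s1"] == pytest.approx(3.0 - 2.0)

    def test_reference_group_mean_score_is_zero(self, network):
        expr, truth = generate_network_expression(
            network, {"kind": "stressor", "fold": 2.0}, n_per_group=5, seed=11
        )
        results = compute_cma_score(
            expr, network, reference_sample_ids=truth["control_samples"]
        )
        ctrl = [r.score for r in results if r.sample_id.startswith("control")]
        assert np.mean(ctrl) == pytest.approx(0.0, abs=1e-9)

    def test_knockout_scores_strictly_below_controls(self, network):
        expr, truth = generate_network_expression(
            network,
            {"kind": "knockout", "gene_id": "lamp2a_c31"},
            n_per_group=6,
            seed=5,
        )
        results = compute_cma_score(
            expr, network, reference_sample_ids=truth["control_samples"]
        )
        ctrl = [r.score for r in results if r.sample_id.startswith("control")]
        ko = [r.score for r in results if r.sample_id.startswith("treated")]
        assert max(ko) < min(ctrl)

    def test_stressor_shift_equals_sum_of_positive_weights(self, network):
        expr, truth = generate_network_expression(
            network,
            {"kind": "stressor", "fold": 2.0},
            n_per_group=4,
            noise_sd_log2=0.0,
            seed=0,
        )
        results = compute_cma_score(
            expr, network, reference_sample_ids=truth["control_samples"]
        )
        positive_weight = sum(
            el.weight for el in network.elements if el.direction == +1
        )
        treated = [r.score for r in results if r.sample_id.startswith("treated")]
        ctrl = [r.score for r in results if r.sample_id.startswith("control")]
        assert np.mean(treated) - np.mean(ctrl) == pytest.approx(positive_weight)

    def test_linearity_doubling_one_gene(self, network):
        genes = network.gene_ids
        base = expr_table(
            np.ones((3, len(genes))), ["ref1", "ref2", "s1"], genes
        )
        doubled = base.values.copy()
        doubled.loc["s1", "gfap"] = 2.0
        r0 = compute_cma_score(base, network, reference_sample_ids=["ref1", "ref2"])
        r1 = compute_cma_score(
            ExpressionTable(doubled), network, reference_sample_ids=["ref1", "ref2"]
        )
        s0 = {r.sample_id: r.score for r in r0}["s1"]
        s1 = {r.sample_id: r.score for r in r1}["s1"]
        el = network["gfap"]
        assert s1 - s0 == pytest.approx(el.weight * el.direction * 1.0)

    def test_gene_column_order_irrelevant(self, network):
        expr, truth = generate_network_expression(network, n_per_group=3, seed=7)
        shuffled = ExpressionTable(expr.values[expr.values.columns[::-1]])
        a = compute_cma_score(expr, network, reference_sample_ids=truth["control_samples"])
        b = compute_cma_score(
            shuffled, network, reference_sample_ids=truth["control_samples"]
        )
        for ra, rb in zip(a, b):
            assert ra.score == pytest.approx(rb.score, rel=1e-12)

    def test_all_network_genes_missing_rejected(self, network):
        table = expr_table([[1.0], [2.0]], ["ref", "s1"], ["unrelated_gene"])
        with pytest.raises(ValueError, match="all network genes"):
            compute_cma_score(table, network, reference_sample_ids=["ref"])

    def test_missing_gene_renormalization_keeps_total_weight(self, network):
        """A tissue not expressing one gene is not biased toward zero."""
        genes = [g for g in network.gene_ids if g != "plin2"]
        vals = np.ones((3, len(genes)))
        vals[2] = 2.0  # uniform doubling of every expressed gene
        table = expr_table(vals, ["ref1", "ref2", "s1"], genes)
        results = compute_cma_score(
            table, network, reference_sample_ids=["ref1", "ref2"],
            missing_policy="exclude_renormalize",
        )
        r = {x.sample_id: x for x in results}["s1"]
        # renormalised weights sum to the full network total
        assert sum(abs(v) for v in r.contributions.values()) == pytest.approx(
            network.total_abs_weight()
        )
        assert "plin2" in r.genes_excluded
        assert r.n_genes_used + len(r.genes_excluded) == len(network.elements)

    def test_accounting_invariant(self, network):
        expr, truth = generate_network_expression(
            network, {"kind": "knockout", "gene_id": "mtor"}, n_per_group=3, seed=2
        )
        results = compute_cma_score(
            expr, network, reference_sample_ids=truth["control_samples"]
        )
        for r in results:
            assert r.n_genes_used + len(r.genes_excluded) == len(network.elements)

    def test_undetected_exclusion_policy(self, network):
        """Passing -inf as the floor excludes undetected cells instead."""
        expr, truth = generate_network_expression(
            network,
            {"kind": "knockout", "gene_id": "lamp2a_c31"},
            n_per_group=3,
            noise_sd_log2=0.0,
            seed=0,
        )
        results = compute_cma_score(
            expr, network, reference_sample_ids=truth["control_samples"],
            undetected_floor_log2=float("-inf"),
        )
        treated = [r for r in results if r.sample_id.startswith("treated")]
        assert all("lamp2a_c31" in r.genes_excluded for r in treated)


class TestCompareScores:
    def _results(self, network, seed, design=None):
        expr, truth = generate_network_expression(
            network, design or {"kind": "stressor", "fold": 2.0}, seed=seed
        )
        results = compute_cma_score(
            expr, network, reference_sample_ids=truth["control_samples"]
        )
        labels = {
            r.sample_id: ("treated" if r.sample_id.startswith("treated") else "control")
            for r in results
        }
        return results, labels

    def test_identical_groups_not_significant(self, network):
        results, labels = self._results(network, seed=3)
        # relabel so both "groups" are samples from the same population
        ctrl = [r for r in results if r.sample_id.startswith("control")]
        labels = {r.sample_id: ("a" if i % 2 else "b") for i, r in enumerate(ctrl)}
        summary = compare_scores(ctrl, labels)
        assert summary["p_value"] > 0.05

    def test_strong_offset_detected_with_correct_sign(self, network):
        results, labels = self._results(network, seed=4)
        summary = compare_scores(results, labels)
        assert summary["p_value"] < 0.01
        assert summary["mean_difference"] > 0  # treated - control

    def test_group_of_one_rejected(self, network):
        results, labels = self._results(network, seed=5)
        tiny = {sid: g for sid, g in labels.items()}
        keep = [r for r in results if r.sample_id != "treated_1"]
        only = {r.sample_id: tiny[r.sample_id] for r in keep
                if tiny[r.sample_id] == "control" or r.sample_id == "treated_2"}
        subset = [r for r in keep if r.sample_id in only]
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_scores(subset, only)

    def test_two_way_anova_reports_both_factors(self, network):
        rng = np.random.default_rng(0)
        results = []
        labels = {}
        for tissue in ("liver", "gills"):
            for condition in ("normoxia", "hypoxia"):
                for i in range(4):
                    sid = f"{tissue}_{condition}_{i}"
                    score = (1.5 if condition == "hypoxia" else 0.0) + rng.normal(0, 0.3)
                    from cmakit.score import CmaScoreResult

                    results.append(
                        CmaScoreResult(sid, score, 10, [], "log2_fold_change")
                    )
                    labels[sid] = (tissue, condition)
        summary = compare_scores(results, labels, design="tissue_by_condition")
        assert set(summary["anova"]) == {"C(tissue)", "C(condition)"}
        assert summary["anova"]["C(condition)"]["p_value"] < 0.01
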