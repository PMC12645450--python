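import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import perturbnet as pn
from perturbnet.io import InteractionNetwork, ValidationError

from conftest import make_expression


class TestRankTransform:
    def test_basic_ascending_ranks(self):
        expr = make_expression([[5.0], [2.0], [9.0]], genes=["gA", "gB", "gC"])
        ranks = pn.rank_transform(expr)
        assert ranks.ranks.iloc[:, 0].tolist() == [2.0, 1.0, 3.0]

    def test_ties_get_average_rank(self):
        expr = make_expression([[3.0], [3.0], [1.0]])
        ranks = pn.rank_transform(expr)
        assert ranks.ranks.iloc[:, 0].tolist() == [2.5, 2.5, 1.0]

    def test_monotone_invariance_under_exp(self):
        rng = np.random.default_rng(0)
        expr = make_expression(rng.normal(size=(30, 4)))
        expr2 = make_expression(np.exp(expr.values.to_numpy()))
        r1 = pn.rank_transform(expr).ranks.to_numpy()
        r2 = pn.rank_transform(expr2).ranks.to_numpy()
        assert (r1 == r2).all()

    def test_rank_sum_invariant(self):
        rng = np.random.default_rng(1)
        expr = make_expression(rng.integers(0, 5, size=(17, 3)).astype(float))
        ranks = pn.rank_transform(expr).ranks
        expected = 17 * 18 / 2
        assert np.allclose(ranks.sum(axis=0), expected)


class TestDeltaRank:
    def test_direction_and_antisymmetry(self):
        expr = make_expression([[5.0], [2.0], [9.0]], genes=["gA", "gB", "gC"])
        ranks = pn.rank_transform(expr)
        fwd = pn.delta_rank(ranks, InteractionNetwork(edges=[("gA", "gC")]))
        rev = pn.delta_rank(ranks, InteractionNetwork(edges=[("gC", "gA")]))
        assert fwd.values.iloc[0, 0] == -1.0
        assert rev.values.iloc[0, 0] == 1.0

    def test_missing_gene_dropped_and_reported(self):
        expr = make_expression([[1.0], [2.0]], genes=["gA", "gB"])
        ranks = pn.rank_transform(expr)
        net = InteractionNetwork(edges=[("gA", "gB"), ("gA", "gZ")])
        delta = pn.delta_rank(ranks, net)
        assert delta.report["edges_dropped"] == 1
        assert list(delta.values.index) == ["gA|gB"]

    def test_empty_overlap_is_an_error(self):
        expr = make_expression([[1.0], [2.0]], genes=["gA", "gB"])
        ranks = pn.rank_transform(expr)
        with pytest.raises(ValidationError, match="overlap empty"):
            pn.delta_rank(ranks, InteractionNetwork(edges=[("x", "y")]))


class TestPerturbationMatrix:
    def test_baseline_subtraction(self):
        # reference deltas 2 and 0 (baseline 1); disease delta 4 -> p = 3
        expr = make_expression(
            [[3.0, 2.0, 5.0], [1.0, 2.0, 1.0], [2.0, 1.0, 2.0], [4.0, 3.0, 3.0],
             [5.0, 4.0, 4.0]],
            samples=["r1", "r2", "d1"],
        )
        ranks = pn.rank_transform(expr)
        delta = pn.delta_rank(ranks, InteractionNetwork(edges=[("g0", "g1")]))
        assert delta.values.loc["g0|g1"].tolist() == [2.0, 0.0, 4.0]
        pert = pn.perturbation_matrix(delta, ["r1", "r2"])
        assert pert.baseline["g0|g1"] == 1.0
        assert pert.values.loc["g0|g1", "d1"] == 3.0

    def test_reference_mean_zero(self, small_perturbation):
        _, _, pert = small_perturbation
        resid = pert.values[pert.reference_ids].mean(axis=1)
        assert np.abs(resid.to_numpy()).max() < 1e-9

    def test_too_few_references(self, small_perturbation):
        _, delta, _ = small_perturbation
        with pytest.raises(ValidationError, match="at least 2"):
            pn.perturbation_matrix(delta, [delta.values.columns[0]])
        with pytest.raises(ValidationError, match="absent"):
            pn.perturbation_matrix(delta, ["nope", "also-nope"])


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_perturbation_invariant_under_increasing_transforms(state):
    """Rank, delta and perturbation matrices depend only on within-sample order."""
    rng = np.random.default_rng(state)
    n_g, n_s = 8, 6
    expr = make_expression(rng.normal(size=(n_g, n_s)))
    # per-sample strictly increasing transforms (affine, cube, exp)
    x = expr.values.to_numpy().copy()
    for j in range(n_s):
        f = [lambda v: 2.0 * v + 1.0, lambda v: v**3, np.exp][j % 3]
        x[:, j] = f(x[:, j])
    expr2 = make_expression(x)
    net = InteractionNetwork(edges=[("g0", "g3"), ("g5", "g1"), ("g2", "g7")])
    refs = ["s0", "s1"]
    p1 = pn.perturbation_matrix(pn.delta_rank(pn.rank_transform(expr), net), refs)
    p2 = pn.perturbation_matrix(pn.delta_rank(pn.rank_transform(expr2), net), refs)
    assert (p1.values.to_numpy() == p2.values.to_numpy()).all()


def test_edge_reversal_negates_perturbation(small_cohort, small_perturbation):
    ranks, _, pert = small_perturbation
    reversed_net = InteractionNetwork(
        edges=[(t, s) for s, t in small_cohort.network.edges]
    )
    delta_rev = pn.delta_rank(ranks, reversed_net)
    pert_rev = pn.perturbation_matrix(
        delta_rev, small_cohort.expression.samples_with("reference")
    )
    assert (pert_rev.values.to_numpy() == -pert.values.to_numpy()).all()


class TestScaleFree:
    def test_preferential_attachment_is_scale_free_like(self):
        net = pn.generate_network(1000, 3, seed=42)
        fit = pn.scale_free_fit(net)
        assert fit.r < -0.7
        assert fit.p_value < 0.0001

    def test_uniform_degree_is_degenerate(self):
        cycle = InteractionNetwork(
            edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")]
        )
        with pytest.raises(ValidationError, match="degenerate"):
            pn.scale_free_fit(cycle)


class TestSelectPerturbedEdges:
    @staticmethod
    def _pert_from(values, samples, edges):
        df = pd.DataFrame(values, index=[f"{s}|{t}" for s, t in edges],
                          columns=samples)
        return pn.PerturbationMatrix(
            values=df, baseline=df.mean(axis=1), edges=edges,
            reference_ids=[],
        )

    def test_planted_shift_retained_null_not(self):
        rng = np.random.default_rng(3)
        samples = [f"r{i}" for i in range(20)] + [f"d{i}" for i in range(20)]
        labels = pd.Series(["reference"] * 20 + ["disease"] * 20, index=samples)
        null = rng.normal(size=(30, 40))
        shifted = rng.normal(size=40)
        shifted[20:] += 3.0  # 3 pooled SDs
        values = np.vstack([shifted, null])
        edges = [("p", "q")] + [(f"a{i}", f"b{i}") for i in range(30)]
        filt = pn.select_perturbed_edges(
            self._pert_from(values, samples, edges), labels, alpha=0.05
        )
        assert bool(filt.table.loc["p|q", "retained"])
        assert filt.table.loc["p|q", "q"] < 0.05

    def test_identical_distributions_not_retained(self):
        samples = [f"r{i}" for i in range(5)] + [f"d{i}" for i in range(5)]
        labels = pd.Series(["reference"] * 5 + ["disease"] * 5, index=samples)
        values = np.tile(np.arange(5, dtype=float), (4, 2))
        filt = pn.select_perturbed_edges(
            self._pert_from(values, samples, [(f"a{i}", f"b{i}") for i in range(4)]),
            labels,
        )
        assert not filt.table["retained"].any()

    def test_small_groups_rejected(self):
        samples = ["r1", "r2", "d1", "d2", "d3"]
        labels = pd.Series(["reference"] * 2 + ["disease"] * 3, index=samples)
        values = np.random.default_rng(0).normal(size=(3, 5))
        with pytest.raises(ValidationError, match="at least 3"):
            pn.select_perturbed_edges(
                self._pert_from(values, samples,
                                [(f"a{i}", f"b{i}") for i in range(3)]),
                labels,
            )

    def test_max_edges_caps_by_smallest_q(self, default_cohort, default_filtered):
        _ = default_cohort
        full = int(default_filtered.table["retained"].sum())
        assert full > 100

    def test_max_edges_cap(self, default_cohort, default_perturbation):
        _, _, pert = default_perturbation
        capped = pn.select_perturbed_edges(
            pert, default_cohort.expression.condition, max_edges=100
        )
        assert int(capped.table["retained"].sum()) == 100
        kept_q = capped.table.loc[capped.table["retained"], "q"]
        dropped_q = capped.table.loc[~capped.table["retained"], "q"]
        assert kept_q.max() <= dropped_q.min() + 1e-12


class TestDisturbanceSummary:
    def test_all_reference_cohort(self, small_perturbation, small_cohort):
        _, _, pert = small_perturbation
        refs = small_cohort.expression.samples_with("reference")
        sub = pn.PerturbationMatrix(
            values=pert.values[refs], baseline=pert.baseline,
            edges=pert.edges, reference_ids=refs,
        )
        labels = pd.Series("reference", index=refs)
        table = pn.disturbance_summary(sub, labels)
        assert list(table.index) == ["reference"]
        assert table.loc["reference", "mean_abs_perturbation"] >= 0

    def test_disease_more_disturbed(self, small_cohort, small_perturbation):
        _, _, pert = small_perturbation
        table = pn.disturbance_summary(pert, small_cohort.expression.condition)
        assert (
            table.loc["disease", "mean_abs_perturbation"]
            > table.loc["reference", "mean_abs_perturbation"]
        )

    def test_zero_matrix(self):
        samples = ["r1", "r2", "d1"]
        df = pd.DataFrame(np.zeros((2, 3)), index=["a|b", "c|d"], columns=samples)
        pert = pn.PerturbationMatrix(values=df, baseline=df.mean(axis=1),
                                     edges=[("a", "b"), ("c", "d")],
                                     reference_ids=["r1", "r2"])
        labels = pd.Series(["reference", "reference", "disease"], index=samples)
        table = pn.disturbance_summary(pert, labels)
        assert (table[["mean_abs_perturbation", "min", "max"]].to_numpy() == 0).all()

    def test_unknown_label_rejected(self, small_perturbation):
        _, _, pert = small_perturbation
        labels = pd.Series("healthy", index=pert.values.columns)
        with pytest.raises(ValidationError, match="unknown condition"):
            pn.disturbance_summary(pert, labels)
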