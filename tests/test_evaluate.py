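"""Z-scores, degree-preserving shuffles, enrichment and hierarchy
comparison."""

import numpy as np
import pytest

from trnhier import (LevelAssignment, MutationSpec, Network,
                     build_pair_set, compare_assignments,
                     degree_preserving_shuffle, level_enrichment,
                     local_vs_global, penalty, planted_hierarchy,
                     robustness_experiment, solve, stability_experiment,
                     zscore)
from trnhier.evaluate import DegenerateNullError, ShuffleStuckError
from trnhier.network import PairSet


class TestZScore:
    def test_empty_pairset_is_degenerate(self, printed_assignment, rng):
        ps = PairSet("adjacency", frozenset())
        with pytest.raises(DegenerateNullError):
            zscore(printed_assignment, ps, n_samples=50, rng=rng)

    def test_example_assignment_beats_its_null(self, example_adj,
                                               printed_assignment):
        z = zscore(printed_assignment, example_adj, n_samples=2000, rng=7)
        assert z.gamma == 1
        assert z.z > 0
        assert z.z == pytest.approx((z.mu - z.gamma) / z.sigma)

    def test_null_preserves_level_histogram(self, example_adj,
                                            printed_assignment):
        """Every null draw is a permutation of the observed levels."""
        rng = np.random.default_rng(3)
        nodes = printed_assignment.nodes
        base = sorted(printed_assignment.levels.values())
        for _ in range(50):
            perm = rng.permutation(len(nodes))
            levels = [printed_assignment.levels[nodes[k]] for k in perm]
            assert sorted(levels) == base

    def test_seeded_reproducibility(self, example_adj, printed_assignment):
        z1 = zscore(printed_assignment, example_adj, n_samples=200, rng=5)
        z2 = zscore(printed_assignment, example_adj, n_samples=200, rng=5)
        assert (z1.mu, z1.sigma, z1.z) == (z2.mu, z2.sigma, z2.z)

    def test_better_assignment_scores_higher(self, example_adj,
                                             printed_assignment):
        """gamma enters z = (mu - gamma)/sigma negatively, so a worse
        assignment with the same level histogram cannot out-score the
        optimum."""
        worse_levels = dict(printed_assignment.levels)
        # swap the top node down: same histogram, more conflicts
        worse_levels["n1"], worse_levels["n7"] = (worse_levels["n7"],
                                                  worse_levels["n1"])
        worse = LevelAssignment(worse_levels, 4)
        assert penalty(worse, example_adj) > penalty(printed_assignment,
                                                     example_adj)
        z_opt = zscore(printed_assignment, example_adj, 1000, rng=11)
        z_bad = zscore(worse, example_adj, 1000, rng=11)
        assert z_opt.z > z_bad.z


class TestMutationSpec:
    def test_percent_to_swap_count(self):
        spec = MutationSpec.from_percent(25, 8)
        assert spec.eta == 2
        assert spec.percent == 25

    def test_percent_rerounded_from_eta(self):
        # 20% of 8 edges rounds to eta=2, which is 25% of the network
        assert MutationSpec.from_percent(20, 8).percent == 25

    def test_zero_edges(self):
        assert MutationSpec.from_percent(50, 0).eta == 0


class TestShuffle:
    def test_zero_swaps_is_identity(self, example_net, rng):
        spec = MutationSpec(percent=0, eta=0)
        assert degree_preserving_shuffle(example_net, spec, rng) == example_net

    @pytest.mark.parametrize("seed", range(8))
    def test_degrees_and_edge_count_invariant(self, example_net, seed):
        spec = MutationSpec(percent=25, eta=2)
        mutant = degree_preserving_shuffle(example_net, spec, rng=seed)
        assert mutant.degree_pairs() == example_net.degree_pairs()
        assert mutant.n_edges == example_net.n_edges
        assert set(mutant.nodes) == set(example_net.nodes)
        assert all(u != v for u, v in mutant.edges)

    def test_shared_source_fan_has_no_admissible_swap(self, rng):
        net = Network([("a", "b"), ("a", "c")])
        spec = MutationSpec(percent=50, eta=1)
        with pytest.raises(ShuffleStuckError) as err:
            degree_preserving_shuffle(net, spec, rng,
                                      max_attempts_per_swap=200)
        assert err.value.completed == 0

    def test_large_network_many_swaps(self):
        inst = planted_hierarchy(100, 4, 2.0, 3, rng=5)
        spec = MutationSpec.from_percent(40, inst.network.n_edges)
        mutant = degree_preserving_shuffle(inst.network, spec, rng=6)
        assert mutant.degree_pairs() == inst.network.degree_pairs()


@pytest.fixture(scope="module")
def planted():
    return planted_hierarchy(80, 5, 2.0, 5, rng=21, tight=True)


class TestExperiments:
    def test_robustness_zero_percent_equals_optimum(self, planted):
        table = robustness_experiment(planted.network, "adjacency", 5,
                                      [0], n_mutants=3, n_zsamples=200,
                                      rng=1)
        ps = build_pair_set(planted.network, "adjacency")
        opt = solve(ps, planted.network.nodes, 5).penalty
        assert table.loc[0, "mean_penalty"] == opt

    def test_robustness_z_stays_positive_under_mutation(self, planted):
        table = robustness_experiment(planted.network, "adjacency", 5,
                                      [5, 10, 20], n_mutants=4,
                                      n_zsamples=300, rng=2)
        assert (table["mean_z"] > 0).all()

    def test_robustness_deterministic_under_seed(self, planted):
        kw = dict(percents=[5], n_mutants=2, n_zsamples=100, rng=3)
        t1 = robustness_experiment(planted.network, "adjacency", 5, **kw)
        t2 = robustness_experiment(planted.network, "adjacency", 5, **kw)
        assert t1.equals(t2)

    def test_stability_zero_percent_matches_fresh_solve(self, planted):
        table = stability_experiment(planted.network, "adjacency", 5,
                                     [0], n_mutants=1, n_zsamples=300,
                                     rng=4)
        ps = build_pair_set(planted.network, "adjacency")
        opt = solve(ps, planted.network.nodes, 5).penalty
        assert table.loc[0, "mean_penalty"] == opt
        assert table.loc[0, "mean_z"] > 0

    def test_stability_penalties_bounded(self, planted):
        table = stability_experiment(planted.network, "adjacency", 5,
                                     [5, 10], n_mutants=2, n_zsamples=100,
                                     rng=5)
        n_pairs = len(build_pair_set(planted.network, "adjacency"))
        assert ((table["mean_penalty"] >= 0)
                & (table["mean_penalty"] <= n_pairs)).all()
        assert (table["mean_z"] > 0).all()


class TestEnrichment:
    def test_term_on_every_node_is_never_enriched(self, printed_assignment):
        ann = {n: {"everywhere"} for n in printed_assignment.nodes}
        table = level_enrichment(printed_assignment, ann)
        assert (table["k"] == table["n"]).all()
        assert table["p_value"].tolist() == pytest.approx(
            [1.0] * len(table))

    def test_hypergeometric_tail_value(self):
        # N=10 nodes, K=5 carriers, one level of n=4 holding k=4 carriers
        levels = {f"x{i}": (0 if i < 4 else 1) for i in range(10)}
        assign = LevelAssignment(levels, 2)
        ann = {f"x{i}": {"T"} for i in (0, 1, 2, 3, 9)}
        table = level_enrichment(assign, ann)
        row = table[(table["level"] == 1) & (table["term"] == "T")].iloc[0]
        assert row["k"] == 4 and row["n"] == 4 and row["K"] == 5
        assert row["p_value"] == pytest.approx(5 / 210)

    def test_binary_annotation_ratio_column(self, printed_assignment):
        essential = {"n1": {"essential"}, "n3": {"essential"}}
        table = level_enrichment(printed_assignment, essential)
        top = table[table["level"] == 4].iloc[0]
        assert top["ratio"] == pytest.approx(1.0)  # n1 alone at the top

    def test_pvalues_in_unit_interval_and_pmf_normalised(
            self, printed_assignment, rng):
        from scipy.stats import hypergeom
        ann = {n: {"T"} for n in list(printed_assignment.nodes)[:3]}
        table = level_enrichment(printed_assignment, ann)
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()
        for _, row in table.iterrows():
            support = np.arange(0, row["n"] + 1)
            total = hypergeom.pmf(support, row["N"], row["K"],
                                  row["n"]).sum()
            assert total == pytest.approx(1.0)

    def test_correction_flag(self, printed_assignment):
        ann = {"n1": {"a"}, "n2": {"b"}}
        table = level_enrichment(printed_assignment, ann,
                                 correction="bonferroni")
        assert (table["p_adjusted"] >= table["p_value"] - 1e-12).all()

    def test_empty_assignment_rejected(self):
        with pytest.raises(ValueError):
            level_enrichment(LevelAssignment({}, 1), {})


class TestCompareAssignments:
    def test_identical_assignments_shift_zero(self, printed_assignment):
        table = compare_assignments(printed_assignment, printed_assignment)
        assert (table["shift"] == 0).all()

    def test_top_to_bottom_is_full_shift(self):
        a = LevelAssignment({"x": 3, "y": 0}, 4)
        b = LevelAssignment({"x": 0, "y": 0}, 4)
        table = compare_assignments(a, b).set_index("node")
        assert table.loc["x", "shift"] == pytest.approx(1.0)
        assert table.index[0] == "x"  # most unstable node first

    def test_single_level_maps_to_midpoint(self):
        a = LevelAssignment({"x": 0}, 1)
        b = LevelAssignment({"x": 1}, 3)
        table = compare_assignments(a, b)
        assert table.loc[0, "scaled_a"] == pytest.approx(0.5)

    def test_example_cross_M_shifts_bounded(self, example_net):
        from trnhier import HierarchyModel
        r4 = HierarchyModel(example_net, "adjacency", 4).fit()
        r3 = HierarchyModel(example_net, "adjacency", 3).fit()
        table = r4.compare(r3)
        assert ((table["shift"] >= 0) & (table["shift"] <= 1)).all()

    def test_node_set_mismatch(self):
        with pytest.raises(KeyError):
            compare_assignments(LevelAssignment({"x": 0}, 2),
                                LevelAssignment({"y": 0}, 2))


class TestLocalVsGlobal:
    def test_full_node_set_gives_equal_penalties(self, example_net):
        rec = local_vs_global(example_net, example_net.nodes, "adjacency",
                              4, n_zsamples=200, rng=1)
        assert rec.local_penalty == rec.global_penalty
        assert rec.incoming == 0 and rec.outgoing == 0

    def test_cycle_subnetwork_local_penalty(self, example_net):
        rec = local_vs_global(example_net, {"n3", "n6", "n7"}, "adjacency",
                              4, n_zsamples=200, rng=2)
        assert rec.local_penalty == 1  # the 3-cycle forces one conflict
        assert rec.incoming == 1 and rec.outgoing == 1
        assert rec.incoming_per_node == pytest.approx(1 / 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_local_never_worse_than_induced(self, seed):
        rng = np.random.default_rng(seed)
        inst = planted_hierarchy(30, 4, 2.0, 3, rng=rng)
        nodes = list(inst.network.nodes)
        keep = [nodes[k] for k in
                rng.choice(len(nodes), size=10, replace=False)]
        rec = local_vs_global(inst.network, keep, "adjacency", 4,
                              n_zsamples=50, rng=rng)
        assert rec.local_penalty <= rec.global_penalty
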