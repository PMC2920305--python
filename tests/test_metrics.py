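"""Degree centrality, density, centralization and the composite report."""

import dataclasses
from itertools import permutations

import pytest

from livelihood_landscapes import (
    DEFAULT_CATEGORIES,
    CategorySet,
    HouseholdRecord,
    build_landscape,
    degree_centralities,
    mean_occupations,
    metrics_report,
    network_centralization,
    network_density,
    normalize_weights,
)

from oracle import brute_centralization, brute_density


def make_network(weights, categories=DEFAULT_CATEGORIES, binary=False):
    """Construct a normalized network with prescribed link weights."""
    net = build_landscape([], categories)
    return dataclasses.replace(
        net,
        links={lk: 1 for lk in weights},
        weights=dict(weights),
        normalized=True,
        binary=binary,
        prune_threshold=0.05 if binary else None,
    )


def star_links(categories, hub):
    return {
        (hub, c): 1.0 for c in categories if c != hub
    } | {(c, hub): 1.0 for c in categories if c != hub}


class TestDegreeCentralities:
    def test_isolate_scores_zero(self, toy_households):
        net = normalize_weights(build_landscape(toy_households))
        assert degree_centralities(net)["gleaning"] == (0.0, 0.0)

    def test_binary_counts_links_each_direction(self):
        weights = {(c, "informal"): 1.0 for c in
                   ("fishing", "farming", "tourism", "salaried", "gleaning")}
        weights[("informal", "other")] = 1.0
        net = make_network(weights, binary=True)
        ins, outs = degree_centralities(net)["informal"]
        assert (ins, outs) == (5.0, 1.0)

    def test_weighted_toy_sums(self, toy_households):
        net = normalize_weights(build_landscape(toy_households))
        degs = degree_centralities(net)
        assert degs["fishing"] == (0.0, pytest.approx(1.5))
        assert degs["informal"] == (pytest.approx(1.5), 0.0)

    def test_in_out_totals_balance(self, synthetic_site):
        net = normalize_weights(build_landscape(synthetic_site))
        degs = degree_centralities(net)
        total_in = sum(i for i, _ in degs.values())
        total_out = sum(o for _, o in degs.values())
        assert total_in == pytest.approx(total_out)
        assert total_in == pytest.approx(sum(net.weights.values()))


class TestNetworkDensity:
    def test_complete_binary_network_is_one(self, four_categories):
        weights = {
            (a, b): 1.0
            for a, b in permutations(four_categories.labels, 2)
        }
        net = make_network(weights, four_categories, binary=True)
        assert network_density(net, weighted=False) == 1.0

    def test_empty_network_is_zero(self):
        net = make_network({}, binary=True)
        assert network_density(net, weighted=False) == 0.0

    def test_weighted_density_formula(self):
        weights = {
            ("fishing", "farming"): 0.5,
            ("fishing", "informal"): 1.0,
            ("farming", "informal"): 0.5,
        }
        net = make_network(weights)
        assert network_density(net, weighted=True) == pytest.approx(2.0 / 90)

    def test_present_node_set_switch(self, toy_households):
        net = normalize_weights(build_landscape(toy_households))
        # 3 categories reported -> denominator 3*2
        dense = network_density(net, weighted=True, node_set="present")
        assert dense == pytest.approx(2.0 / 6)

    def test_small_node_set_rejected(self):
        net = make_network({}, CategorySet(("fishing",)), binary=True)
        with pytest.raises(ValueError, match="fewer than 2"):
            network_density(net, weighted=False)

    def test_branch_state_enforced(self, toy_households):
        weighted_net = normalize_weights(build_landscape(toy_households))
        with pytest.raises(ValueError, match="binarized"):
            network_density(weighted_net, weighted=False)


class TestCentralization:
    def test_perfect_star_attains_one(self):
        net = make_network(star_links(DEFAULT_CATEGORIES, "informal"), binary=True)
        assert network_centralization(net, weighted=False) == pytest.approx(1.0)

    @pytest.mark.parametrize("kind", ["complete", "empty", "ring"])
    def test_degree_regular_networks_score_zero(self, four_categories, kind):
        labels = four_categories.labels
        if kind == "complete":
            weights = {(a, b): 1.0 for a, b in permutations(labels, 2)}
        elif kind == "empty":
            weights = {}
        else:
            weights = {
                (labels[i], labels[(i + 1) % len(labels)]): 1.0
                for i in range(len(labels))
            }
        net = make_network(weights, four_categories, binary=True)
        assert network_centralization(net, weighted=False) == pytest.approx(0.0)

    def test_weighted_toy_against_oracle(self, four_categories):
        labels = four_categories.labels
        weights = {(labels[0], s): 1.0 for s in labels[1:]}
        weights.update({(s, labels[0]): 1.0 for s in labels[1:]})
        weights[(labels[1], labels[2])] = 0.5
        net = make_network(weights, four_categories)
        expected = brute_centralization(weights, labels, weighted=True)
        assert network_centralization(net, weighted=True) == pytest.approx(expected)

    def test_zero_link_weighted_network_defined_as_zero(self):
        assert network_centralization(make_network({}), weighted=True) == 0.0

    def test_too_few_nodes_rejected(self):
        net = make_network({}, CategorySet(("fishing", "farming")), binary=True)
        with pytest.raises(ValueError, match="fewer than 3"):
            network_centralization(net, weighted=False)


class TestMeanOccupations:
    def test_hand_values(self):
        records = [
            HouseholdRecord("h1", "s", ("fishing",)),
            HouseholdRecord("h2", "s", ("fishing", "farming")),
            HouseholdRecord("h3", "s", ("fishing", "farming", "informal")),
        ]
        assert mean_occupations(records) == pytest.approx(2.0)

    def test_none_counts_as_zero(self):
        records = [
            HouseholdRecord("h1", "s", ("none",)),
            HouseholdRecord("h2", "s", ("fishing", "farming")),
        ]
        assert mean_occupations(records) == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mean_occupations([])

    def test_synthetic_half_half_portfolio_mix(self):
        from livelihood_landscapes import SyntheticConfig, generate_community

        n = 10_000
        cfg = SyntheticConfig(
            n_households=n, k_distribution={1: 0.5, 2: 0.5}, seed=21
        )
        mean = mean_occupations(generate_community(cfg, "a"))
        se = (0.25 / n) ** 0.5  # sd of Bernoulli(0.5) over n households
        assert abs(mean - 1.5) < 3 * se


class TestMetricsReport:
    def test_single_occupation_site_all_zero(self):
        records = [
            HouseholdRecord(f"h{i}", "s", ("fishing",)) for i in range(5)
        ]
        rep = metrics_report(records)
        assert all(v == 0 for v in rep.weighted_in.values())
        assert rep.density_binary == 0.0 and rep.density_weighted == 0.0
        assert rep.centralization_binary == 0.0
        assert rep.centralization_weighted == 0.0
        assert rep.mean_occupations == 1.0

    def test_toy_report_matches_hand_computation(self, toy_households):
        rep = metrics_report(toy_households)
        n = len(DEFAULT_CATEGORIES)
        assert rep.weighted_out["fishing"] == pytest.approx(1.5)
        assert rep.weighted_in["informal"] == pytest.approx(1.5)
        assert rep.binary_out["fishing"] == 2
        assert rep.density_weighted == pytest.approx(2.0 / (n * (n - 1)))
        assert rep.density_binary == pytest.approx(3.0 / (n * (n - 1)))
        # binary: three reported nodes at symmetrized degree 1, seven isolates
        assert rep.centralization_binary == pytest.approx(7.0 / 72.0)
        # weighted: d = (.75, .5, .75), mean weight 2/3
        assert rep.centralization_weighted == pytest.approx(5.5 / 48.0)
        assert rep.mean_occupations == pytest.approx(2.0)
        assert rep.n_nodes == n and rep.n_hh == 3

    def test_weighted_branch_never_pruned(self, toy_households):
        loose = metrics_report(toy_households, prune_threshold=0.05)
        tight = metrics_report(toy_households, prune_threshold=0.9)
        assert loose.density_weighted == tight.density_weighted
        assert loose.weighted_in == tight.weighted_in
        assert loose.density_binary >= tight.density_binary

    def test_matches_brute_oracle_on_random_sites(self, four_categories):
        import random

        from oracle import brute_binarize, brute_prune, brute_weights

        rng = random.Random(5)
        labels = four_categories.labels
        for _ in range(30):
            records = []
            for i in range(rng.randint(1, 6)):
                k = rng.randint(1, 4)
                records.append(
                    HouseholdRecord(f"h{i}", "s", tuple(rng.sample(labels, k)))
                )
            rep = metrics_report(records, four_categories)
            weights = brute_weights([r.occupations for r in records], labels)
            binary = brute_binarize(brute_prune(weights, 0.05))
            assert rep.density_weighted == pytest.approx(
                brute_density(weights, 4, weighted=True)
            )
            assert rep.density_binary == pytest.approx(
                brute_density(binary, 4, weighted=False)
            )
            assert rep.centralization_weighted == pytest.approx(
                brute_centralization(weights, labels, weighted=True)
            )
            assert rep.centralization_binary == pytest.approx(
                brute_centralization(binary, labels, weighted=False)
            )

    def test_isolate_changes_density_not_degrees(self, toy_households):
        base = CategorySet(("fishing", "farming", "informal"))
        extra = CategorySet(("fishing", "farming", "informal", "gleaning"))
        r3 = metrics_report(toy_households, base)
        r4 = metrics_report(toy_households, extra)
        for c in base:
            assert r3.weighted_in[c] == r4.weighted_in[c]
            assert r3.weighted_out[c] == r4.weighted_out[c]
        assert r4.density_weighted == pytest.approx(
            r3.density_weighted * (3 * 2) / (4 * 3)
        )
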