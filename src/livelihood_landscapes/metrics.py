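"""Sectoral and systemic statistics of livelihood landscapes.

Sectoral: weighted in- and out-degree centrality of each occupation (the sum
of incoming / outgoing link weights).  Out-degree measures how often an
occupation is ranked above others in the same households; in-degree measures
how often it is taken on as a lower-ranked, supplemental activity.

Systemic: network density (links, or summed link weights, over the n(n-1)
possible directed links on the fixed node set) and Freeman-style degree
centralization

    C_d = sum_v [d* - d(v)] / [(n-1)(n-2)],   d(v) = (in(v) + out(v)) / 2

which is 1.0 for a perfect star (one hub bidirectionally linked to every
spoke, no spoke-spoke links) and 0 for any degree-regular network.  In the
weighted variant the degrees are weighted and the denominator is multiplied
by the mean positive link weight.

Protocol: weighted statistics are computed on the unpruned normalized
network; binary statistics on the network pruned at weight 0.05 and then
binarized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import fmean
from typing import Mapping, Sequence

from .builder import LivelihoodNetwork, binarize, build_landscape, normalize_weights, prune_links
from .categories import DEFAULT_CATEGORIES, NONE_LABEL, CategorySet
from .survey_io import HouseholdRecord

DEFAULT_PRUNE_THRESHOLD = 0.05


@dataclass(frozen=True)
class MetricsReport:
    """All per-node and whole-network statistics for one household selection."""

    weighted_in: Mapping[str, float]
    weighted_out: Mapping[str, float]
    binary_in: Mapping[str, int]
    binary_out: Mapping[str, int]
    density_binary: float
    density_weighted: float
    centralization_binary: float
    centralization_weighted: float
    mean_occupations: float
    n_nodes: int
    n_hh: int
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD

    def systemic(self) -> dict[str, float]:
        return {
            "density_binary": self.density_binary,
            "density_weighted": self.density_weighted,
            "centralization_binary": self.centralization_binary,
            "centralization_weighted": self.centralization_weighted,
            "mean_occupations": self.mean_occupations,
        }

    def to_dict(self) -> dict:
        return {
            "per_node": {
                cat: {
                    "weighted_in": self.weighted_in[cat],
                    "weighted_out": self.weighted_out[cat],
                    "binary_in": self.binary_in[cat],
                    "binary_out": self.binary_out[cat],
                }
                for cat in self.weighted_in
            },
            "systemic": self.systemic(),
            "n_nodes": self.n_nodes,
            "n_hh": self.n_hh,
            "prune_threshold": self.prune_threshold,
        }


def degree_centralities(
    network: LivelihoodNetwork,
) -> dict[str, tuple[float, float]]:
    """Per-category (in, out) degree centrality: summed link weights.

    Isolates score (0, 0).  On a binarized network this is the plain link
    count in each direction.
    """
    if network.weights is None:
        raise ValueError("degree centralities need a normalized network")
    ins = {c: 0.0 for c in network.categories}
    outs = {c: 0.0 for c in network.categories}
    for (o, d), w in network.weights.items():
        outs[o] += w
        ins[d] += w
    return {c: (ins[c], outs[c]) for c in network.categories}


def _node_count(network: LivelihoodNetwork, node_set: str) -> int:
    if node_set == "fixed":
        return network.n_nodes
    if node_set == "present":
        return sum(1 for c in network.categories if network.total(c) > 0)
    raise ValueError(f"unknown node_set {node_set!r}")


def network_density(
    network: LivelihoodNetwork, weighted: bool, node_set: str = "fixed"
) -> float:
    """Links (binary) or summed link weights (weighted) over n(n-1).

    The denominator counts every ordered pair of distinct nodes in the fixed
    category list; since the maximum link weight is 1 under the default
    normalization, the two variants share it.
    """
    if network.weights is None:
        raise ValueError("density needs a normalized network")
    if weighted and network.binary:
        raise ValueError("weighted density must use the non-binarized network")
    if not weighted and not network.binary:
        raise ValueError("binary density must use the pruned, binarized network")
    n = _node_count(network, node_set)
    if n < 2:
        raise ValueError("density undefined for fewer than 2 nodes")
    total = sum(network.weights.values()) if weighted else len(network.weights)
    return total / (n * (n - 1))


def network_centralization(
    network: LivelihoodNetwork, weighted: bool, node_set: str = "fixed"
) -> float:
    """Freeman degree centralization with symmetrized degrees.

    d(v) = (in(v) + out(v)) / 2 over the fixed node set; the statistic sums
    the shortfall of every node's degree from the maximum and divides by
    (n-1)(n-2), the shortfall sum of the perfect star.  The weighted variant
    additionally multiplies the denominator by the mean positive link
    weight; with no links at all it is defined as 0.
    """
    if network.weights is None:
        raise ValueError("centralization needs a normalized network")
    if weighted and network.binary:
        raise ValueError("weighted centralization must use the non-binarized network")
    if not weighted and not network.binary:
        raise ValueError("binary centralization must use the pruned, binarized network")
    n = _node_count(network, node_set)
    if n < 3:
        raise ValueError("centralization undefined for fewer than 3 nodes")
    if not network.weights:
        return 0.0
    degs = degree_centralities(network)
    if node_set == "present":
        degs = {c: d for c, d in degs.items() if network.total(c) > 0}
    d = {c: (i + o) / 2.0 for c, (i, o) in degs.items()}
    d_star = max(d.values())
    numerator = sum(d_star - dv for dv in d.values())
    denominator = (n - 1) * (n - 2)
    if weighted:
        denominator *= fmean(network.weights.values())
    return numerator / denominator


def mean_occupations(households: Sequence[HouseholdRecord]) -> float:
    """Mean portfolio size; a ``none`` household counts as zero occupations."""
    if not households:
        raise ValueError("mean_occupations needs at least one household")
    sizes = [
        0 if rec.occupations == (NONE_LABEL,) else rec.k for rec in households
    ]
    return fmean(sizes)


def metrics_report(
    households: Sequence[HouseholdRecord],
    categories: CategorySet = DEFAULT_CATEGORIES,
    prune_threshold: float = DEFAULT_PRUNE_THRESHOLD,
    denominator_mode: str = "origin_total",
    node_set: str = "fixed",
    provenance: str = "",
) -> MetricsReport:
    """Build the network once and populate every statistic.

    The weighted branch normalizes only; the binary branch normalizes,
    prunes at ``prune_threshold`` and binarizes, matching the analysis
    protocol (weighted analyses never drop links).
    """
    raw = build_landscape(households, categories, provenance=provenance)
    weighted_net = normalize_weights(raw, denominator_mode)
    binary_net = binarize(prune_links(weighted_net, prune_threshold))

    wdeg = degree_centralities(weighted_net)
    bdeg = degree_centralities(binary_net)
    return MetricsReport(
        weighted_in={c: i for c, (i, _) in wdeg.items()},
        weighted_out={c: o for c, (_, o) in wdeg.items()},
        binary_in={c: int(round(i)) for c, (i, _) in bdeg.items()},
        binary_out={c: int(round(o)) for c, (_, o) in bdeg.items()},
        density_binary=network_density(binary_net, weighted=False, node_set=node_set),
        density_weighted=network_density(weighted_net, weighted=True, node_set=node_set),
        centralization_binary=network_centralization(
            binary_net, weighted=False, node_set=node_set
        ),
        centralization_weighted=network_centralization(
            weighted_net, weighted=True, node_set=node_set
        ),
        mean_occupations=mean_occupations(households),
        n_nodes=_node_count(weighted_net, node_set),
        n_hh=len(households),
        prune_threshold=prune_threshold,
    )
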