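"""Build livelihood-landscape networks from ranked household portfolios.

An occupation is a node; a household that reports occupations at ranks i < j
contributes one directed link from the higher-ranked to the lower-ranked
occupation, for EVERY ordered rank pair — a household with k activities adds
k(k-1)/2 link contributions.  Each node carries a primary counter (households
ranking it first) and a secondary counter (households ranking it second or
lower).

Raw link counts are normalized to weights by dividing by the originating
node's total household count (primary + secondary), so a weight is the
fraction of households engaged in the origin occupation that also engage in
the destination occupation at a lower rank; the maximum weight is 1.0.  An
alternative ``origin_secondary`` mode divides by the origin's secondary
counter alone, under which weights can exceed 1.

The node set is the full configured category list — categories nobody
reported stay in the network as isolates — so network size is identical for
every selection of households and density/centralization are comparable
across aggregation levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from .categories import DEFAULT_CATEGORIES, CategorySet
from .survey_io import CommunityMetadata, HouseholdRecord

Link = tuple[str, str]


@dataclass(frozen=True)
class LivelihoodNetwork:
    """A directed, weighted occupation network over a fixed category set.

    ``links`` maps (origin, destination) to the number of households that
    constitute the link; ``weights`` is ``None`` until normalization.  State
    flags record what has been done to the network so metric functions can
    insist on the right input (weighted analyses use the unpruned normalized
    network; binary analyses use the pruned, binarized one).
    """

    categories: CategorySet
    primary: Mapping[str, int]
    secondary: Mapping[str, int]
    links: Mapping[Link, int]
    weights: Mapping[Link, float] | None = None
    normalized: bool = False
    prune_threshold: float | None = None
    binary: bool = False
    provenance: str = ""
    n_hh: int = 0

    def total(self, category: str) -> int:
        """Distinct households reporting ``category`` at any rank."""
        return self.primary[category] + self.secondary[category]

    @property
    def n_nodes(self) -> int:
        return len(self.categories)

    def link_weight(self, origin: str, destination: str) -> float:
        if self.weights is None:
            raise ValueError("network is not normalized; no weights yet")
        return self.weights.get((origin, destination), 0.0)

    def to_networkx(self) -> nx.DiGraph:
        """Export to a DiGraph with node attrs primary/secondary and edge
        attrs count/weight; graph attrs carry the state flags."""
        g = nx.DiGraph(
            normalized=self.normalized,
            binary=self.binary,
            provenance=self.provenance,
            n_hh=self.n_hh,
        )
        if self.prune_threshold is not None:
            g.graph["prune_threshold"] = float(self.prune_threshold)
        for cat in self.categories:
            g.add_node(cat, primary=self.primary[cat], secondary=self.secondary[cat])
        for (o, d), count in self.links.items():
            attrs = {"count": int(count)}
            if self.weights is not None:
                attrs["weight"] = float(self.weights[(o, d)])
            g.add_edge(o, d, **attrs)
        return g


def select_households(
    records: Sequence[HouseholdRecord],
    predicate: Callable[[HouseholdRecord], bool] | None = None,
    *,
    metadata: Iterable[CommunityMetadata] = (),
    site_id: str | set[str] | None = None,
    country: str | None = None,
    settlement_type: str | None = None,
) -> list[HouseholdRecord]:
    """Subset households for one aggregation level, preserving order.

    Either pass an arbitrary ``predicate`` over records, or filter by
    ``site_id`` directly, or by ``country`` / ``settlement_type`` (which
    require ``metadata`` to resolve sites).  Filters compose conjunctively;
    disjoint filters partition the input.
    """
    meta_by_site = {m.site_id: m for m in metadata}
    if (country is not None or settlement_type is not None) and not meta_by_site:
        raise ValueError("country/settlement_type filters require metadata")

    def keep(rec: HouseholdRecord) -> bool:
        if predicate is not None and not predicate(rec):
            return False
        if site_id is not None:
            wanted = {site_id} if isinstance(site_id, str) else set(site_id)
            if rec.site_id not in wanted:
                return False
        if country is not None or settlement_type is not None:
            meta = meta_by_site.get(rec.site_id)
            if meta is None:
                return False
            if country is not None and meta.country != country:
                return False
            if settlement_type is not None and meta.settlement_type != settlement_type:
                return False
        return True

    return [rec for rec in records if keep(rec)]


def build_landscape(
    households: Sequence[HouseholdRecord],
    categories: CategorySet = DEFAULT_CATEGORIES,
    provenance: str = "",
) -> LivelihoodNetwork:
    """Run the counter/link construction over a household selection.

    Per household: the rank-1 category's primary counter is incremented once;
    every lower-ranked category's secondary counter is incremented once; one
    directed link contribution is added for every ordered pair
    (higher rank -> lower rank).  Exclusive single-entry portfolios (``none``)
    contribute a primary count and no links.
    """
    primary = {c: 0 for c in categories}
    secondary = {c: 0 for c in categories}
    links: dict[Link, int] = {}
    for rec in households:
        for occ in rec.occupations:
            if occ not in categories:
                raise ValueError(
                    f"household {rec.household_id!r}: occupation {occ!r} is "
                    "outside the configured category list"
                )
        occs = rec.occupations
        primary[occs[0]] += 1
        for occ in occs[1:]:
            secondary[occ] += 1
        for i in range(len(occs)):
            for j in range(i + 1, len(occs)):
                links[(occs[i], occs[j])] = links.get((occs[i], occs[j]), 0) + 1
    return LivelihoodNetwork(
        categories=categories,
        primary=primary,
        secondary=secondary,
        links=links,
        provenance=provenance or f"{len(households)} households",
        n_hh=len(households),
    )


def normalize_weights(
    network: LivelihoodNetwork, denominator_mode: str = "origin_total"
) -> LivelihoodNetwork:
    """Turn raw link counts into weights.

    ``origin_total`` (default): weight(A->B) = count(A->B) / (primary(A) +
    secondary(A)) — the fraction of households reporting A that also report B
    at a lower rank; bounded by 1.  ``origin_secondary`` divides by the
    origin's secondary counter alone; weights can then exceed 1 (a warning is
    issued) and the mode is undefined for an origin with no secondary
    reports.
    """
    if network.normalized:
        raise ValueError("network is already normalized")
    if denominator_mode not in ("origin_total", "origin_secondary"):
        raise ValueError(f"unknown denominator_mode {denominator_mode!r}")
    weights: dict[Link, float] = {}
    for (o, d), count in network.links.items():
        if denominator_mode == "origin_total":
            denom = network.total(o)
            assert denom > 0, "origin with outgoing links must have been reported"
        else:
            denom = network.secondary[o]
            if denom == 0:
                raise ValueError(
                    f"origin_secondary normalization undefined: {o!r} has "
                    "outgoing links but a zero secondary counter"
                )
        weights[(o, d)] = count / denom
    if denominator_mode == "origin_secondary" and any(w > 1 for w in weights.values()):
        warnings.warn(
            "origin_secondary normalization produced link weights above 1",
            stacklevel=2,
        )
    return replace(network, weights=weights, normalized=True)


def prune_links(
    network: LivelihoodNetwork, threshold: float = 0.05
) -> LivelihoodNetwork:
    """Drop links with weight strictly below ``threshold``.

    A weight exactly at the threshold survives.  Node counters are untouched;
    only the link set shrinks.
    """
    if not network.normalized:
        raise ValueError("prune requires a normalized network")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0, 1]")
    assert network.weights is not None
    kept = {lk: w for lk, w in network.weights.items() if w >= threshold}
    links = {lk: network.links[lk] for lk in kept}
    return replace(
        network, links=links, weights=kept, prune_threshold=threshold
    )


def binarize(network: LivelihoodNetwork) -> LivelihoodNetwork:
    """Set every surviving link weight to 1 (idempotent)."""
    if not network.normalized:
        raise ValueError("binarize requires a normalized network")
    assert network.weights is not None
    return replace(
        network, weights={lk: 1.0 for lk in network.weights}, binary=True
    )
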