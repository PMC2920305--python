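"""Independent brute-force reference for network construction and metrics.

Works directly on plain portfolios (tuples of category labels, rank order =
position) and never imports the package's builder or metrics code, so it can
serve as an oracle: counters by direct counting, links by explicit pair
enumeration, degrees by summation over the link table, density and
centralization by literal evaluation of their formulas.
"""

from __future__ import annotations

from itertools import combinations
from typing import Mapping, Sequence

Portfolio = tuple[str, ...]


def brute_counters(
    portfolios: Sequence[Portfolio], categories: Sequence[str]
) -> tuple[dict[str, int], dict[str, int]]:
    primary = {c: 0 for c in categories}
    secondary = {c: 0 for c in categories}
    for p in portfolios:
        primary[p[0]] += 1
        for occ in p[1:]:
            secondary[occ] += 1
    return primary, secondary


def brute_links(portfolios: Sequence[Portfolio]) -> dict[tuple[str, str], int]:
    links: dict[tuple[str, str], int] = {}
    for p in portfolios:
        for a, b in combinations(p, 2):  # keeps rank order: a ranked above b
            links[(a, b)] = links.get((a, b), 0) + 1
    return links


def brute_weights(
    portfolios: Sequence[Portfolio], categories: Sequence[str]
) -> dict[tuple[str, str], float]:
    primary, secondary = brute_counters(portfolios, categories)
    return {
        (a, b): n / (primary[a] + secondary[a])
        for (a, b), n in brute_links(portfolios).items()
    }


def brute_degrees(
    weights: Mapping[tuple[str, str], float], categories: Sequence[str]
) -> dict[str, tuple[float, float]]:
    ins = {c: 0.0 for c in categories}
    outs = {c: 0.0 for c in categories}
    for (a, b), w in weights.items():
        outs[a] += w
        ins[b] += w
    return {c: (ins[c], outs[c]) for c in categories}


def brute_density(
    weights: Mapping[tuple[str, str], float], n: int, weighted: bool
) -> float:
    total = sum(weights.values()) if weighted else len(weights)
    return total / (n * (n - 1))


def brute_centralization(
    weights: Mapping[tuple[str, str], float],
    categories: Sequence[str],
    weighted: bool,
) -> float:
    n = len(categories)
    if not weights:
        return 0.0
    degs = brute_degrees(weights, categories)
    d = {c: (i + o) / 2.0 for c, (i, o) in degs.items()}
    d_star = max(d.values())
    numerator = sum(d_star - v for v in d.values())
    denominator = (n - 1) * (n - 2)
    if weighted:
        denominator *= sum(weights.values()) / len(weights)
    return numerator / denominator


def brute_prune(
    weights: Mapping[tuple[str, str], float], threshold: float
) -> dict[tuple[str, str], float]:
    return {lk: w for lk, w in weights.items() if w >= threshold}


def brute_binarize(
    weights: Mapping[tuple[str, str], float],
) -> dict[tuple[str, str], float]:
    return {lk: 1.0 for lk in weights}
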