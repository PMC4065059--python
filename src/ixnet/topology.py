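"""Network diagnostics: degree / FSW distributions, power-law slope and
class composition of the top-ranked FSW edges."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np

from .scoring import CLASS_ORDER
from .types import canonical_pair

FSW_BIN_WIDTH = 0.1


@dataclass
class TopologySummary:
    degree_distribution: dict[int, float] = field(default_factory=dict)
    average_degree: float = 0.0
    slope: float | None = None
    fsw_distribution: dict[int, float] = field(default_factory=dict)
    fit_range: list[int] = field(default_factory=list)


def degree_distribution(net: nx.Graph) -> TopologySummary:
    """P(k) = fraction of nodes of degree k, plus the average degree."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    counts: dict[int, int] = {}
    for _, deg in net.degree():
        counts[deg] = counts.get(deg, 0) + 1
    n = net.number_of_nodes()
    dist = {k: c / n for k, c in sorted(counts.items())}
    return TopologySummary(
        degree_distribution=dist,
        average_degree=sum(k * p for k, p in dist.items()),
    )


def fsw_distribution(net: nx.Graph, bin_width: float = FSW_BIN_WIDTH) -> dict[int, float]:
    """Probability per integer FSW bin (value // bin_width)."""
    values = [data.get("fsw", 0.0) for _, _, data in net.edges(data=True)]
    if not values:
        return {}
    counts: dict[int, int] = {}
    for v in values:
        b = int(v / bin_width)
        counts[b] = counts.get(b, 0) + 1
    total = len(values)
    return {b: c / total for b, c in sorted(counts.items())}


def powerlaw_slope(dist: Mapping[float, float]) -> float:
    """Least-squares slope of log P vs log k over positive-probability,
    positive-k bins."""
    points = [(k, p) for k, p in dist.items() if p > 0 and k > 0]
    if len(points) < 2:
        raise ValueError("need at least 2 positive-probability bins")
    xs = np.log([k for k, _ in points])
    ys = np.log([p for _, p in points])
    slope, _ = np.polyfit(xs, ys, 1)
    return float(slope)


def summarize(net: nx.Graph) -> TopologySummary:
    summary = degree_distribution(net)
    positive = {k: p for k, p in summary.degree_distribution.items() if k > 0 and p > 0}
    if len(positive) >= 2:
        summary.slope = powerlaw_slope(summary.degree_distribution)
        summary.fit_range = sorted(positive)
    summary.fsw_distribution = fsw_distribution(net)
    return summary


def score_class_composition(
    net: nx.Graph, fraction: float = 0.10
) -> dict[str, dict[str, float]]:
    """Class-label percentages among the top-FSW edges vs all edges.

    Edges are ranked by FSW descending (ties: better class, then
    canonical pair key) and the top ceil(fraction * |E|) are compared to
    the full edge set.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    edges = [
        (data.get("fsw", 0.0), data.get("class", "unclassified"), canonical_pair(a, b))
        for a, b, data in net.edges(data=True)
    ]
    if not edges:
        return {"top": {}, "all": {}}
    edges.sort(key=lambda e: (-e[0], CLASS_ORDER.index(e[1]), e[2]))
    n_top = math.ceil(fraction * len(edges))
    top = edges[:n_top]

    def percentages(subset) -> dict[str, float]:
        counts: dict[str, int] = {}
        for _, label, _ in subset:
            counts[label] = counts.get(label, 0) + 1
        return {label: 100.0 * c / len(subset) for label, c in sorted(counts.items())}

    return {"top": percentages(top), "all": percentages(edges)}


def write_summary(summary: TopologySummary, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# average_degree\t{summary.average_degree:.6g}\n")
        if summary.slope is not None:
            fh.write(f"# gamma\t{summary.slope:.6g}\n")
        fh.write("kind\tbin\tprobability\n")
        for k, p in summary.degree_distribution.items():
            fh.write(f"degree\t{k}\t{p:.6g}\n")
        for b, p in summary.fsw_distribution.items():
            fh.write(f"fsw\t{b}\t{p:.6g}\n")
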