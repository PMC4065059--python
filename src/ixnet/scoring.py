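"""Edge and node confidence measures.

Three measures: an additive class score over evidence type, publication
record and co-localization; a neighborhood-overlap weight (FSW) with a
pseudo-count correction; and a binomial-proportion node significance
converted to upper-tail normal p-values after batch standardization.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import networkx as nx

from .types import (
    ClassScore,
    EvidenceProfile,
    FswConfig,
    NodeSignificanceInputs,
    Publication,
)

HT_INTERACTION_THRESHOLD = 500

EXPERIMENTAL_POINTS = 4
SAME_CC_POINTS = 1
MULTI_PUB_NON_HT_POINTS = 4
MULTI_PUB_POINTS = 3
SINGLE_PUB_POINTS = 1

#: class label -> rendered edge width
CLASS_WIDTHS = {"A": 2.5, "B": 2.0, "C": 1.5, "D": 1.0, "E": 0.5}
UNCLASSIFIED = "unclassified"
UNCLASSIFIED_WIDTH = 0.5

#: filter ordering, best first
CLASS_ORDER = ["A", "B", "C", "D", "E", UNCLASSIFIED]


def is_high_throughput(pub: Publication) -> bool:
    """True iff the paper describes more than 500 interactions.

    Unknown counts are conservatively treated as high-throughput (they
    can never upgrade an edge on their own).
    """
    if pub.interaction_count is None:
        return True
    return pub.interaction_count > HT_INTERACTION_THRESHOLD


def publication_points(publications: Iterable[Publication]) -> int:
    pubs = list(publications)
    if len(pubs) > 1:
        if any(not is_high_throughput(p) for p in pubs):
            return MULTI_PUB_NON_HT_POINTS
        return MULTI_PUB_POINTS
    if len(pubs) == 1:
        return SINGLE_PUB_POINTS
    return 0


def class_score(ev: EvidenceProfile) -> ClassScore:
    """Additive confidence total with its class label and edge width.

    Total = evidence-type (+4 experimental) + publication record
    (+4 multi-paper with a low-throughput one, +3 multi-paper, +1 single
    paper) + co-localization (+1). Labels follow the experimental
    classes A(9) B(7,8) C(6) D(5) E(4); an unpublished experimental edge
    is class E regardless of co-localization, and predicted edges are
    unclassified.
    """
    total = (
        (EXPERIMENTAL_POINTS if ev.experimental else 0)
        + publication_points(ev.publications)
        + (SAME_CC_POINTS if ev.same_cc else 0)
    )
    n_pubs = len(ev.publications)
    if not ev.experimental:
        label = UNCLASSIFIED
    elif n_pubs == 0:
        label = "E"  # novel interaction: class E even with shared CC
    elif n_pubs == 1:
        label = "C" if ev.same_cc else "D"
    elif total >= 9:
        label = "A"
    else:
        label = "B"
    width = CLASS_WIDTHS.get(label, UNCLASSIFIED_WIDTH)
    return ClassScore(total=total, class_label=label, edge_width=width)


def class_at_least(label: str, cutoff: str) -> bool:
    """True iff ``label`` is at least as confident as ``cutoff``."""
    return CLASS_ORDER.index(label) <= CLASS_ORDER.index(cutoff)


# -- FSW ----------------------------------------------------------------

def average_neighborhood_size(graph: nx.Graph, include_self: bool = True) -> float:
    """Mean neighborhood size over all nodes (closed by default)."""
    n = graph.number_of_nodes()
    if n == 0:
        return 0.0
    bonus = 1 if include_self else 0
    return sum(graph.degree(u) + bonus for u in graph.nodes) / n


def make_fsw_config(graph: nx.Graph, include_self: bool = True,
                    lambda_mode: str = "chua_pseudocount") -> FswConfig:
    return FswConfig(
        include_self=include_self,
        lambda_mode=lambda_mode,
        n_avg=average_neighborhood_size(graph, include_self=include_self),
    )


def fsw_score(u, v, graph: nx.Graph, cfg: FswConfig | None = None) -> float:
    """Neighborhood-overlap reliability weight in [0, 1].

    With (closed) neighborhoods N_u, N_v, common count c, exclusive
    counts e_u, e_v and pseudo-counts
    lambda_uv = max(0, n_avg - (e_u + c)),
    lambda_vu = max(0, n_avg - (e_v + c)):

        FSW = [2c / (e_u + 2c + lambda_uv)] * [2c / (e_v + 2c + lambda_vu)]

    Symmetric in (u, v); 0 whenever the neighborhoods are disjoint.
    """
    if u not in graph or v not in graph:
        raise KeyError(f"node absent from graph: {u if u not in graph else v}")
    if cfg is None:
        cfg = make_fsw_config(graph)
    nu = set(graph.neighbors(u))
    nv = set(graph.neighbors(v))
    nu.discard(u)
    nv.discard(v)
    if cfg.include_self:
        nu.add(u)
        nv.add(v)
    c = len(nu & nv)
    if c == 0:
        return 0.0
    e_u = len(nu - nv)
    e_v = len(nv - nu)
    if cfg.lambda_mode == "chua_pseudocount":
        lam_uv = max(0.0, cfg.n_avg - (e_u + c))
        lam_vu = max(0.0, cfg.n_avg - (e_v + c))
    else:
        lam_uv = lam_vu = 0.0
    return (2 * c / (e_u + 2 * c + lam_uv)) * (2 * c / (e_v + 2 * c + lam_vu))


# -- node significance --------------------------------------------------

def _normal_sf(x: float) -> float:
    return 0.5 * math.erfc(x / math.sqrt(2.0))


def raw_z(inp: NodeSignificanceInputs) -> float | None:
    """Binomial-proportion z; None when the background rate is degenerate."""
    if inp.N <= 0 or inp.n <= 0:
        raise ValueError("need N > 0 and n > 0")
    p0 = inp.K_i / inp.N
    if p0 <= 0.0 or p0 >= 1.0:
        return None
    return (inp.k_i / inp.n - p0) / math.sqrt(p0 * (1.0 - p0) / inp.n)


def node_significance(
    inputs: Sequence[NodeSignificanceInputs],
) -> dict[str, dict[str, float | bool | None]]:
    """Per-node p-values from batch-standardized binomial-proportion z.

    Raw z-scores are standardized by their empirical mean and standard
    deviation across the subnetwork, then converted through the
    upper-tail standard normal. Degenerate background rates (K_i of 0 or
    N) get the worst p of the valid batch, flagged; a zero batch
    standard deviation yields p = 0.5 for all nodes.
    """
    raw: dict[str, float | None] = {inp.node_id: raw_z(inp) for inp in inputs}
    valid = {k: z for k, z in raw.items() if z is not None}
    out: dict[str, dict[str, float | bool | None]] = {}
    if valid:
        zs = list(valid.values())
        mean = sum(zs) / len(zs)
        var = sum((z - mean) ** 2 for z in zs) / len(zs)
        sd = math.sqrt(var)
        for node, z in valid.items():
            if sd == 0.0:
                std_z, p = 0.0, 0.5
            else:
                std_z = (z - mean) / sd
                p = _normal_sf(std_z)
            out[node] = {"raw_z": z, "std_z": std_z, "p_value": p, "degenerate": False}
        worst = max(rec["p_value"] for rec in out.values())
    else:
        worst = 0.5
    for node, z in raw.items():
        if z is None:
            out[node] = {
                "raw_z": None,
                "std_z": None,
                "p_value": worst,
                "degenerate": True,
            }
    return out
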