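"""Seed expansion, scoring, ordered filtering and expression annotation.

Networks are ``networkx.Graph`` objects whose node/edge attribute
dictionaries carry everything the XGMML writer serializes.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Optional, Sequence

import networkx as nx

from . import scoring
from .store import AnnotationCatalog, InteractionStore
from .types import (
    BuildConfig,
    EntityKind,
    EvidenceProfile,
    ExpressionConfig,
    NodeSignificanceInputs,
)

Network = nx.Graph

#: Fig-3 style level palette; expression coloring overrides it.
COLORS = {
    "bait": "#FF0000",
    "seed": "#0000FF",
    "level1": "#00FF00",
    "level2": "#FFA500",
    "level3": "#800080",
    "small_molecule": "#FFFF00",
    "up": "#FF0000",
    "down": "#00FF00",
    "default": "#C0C0C0",
}

SHAPES = {
    EntityKind.PROTEIN: "ELLIPSE",
    EntityKind.METABOLITE: "RECTANGLE",
    EntityKind.DRUG: "TRIANGLE",
}

NODE_BASE_SIZE = 35.0


def protein_nodes(net: Network) -> list[str]:
    return [n for n, d in net.nodes(data=True) if d.get("entity_kind") == "protein"]


def _level_color(data: dict) -> str:
    if data.get("bait"):
        return COLORS["bait"]
    if data.get("entity_kind") in ("metabolite", "drug"):
        return COLORS["small_molecule"]
    if data.get("seed"):
        return COLORS["seed"]
    level = data.get("level")
    return COLORS.get(f"level{level}", COLORS["default"])


def _add_node(net: Network, entity_id: str, store: InteractionStore,
              catalog: AnnotationCatalog, level: int, seed: bool) -> None:
    ent = store.entities[entity_id]
    net.add_node(
        entity_id,
        level=level,
        seed=seed,
        bait=False,
        entity_kind=ent.entity_kind.value,
        organism=ent.organism,
        symbol=ent.symbol or entity_id,
        selected_cc=sorted(catalog.cc_terms.get(entity_id, ())),
        fold_change=None,
        regulation="none",
        top_bp="",
        top_kegg="",
        p_value=None,
        raw_z=None,
        std_z=None,
        shape=SHAPES[ent.entity_kind],
    )


def refresh_degrees(net: Network) -> None:
    for node in net.nodes:
        net.nodes[node]["degree"] = net.degree(node)


def refresh_display(net: Network, size_scaling: str = "fixed") -> None:
    """Recompute display color/size from level, kind, regulation and degree."""
    for node, data in net.nodes(data=True):
        reg = data.get("regulation")
        if reg == "up":
            data["color"] = COLORS["up"]
        elif reg == "down":
            data["color"] = COLORS["down"]
        else:
            data["color"] = _level_color(data)
        fc = data.get("fold_change")
        if size_scaling == "proportional_abs_fc" and fc is not None:
            data["size"] = NODE_BASE_SIZE * max(1.0, abs(fc))
        else:
            # degree gradient so hubs stand out
            data["size"] = NODE_BASE_SIZE + 5.0 * data.get("degree", 0)


def expand(
    seeds: Sequence[str],
    store: InteractionStore,
    cfg: BuildConfig,
    catalog: Optional[AnnotationCatalog] = None,
) -> Network:
    """Breadth-first expansion of the seeds into an induced subnetwork.

    Frontiers grow to ``cfg.depth`` using store neighbors with the
    metabolite/drug flags respected; the edge set is every store pair
    among the retained nodes (not only traversal edges). Unresolved
    seeds are reported with a warning, an empty seed list is an error.
    """
    if not seeds:
        raise ValueError("empty seed list")
    catalog = catalog or AnnotationCatalog()
    known = [s for s in seeds if s in store.entities]
    missing = [s for s in seeds if s not in store.entities]
    if missing:
        warnings.warn(f"{len(missing)} seed(s) not in store: {sorted(missing)}")
    net = Network()
    net.graph["name"] = "ixnet"
    for s in sorted(set(known)):
        _add_node(net, s, store, catalog, level=0, seed=True)
    frontier = set(net.nodes)
    visited = set(net.nodes)
    for level in range(1, cfg.depth + 1):
        nxt = set()
        for node in frontier:
            nxt |= store.neighbors(
                node,
                include_metabolites=cfg.include_metabolites,
                include_drugs=cfg.include_drugs,
            )
        nxt -= visited
        for node in sorted(nxt):
            _add_node(net, node, store, catalog, level=level, seed=False)
        visited |= nxt
        frontier = nxt
        if not frontier:
            break
    _induce_edges(net, store, cfg)
    refresh_degrees(net)
    return net


def _induce_edges(net: Network, store: InteractionStore, cfg: BuildConfig) -> None:
    nodes = set(net.nodes)
    for (a, b), pe in store.pairs.items():
        if a == b or a not in nodes or b not in nodes:
            continue
        net.add_edge(
            a,
            b,
            experimental=pe.experimental,
            methods=sorted(pe.methods),
            sources=sorted(pe.sources),
            pmids=sorted(pe.pmids),
            novel=False,
        )


def score_edges(
    net: Network,
    store: InteractionStore,
    catalog: AnnotationCatalog,
    lambda_mode: str = "chua_pseudocount",
) -> None:
    """Attach class score and FSW attributes to every edge in-place."""
    fsw_cfg = scoring.make_fsw_config(net, lambda_mode=lambda_mode)
    for a, b, data in net.edges(data=True):
        pair = (a, b) if a <= b else (b, a)
        if data.get("novel"):
            pubs = frozenset()
            experimental = True
        elif pair in store.pairs:
            pubs = store.pair_publications(pair)
            experimental = store.pairs[pair].experimental
        else:
            pubs = frozenset()
            experimental = data.get("experimental", True)
        same_cc = bool(
            catalog.cc_terms.get(a, set()) & catalog.cc_terms.get(b, set())
        )
        cs = scoring.class_score(
            EvidenceProfile(experimental=experimental, publications=pubs, same_cc=same_cc)
        )
        data["class"] = cs.class_label
        data["class_score"] = cs.total
        data["width"] = cs.edge_width
        data["fsw"] = scoring.fsw_score(a, b, net, fsw_cfg)


def attach_bait(
    net: Network,
    bait: str,
    preys: Sequence[str],
    store: InteractionStore,
    catalog: Optional[AnnotationCatalog] = None,
) -> Network:
    """Connect a bait to its preys, adding novel edges where no store
    evidence exists.

    Novel edges carry zero publications and therefore class E; pairs
    already evidenced in the store keep their scored edge. A prey equal
    to the bait is skipped with a warning.
    """
    catalog = catalog or AnnotationCatalog()
    if bait not in net:
        if bait in store.entities:
            _add_node(net, bait, store, catalog, level=0, seed=True)
        else:
            net.add_node(
                bait,
                level=0,
                seed=True,
                bait=True,
                entity_kind="protein",
                organism="",
                symbol=bait,
                selected_cc=sorted(catalog.cc_terms.get(bait, ())),
                fold_change=None,
                regulation="none",
                top_bp="",
                top_kegg="",
                p_value=None,
                raw_z=None,
                std_z=None,
                shape="ELLIPSE",
            )
    net.nodes[bait]["bait"] = True
    net.nodes[bait]["seed"] = True
    net.nodes[bait]["level"] = 0
    for prey in preys:
        if prey == bait:
            warnings.warn(f"bait {bait} listed among preys; self-edge skipped")
            continue
        if prey not in net:
            continue
        if net.has_edge(bait, prey):
            continue
        pair = (bait, prey) if bait <= prey else (prey, bait)
        if pair in store.pairs:
            pe = store.pairs[pair]
            net.add_edge(
                bait,
                prey,
                experimental=pe.experimental,
                methods=sorted(pe.methods),
                sources=sorted(pe.sources),
                pmids=sorted(pe.pmids),
                novel=False,
            )
        else:
            net.add_edge(
                bait,
                prey,
                experimental=True,
                methods=[],
                sources=[],
                pmids=[],
                novel=True,
            )
    refresh_degrees(net)
    return net


def compute_node_significance(
    net: Network, store: InteractionStore, organism: str
) -> None:
    """Attach binomial-proportion p-values against the organism-filtered
    store to every node, in-place."""
    n = net.number_of_edges()
    N = store.n_pairs(organism)
    if n == 0 or N == 0:
        warnings.warn("no pairs in subnetwork or organism-filtered store; "
                      "p-values not computed")
        return
    inputs = [
        NodeSignificanceInputs(
            node_id=node,
            k_i=net.degree(node),
            n=n,
            K_i=store.degree(node, organism),
            N=N,
        )
        for node in net.nodes
    ]
    for node, rec in scoring.node_significance(inputs).items():
        net.nodes[node]["raw_z"] = rec["raw_z"]
        net.nodes[node]["std_z"] = rec["std_z"]
        net.nodes[node]["p_value"] = rec["p_value"]


def prune_low_degree(
    net: Network, iterate: bool = False, protect_seeds: bool = False
) -> Network:
    """Remove all nodes of entry degree <= 1 in one simultaneous pass.

    Not a 2-core reduction by default: nodes isolated *by* the pass
    survive it. ``iterate=True`` repeats passes to the 2-core.
    """
    while True:
        doomed = [
            node
            for node in net.nodes
            if net.degree(node) <= 1
            and not (protect_seeds and net.nodes[node].get("seed"))
        ]
        net.remove_nodes_from(doomed)
        if not iterate or not doomed:
            break
    refresh_degrees(net)
    return net


def apply_filters(net: Network, cfg: BuildConfig) -> tuple[Network, dict[str, int]]:
    """Apply the ordered filter pipeline to a copy of the network.

    Order: (i) class score, (ii) node p-value, (iii) degree-0/1 deletion,
    (iv) FSW. Every stage only removes elements; degrees are refreshed
    between stages. Returns the filtered network and per-stage removal
    counts.
    """
    net = net.copy()
    report: dict[str, int] = {}

    if cfg.class_cutoff is not None:
        doomed = [
            (a, b)
            for a, b, data in net.edges(data=True)
            if not scoring.class_at_least(data["class"], cfg.class_cutoff)
        ]
        net.remove_edges_from(doomed)
        report["class_edges_removed"] = len(doomed)
        refresh_degrees(net)

    if cfg.pvalue_cutoff is not None:
        doomed_nodes = [
            node
            for node, data in net.nodes(data=True)
            if data.get("p_value") is None or data["p_value"] > cfg.pvalue_cutoff
        ]
        net.remove_nodes_from(doomed_nodes)
        report["pvalue_nodes_removed"] = len(doomed_nodes)
        refresh_degrees(net)

    if cfg.delete_degree_01:
        before = net.number_of_nodes()
        prune_low_degree(
            net, iterate=cfg.iterate_degree_prune, protect_seeds=cfg.protect_seeds
        )
        report["degree_nodes_removed"] = before - net.number_of_nodes()

    if cfg.fsw_cutoff is not None:
        doomed = [
            (a, b)
            for a, b, data in net.edges(data=True)
            if data.get("fsw", 0.0) < cfg.fsw_cutoff
        ]
        net.remove_edges_from(doomed)
        report["fsw_edges_removed"] = len(doomed)
        refresh_degrees(net)

    return net, report


def read_foldchange_table(path) -> list[tuple[str, float]]:
    """Read two-column identifier / fold-change lines (tab or whitespace)."""
    entries = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected identifier and fold change")
            try:
                fc = float(parts[1])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric fold change {parts[1]!r}"
                ) from None
            entries.append((parts[0], fc))
    return entries


def annotate_expression(
    net: Network,
    table: Sequence[tuple[str, float]],
    cfg: ExpressionConfig,
    resolver: Optional[dict[str, str]] = None,
) -> Network:
    """Attach fold change, regulation and display overrides in-place.

    Regulation uses closed boundaries: up iff fc >= up_cutoff, down iff
    fc <= down_cutoff, else unchanged. Duplicate identifiers keep the
    last value with a warning; identifiers missing from the network are
    ignored; untouched nodes keep regulation "none".
    """
    values: dict[str, float] = {}
    for token, fc in table:
        node = (resolver or {}).get(token, token)
        if node in values:
            warnings.warn(f"duplicate fold-change identifier {token}; last value wins")
        values[node] = fc
    for node, fc in values.items():
        if node not in net:
            continue
        data = net.nodes[node]
        data["fold_change"] = fc
        if fc >= cfg.up_cutoff:
            data["regulation"] = "up"
        elif fc <= cfg.down_cutoff:
            data["regulation"] = "down"
        else:
            data["regulation"] = "unchanged"
    refresh_display(net, size_scaling=cfg.size_scaling)
    return net


def build_network(
    seeds: Sequence[str],
    store: InteractionStore,
    catalog: AnnotationCatalog,
    cfg: BuildConfig,
    preys: Optional[Sequence[str]] = None,
) -> tuple[Network, dict[str, int]]:
    """Full pipeline: expand, attach bait, score, p-values, filters."""
    net = expand(seeds, store, cfg, catalog)
    if cfg.bait:
        attach_bait(net, cfg.bait, preys if preys is not None else list(net.nodes),
                    store, catalog)
    score_edges(net, store, catalog)
    if cfg.background_organism:
        compute_node_significance(net, store, cfg.background_organism)
    net, report = apply_filters(net, cfg)
    if cfg.recompute_fsw_post_filter and net.number_of_nodes():
        fsw_cfg = scoring.make_fsw_config(net)
        for a, b, data in net.edges(data=True):
            data["fsw"] = scoring.fsw_score(a, b, net, fsw_cfg)
    refresh_degrees(net)
    refresh_display(net)
    return net, report
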