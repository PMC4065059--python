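"""Cytoscape-compatible XGMML serialization (2.8-era dialect).

Writes one ``graph`` element with ``node``/``edge`` children carrying
typed ``att`` elements and ``graphics`` hints; element ordering is
deterministic (nodes then edges, each sorted), so output is
byte-reproducible. A reader reconstructs networks for round-tripping.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional
from xml.sax.saxutils import escape, quoteattr

import networkx as nx

from .types import canonical_pair

XGMML_NS = "http://www.cs.rpi.edu/XGMML"

#: (xgmml attribute name, internal key, att type)
NODE_ATTS = [
    ("Node Type", "entity_kind", "string"),
    ("Level", "level", "integer"),
    ("Seed", "seed", "boolean"),
    ("Bait", "bait", "boolean"),
    ("Organism", "organism", "string"),
    ("Symbol", "symbol", "string"),
    ("Selected CC", "selected_cc", "list"),
    ("Top Enriched BP", "top_bp", "string"),
    ("Top Enriched KEGG", "top_kegg", "string"),
    ("Degree", "degree", "integer"),
    ("P-value", "p_value", "real"),
    ("Raw Z", "raw_z", "real"),
    ("Std Z", "std_z", "real"),
    ("Fold Change", "fold_change", "real"),
    ("Regulation", "regulation", "string"),
]

EDGE_ATTS = [
    ("Class", "class", "string"),
    ("Class Score", "class_score", "integer"),
    ("FSW", "fsw", "real"),
    ("Experimental", "experimental", "boolean"),
    ("Novel", "novel", "boolean"),
    ("PubMed IDs", "pmids", "list"),
    ("Methods", "methods", "list"),
    ("Sources", "sources", "list"),
]

_NODE_KEY_BY_NAME = {name: (key, typ) for name, key, typ in NODE_ATTS}
_EDGE_KEY_BY_NAME = {name: (key, typ) for name, key, typ in EDGE_ATTS}

LIST_SEP = "|"


class XgmmlError(ValueError):
    """Raised on malformed XGMML input."""


def _format_value(value, typ: str) -> Optional[tuple[str, str]]:
    """(xgmml type, string value) or None when the field is unset."""
    if value is None:
        return None
    if typ == "string":
        return ("string", str(value))
    if typ == "integer":
        return ("integer", str(int(value)))
    if typ == "real":
        return ("real", repr(float(value)))
    if typ == "boolean":
        return ("integer", "1" if value else "0")
    if typ == "list":
        return ("string", LIST_SEP.join(str(v) for v in value))
    raise ValueError(f"unknown att type {typ}")


def _parse_value(raw: str, typ: str):
    if typ == "string":
        return raw
    if typ == "integer":
        return int(raw)
    if typ == "real":
        return float(raw)
    if typ == "boolean":
        return raw == "1"
    if typ == "list":
        return raw.split(LIST_SEP) if raw else []
    raise ValueError(f"unknown att type {typ}")


def _att_lines(data: dict, spec, indent: str) -> list[str]:
    lines = []
    for name, key, typ in spec:
        if key not in data:
            continue
        formatted = _format_value(data[key], typ)
        if formatted is None:
            continue
        xtype, value = formatted
        lines.append(
            f'{indent}<att name={quoteattr(name)} type="{xtype}" value={quoteattr(value)}/>'
        )
    for name, value in sorted(data.get("extra", {}).items()):
        lines.append(
            f'{indent}<att name={quoteattr(name)} type="string" value={quoteattr(str(value))}/>'
        )
    return lines


def write_xgmml(net: nx.Graph, path) -> None:
    """Serialize a network to XGMML; deterministic byte-for-byte."""
    lines = ['<?xml version="1.0" encoding="UTF-8"?>']
    name = net.graph.get("name", "ixnet")
    lines.append(
        f'<graph label={quoteattr(name)} directed="0" xmlns="{XGMML_NS}">'
    )
    for node in sorted(net.nodes):
        data = net.nodes[node]
        label = data.get("symbol", node)
        lines.append(f"  <node id={quoteattr(str(node))} label={quoteattr(str(label))}>")
        lines.extend(_att_lines(data, NODE_ATTS, "    "))
        shape = data.get("shape")
        if shape is not None:
            size = data.get("size", 35.0)
            fill = data.get("color", "#C0C0C0")
            lines.append(
                f'    <graphics type={quoteattr(shape)} fill={quoteattr(fill)} '
                f'w="{repr(float(size))}" h="{repr(float(size))}"/>'
            )
        lines.append("  </node>")
    for a, b in sorted(canonical_pair(u, v) for u, v in net.edges):
        data = net.edges[a, b]
        label = f"{a} (pp) {b}"
        lines.append(
            f"  <edge source={quoteattr(str(a))} target={quoteattr(str(b))} "
            f"label={quoteattr(label)}>"
        )
        lines.extend(_att_lines(data, EDGE_ATTS, "    "))
        width = data.get("width")
        if width is not None:
            lines.append(f'    <graphics width="{repr(float(width))}" fill="#999999"/>')
        lines.append("  </edge>")
    lines.append("</graph>")
    Path(path).write_bytes(("\n".join(lines) + "\n").encode("utf-8"))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _read_atts(element, spec_by_name, data: dict, where: str) -> None:
    for child in element:
        tag = _local(child.tag)
        if tag == "att":
            name = child.get("name")
            value = child.get("value")
            if name is None or value is None:
                raise XgmmlError(f"{where}: att element missing name/value")
            if name in spec_by_name:
                key, typ = spec_by_name[name]
                data[key] = _parse_value(value, typ)
            else:
                data.setdefault("extra", {})[name] = value
        elif tag == "graphics":
            if "width" in child.attrib:
                data["width"] = float(child.get("width"))
            if "type" in child.attrib:
                data["shape"] = child.get("type")
            if "fill" in child.attrib and _local(element.tag) == "node":
                data["color"] = child.get("fill")
            if "w" in child.attrib:
                data["size"] = float(child.get("w"))


def read_xgmml(path) -> nx.Graph:
    """Parse an XGMML file written by :func:`write_xgmml` (or compatible)."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise XgmmlError(f"{path}: malformed XGMML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "graph":
        raise XgmmlError(f"{path}: root element is <{_local(root.tag)}>, expected <graph>")
    net = nx.Graph()
    net.graph["name"] = root.get("label", "ixnet")
    for element in root:
        tag = _local(element.tag)
        if tag == "node":
            node_id = element.get("id")
            if node_id is None:
                raise XgmmlError(f"{path}: <node> without id")
            data: dict = {"symbol": element.get("label", node_id)}
            _read_atts(element, _NODE_KEY_BY_NAME, data, f"node {node_id}")
            net.add_node(node_id, **data)
    for element in root:
        if _local(element.tag) == "edge":
            a, b = element.get("source"), element.get("target")
            if a is None or b is None:
                raise XgmmlError(f"{path}: <edge> without source/target")
            if a not in net or b not in net:
                raise XgmmlError(f"{path}: edge {a}-{b} references unknown node")
            data = {}
            _read_atts(element, _EDGE_KEY_BY_NAME, data, f"edge {a}-{b}")
            net.add_edge(a, b, **data)
    return net


def _projection(net: nx.Graph):
    nodes = {}
    for node in net.nodes:
        data = net.nodes[node]
        atts = {}
        for name, key, typ in NODE_ATTS:
            if key in data:
                formatted = _format_value(data[key], typ)
                if formatted is not None:
                    atts[name] = formatted
        for name, value in data.get("extra", {}).items():
            atts[name] = ("string", str(value))
        for key in ("shape", "color", "size"):
            if data.get(key) is not None:
                atts[key] = str(data[key]) if key != "size" else repr(float(data[key]))
        nodes[str(node)] = atts
    edges = {}
    for u, v in net.edges:
        data = net.edges[u, v]
        atts = {}
        for name, key, typ in EDGE_ATTS:
            if key in data:
                formatted = _format_value(data[key], typ)
                if formatted is not None:
                    atts[name] = formatted
        if data.get("width") is not None:
            atts["width"] = repr(float(data["width"]))
        edges[canonical_pair(str(u), str(v))] = atts
    return nodes, edges


def networks_equal(a: nx.Graph, b: nx.Graph) -> bool:
    """Attribute-wise equality over everything XGMML serializes."""
    return _projection(a) == _projection(b)


def write_edge_list(net: nx.Graph, path) -> None:
    """Plain TSV edge list for diffing."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id_a\tid_b\tclass\tclass_score\tfsw\n")
        for a, b in sorted(canonical_pair(u, v) for u, v in net.edges):
            data = net.edges[a, b]
            fh.write(
                f"{a}\t{b}\t{data.get('class', '')}\t{data.get('class_score', '')}\t"
                f"{data.get('fsw', '')}\n"
            )
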