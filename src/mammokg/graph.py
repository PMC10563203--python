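"""Knowledge-graph compilation, export, semantic query and CAD association.

Every report instantiates the full concept-layer skeleton regardless of
content: one Report node with ``has_a`` edges to its three children
(basic information, mammography information, BI-RADS information), the
mammography-information node with ``instance_of`` edges to the four
first-level sign groups, and each first-level group with ``part_of``
edges to its mapped feature types (15 per report).  The ``has_a`` /
``instance_of`` / ``part_of`` totals are therefore the
content-independent constants 3n / 4n / 15n for n reports; only the
``select`` edges — extracted attribute values, demographics and the
BI-RADS category — depend on report content.

The graph is a property graph held in a :class:`networkx.MultiDiGraph`;
exports target Neo4j-style tooling (GraphML, a Cypher CREATE script,
CSV node/edge tables).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import networkx as nx

from .corpus_io import BIRADS_CATEGORIES, Demographics
from .fusion import ANCHOR_TYPES, ANCHOR_OWNER_MAP, Finding
from .schema import ConceptLayer, Triple, validate_triple

__all__ = [
    "ReportRecord",
    "AssociationResult",
    "GraphError",
    "build_graph",
    "edge_counts",
    "validate_graph",
    "export_graph",
    "import_graphml",
    "query_patients",
    "feature_category_association",
]


class GraphError(ValueError):
    pass


@dataclass
class ReportRecord:
    """Input to graph construction: one report's fused content."""

    report_id: str
    demographics: Demographics | None
    findings: list[Finding]
    birads_category: str | None


@dataclass
class AssociationResult:
    """Conditional BI-RADS distribution for a feature combination."""

    feature_predicate: str
    support: int
    category_distribution: dict[str, float]
    top_category: str | None


def _add_node(g, node_id, label, **props):
    g.add_node(node_id, label=label, **props)
    return node_id


def _add_edge(g, schema, src, pred, dst, **props):
    s_label = g.nodes[src]["label"]
    d = g.nodes[dst]
    d_label = d.get("value", d["label"]) if d["label"] == "Attribute" else d["label"]
    if not validate_triple(Triple(s_label, pred, d_label), schema):
        raise GraphError(f"triple ({s_label}, {pred}, {d_label}) violates the schema")
    g.add_edge(src, dst, predicate=pred, **props)


def build_graph(records: Sequence[ReportRecord], schema: ConceptLayer) -> nx.MultiDiGraph:
    """Compile fused findings, demographics and categories into the KG."""
    g = nx.MultiDiGraph()
    for rec in records:
        rid = rec.report_id
        report = _add_node(g, f"{rid}", "Report", report_id=rid)
        children = {}
        for child in schema.report_children:
            children[child] = _add_node(g, f"{rid}:{child}", child, report_id=rid)
            _add_edge(g, schema, report, "has_a", children[child])

        mammo = children["Mammography information"]
        first_level = {}
        for fl in schema.first_level_entities:
            first_level[fl] = _add_node(g, f"{rid}:{fl}", fl, report_id=rid)
            _add_edge(g, schema, mammo, "instance_of", first_level[fl])

        ftype_nodes = {}
        for ftype, parent in schema.feature_type_map.items():
            ftype_nodes[ftype] = _add_node(g, f"{rid}:{ftype}", ftype, report_id=rid)
            _add_edge(g, schema, first_level[parent], "part_of", ftype_nodes[ftype])

        def value_node(value: str):
            nid = f"{rid}:V:{value}"
            if nid not in g:
                _add_node(g, nid, "Attribute", value=value, report_id=rid)
            return nid

        basic = children["Basic information"]
        if rec.demographics is not None:
            g.nodes[basic]["sex"] = rec.demographics.sex
            g.nodes[basic]["age"] = int(rec.demographics.age)
            _add_edge(g, schema, basic, "select", value_node(rec.demographics.sex))
            _add_edge(g, schema, basic, "select", value_node(str(rec.demographics.age)))

        birads = children["BI-RADS information"]
        if rec.birads_category is not None:
            if rec.birads_category not in BIRADS_CATEGORIES:
                raise GraphError(f"unknown BI-RADS category {rec.birads_category!r}")
            g.nodes[birads]["category"] = rec.birads_category
            _add_edge(g, schema, birads, "select",
                      value_node(f"BI-RADS {rec.birads_category}"))

        for f_idx, finding in enumerate(rec.findings):
            if finding.kind not in ANCHOR_TYPES:
                raise GraphError(f"finding kind {finding.kind!r} is not an anchor type")
            owner = ANCHOR_OWNER_MAP[finding.kind]
            licensed = set(schema.licensed_slots(owner))
            anchor = ftype_nodes[finding.kind]
            vnode = value_node(finding.value)
            # polarity lives on the edge: value nodes are shared per report
            _add_edge(g, schema, anchor, "select", vnode, finding=f_idx,
                      negated=bool(finding.negated))
            for slot, values in finding.attributes.items():
                if slot not in licensed:
                    raise GraphError(
                        f"{rid}: slot {slot!r} is not licensed for {owner!r}"
                    )
                for value in values:
                    _add_edge(g, schema, anchor, "select", value_node(value),
                              finding=f_idx, slot=slot)
    return g


def edge_counts(g: nx.MultiDiGraph) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, _, data in g.edges(data=True):
        counts[data["predicate"]] = counts.get(data["predicate"], 0) + 1
    return counts


def validate_graph(g: nx.MultiDiGraph, schema: ConceptLayer) -> None:
    """Re-check every node and edge against the concept layer."""
    for node, data in g.nodes(data=True):
        label = data.get("label")
        if label is None:
            raise GraphError(f"node {node!r} has no label")
        if label != "Attribute" and not schema.is_entity_name(label):
            raise GraphError(f"node {node!r} has unknown label {label!r}")
    for src, dst, data in g.edges(data=True):
        pred = data.get("predicate")
        if pred not in schema.predicates:
            raise GraphError(f"edge {src}->{dst} has unknown predicate {pred!r}")
        s_label = g.nodes[src]["label"]
        d = g.nodes[dst]
        d_label = d.get("value", d["label"]) if d["label"] == "Attribute" else d["label"]
        if not validate_triple(Triple(s_label, pred, d_label), schema):
            raise GraphError(f"edge ({s_label}, {pred}, {d_label}) violates the schema")


# -- export ----------------------------------------------------------------

def _cypher_quote(value) -> str:
    return json.dumps(value, ensure_ascii=False)


def export_graph(g: nx.MultiDiGraph, fmt: str, out_path: str) -> str:
    """Write the graph as ``graphml``, ``cypher`` or ``csv``.

    ``csv`` writes ``<out_path>_nodes.csv`` and ``<out_path>_edges.csv``
    and returns the node-table path; the other formats write one file.
    """
    if fmt == "graphml":
        nx.write_graphml(g, out_path, encoding="utf-8")
        return out_path
    if fmt == "cypher":
        lines = []
        for node, data in g.nodes(data=True):
            label = data["label"].replace(" ", "_").replace("-", "_")
            props = {"id": str(node)}
            props.update({k: v for k, v in data.items() if k != "label"})
            body = ", ".join(f"{k}: {_cypher_quote(v)}" for k, v in props.items())
            lines.append(f"CREATE (:{label} {{{body}}});")
        for src, dst, data in g.edges(data=True):
            pred = data["predicate"]
            lines.append(
                f"MATCH (a {{id: {_cypher_quote(str(src))}}}), "
                f"(b {{id: {_cypher_quote(str(dst))}}}) "
                f"CREATE (a)-[:{pred}]->(b);"
            )
        with open(out_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
        return out_path
    if fmt == "csv":
        import csv

        node_path = f"{out_path}_nodes.csv"
        edge_path = f"{out_path}_edges.csv"
        with open(node_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["id", "label", "props"])
            for node, data in g.nodes(data=True):
                props = {k: v for k, v in data.items() if k != "label"}
                w.writerow([node, data["label"],
                            json.dumps(props, ensure_ascii=False, sort_keys=True)])
        with open(edge_path, "w", encoding="utf-8", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["src", "rel", "dst"])
            for src, dst, data in g.edges(data=True):
                w.writerow([src, data["predicate"], dst])
        return node_path
    raise GraphError(f"unknown export format {fmt!r}")


def import_graphml(path: str) -> nx.MultiDiGraph:
    g = nx.read_graphml(path, force_multigraph=True)
    return nx.MultiDiGraph(g)


# -- queries ---------------------------------------------------------------

def _report_meta(g: nx.MultiDiGraph):
    """(report_id, age, category) rows recovered from the graph."""
    rows = []
    for node, data in g.nodes(data=True):
        if data.get("label") != "Report":
            continue
        rid = data.get("report_id", str(node))
        age, category = None, None
        for _, dst, edata in g.edges(node, data=True):
            if edata["predicate"] != "has_a":
                continue
            child = g.nodes[dst]
            if child["label"] == "Basic information":
                age = child.get("age")
            elif child["label"] == "BI-RADS information":
                category = child.get("category")
        rows.append((rid, age, category))
    return rows


def query_patients(g: nx.MultiDiGraph, age_range: tuple[int, int],
                   birads_category: str) -> list[str]:
    """Report ids with age in the inclusive range and the given category."""
    lo, hi = age_range
    if lo > hi:
        raise GraphError(f"invalid age range [{lo}, {hi}]")
    out = [
        rid for rid, age, cat in _report_meta(g)
        if age is not None and lo <= age <= hi and cat == birads_category
    ]
    return sorted(out)


def _findings_per_report(g: nx.MultiDiGraph):
    """report_id -> list of findings rebuilt from select edges."""
    per_report: dict[str, dict[tuple[str, int], dict]] = {}
    for src, dst, data in g.edges(data=True):
        if data["predicate"] != "select" or "finding" not in data:
            continue
        sdata = g.nodes[src]
        kind = sdata["label"]
        rid = sdata.get("report_id")
        f = per_report.setdefault(rid, {}).setdefault(
            (kind, data["finding"]),
            {"kind": kind, "value": None, "attributes": {}, "negated": False},
        )
        value = g.nodes[dst].get("value")
        if "slot" in data:
            f["attributes"].setdefault(data["slot"], []).append(value)
        else:
            f["value"] = value
            if data.get("negated"):
                f["negated"] = True
    return {rid: list(fs.values()) for rid, fs in per_report.items()}


def feature_category_association(
    g: nx.MultiDiGraph,
    conditions: Sequence[tuple[str, str | None]],
    lexicon=None,
) -> AssociationResult:
    """Conditional BI-RADS category distribution given feature conditions.

    Each condition is ``(feature type, value)`` — an anchor type with an
    optional value, or an attribute type with a canonical value.  A
    report counts toward the support when one non-negated finding
    satisfies every condition.
    """
    from .schema import FEATURE_TYPES

    for ftype, value in conditions:
        if ftype not in FEATURE_TYPES:
            raise GraphError(f"unknown feature type {ftype!r}")
        if lexicon is not None and value is not None and ftype in lexicon.types():
            if value not in lexicon.canonicals(ftype):
                raise GraphError(f"{value!r} is not a canonical {ftype} value")

    findings = _findings_per_report(g)
    categories = {rid: cat for rid, _, cat in _report_meta(g)}

    def satisfies(f: dict, ftype: str, value) -> bool:
        if f["negated"]:
            return False
        if ftype in ANCHOR_TYPES:
            return f["kind"] == ftype and (value is None or f["value"] == value)
        return value in f["attributes"].get(ftype, ())

    matched = [
        rid for rid, fs in findings.items()
        if any(all(satisfies(f, ft, v) for ft, v in conditions) for f in fs)
    ]
    support = len(matched)
    dist: dict[str, float] = {}
    if support:
        for rid in matched:
            cat = categories.get(rid)
            if cat is not None:
                dist[cat] = dist.get(cat, 0) + 1
        total = sum(dist.values())
        dist = {c: n / total for c, n in sorted(dist.items())}
    top = max(dist, key=lambda c: (dist[c], c)) if dist else None
    predicate = " AND ".join(
        f"{ft}={v}" if v is not None else ft for ft, v in conditions
    )
    return AssociationResult(predicate, support, dist, top)
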