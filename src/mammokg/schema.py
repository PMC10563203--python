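"""Concept layer (ontology) of the mammography knowledge graph.

The knowledge graph is built top-down: a fixed concept layer — four
first-level sign groups, nine second-level entities, 39 attribute slots
and four relation predicates (``has_a``, ``instance_of``, ``part_of``,
``select``) — constrains everything the data layer may store.  The
concept layer is data, not code: it ships as ``data/concept_layer.yaml``
so the same engine can be re-targeted at other report types by swapping
the schema file.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

__all__ = [
    "ConceptLayer",
    "Triple",
    "SchemaError",
    "PREDICATES",
    "FEATURE_TYPES",
    "load_schema",
    "default_schema",
    "validate_triple",
]

#: The four relation predicates of the concept layer.
PREDICATES = frozenset({"has_a", "instance_of", "part_of", "select"})

#: The 15 data-layer mammography feature types.
FEATURE_TYPES = (
    "Calcification",
    "Density",
    "Distribute",
    "Location",
    "Mass",
    "Lymph Node",
    "Margin",
    "Merge",
    "Number",
    "Shape",
    "Size",
    "Special",
    "Structure",
    "Category descriptions",
    "Negation",
)


class SchemaError(ValueError):
    """Raised when a schema file violates a concept-layer invariant."""


@dataclass(frozen=True)
class Triple:
    """A subject-predicate-object statement of the concept layer."""

    subject: str
    predicate: str
    object: str


@dataclass
class ConceptLayer:
    """The validated concept layer.

    Parameters
    ----------
    first_level_entities
        The four first-level sign groups.
    second_level_entities
        Mapping second-level entity name -> first-level parent (9 entries).
    attribute_slots
        Mapping owner entity -> attribute slot names (39 slots in total).
    report_children
        Report-level entities attached to each report node.
    predicates
        The four relation predicates.
    feature_type_map
        Mapping each of the 15 data-layer feature types -> first-level parent.
    select_subjects
        Report children licensed to ``select`` attribute values directly.
    chinese_names
        Optional Chinese surface form per English entity key.
    """

    first_level_entities: list[str]
    second_level_entities: dict[str, str]
    attribute_slots: dict[str, list[str]]
    report_children: list[str]
    predicates: set[str]
    feature_type_map: dict[str, str]
    select_subjects: list[str] = field(default_factory=list)
    chinese_names: dict[str, str] = field(default_factory=dict)

    def validate(self) -> "ConceptLayer":
        """Check every structural invariant; raise :class:`SchemaError` on failure."""
        if len(self.first_level_entities) != 4:
            raise SchemaError(
                f"expected 4 first-level entities, got {len(self.first_level_entities)}"
            )
        if len(self.second_level_entities) != 9:
            raise SchemaError(
                f"expected 9 second-level entities, got {len(self.second_level_entities)}"
            )
        if set(self.predicates) != PREDICATES:
            raise SchemaError(
                f"expected predicates {sorted(PREDICATES)}, got {sorted(self.predicates)}"
            )
        if len(self.report_children) != 3:
            raise SchemaError(
                f"expected 3 report children, got {len(self.report_children)}"
            )
        n_slots = sum(len(v) for v in self.attribute_slots.values())
        if n_slots != 39:
            raise SchemaError(f"expected 39 attribute slots in total, got {n_slots}")
        for name, parent in self.second_level_entities.items():
            if parent not in self.first_level_entities:
                raise SchemaError(
                    f"second-level entity {name!r} names unknown parent {parent!r}"
                )
        if len(self.feature_type_map) != 15:
            raise SchemaError(
                f"expected 15 feature types, got {len(self.feature_type_map)}"
            )
        if set(self.feature_type_map) != set(FEATURE_TYPES):
            missing = set(FEATURE_TYPES) - set(self.feature_type_map)
            extra = set(self.feature_type_map) - set(FEATURE_TYPES)
            raise SchemaError(
                f"feature_type_map keys mismatch (missing={sorted(missing)}, "
                f"extra={sorted(extra)})"
            )
        for ftype, parent in self.feature_type_map.items():
            if parent not in self.first_level_entities:
                raise SchemaError(
                    f"feature type {ftype!r} maps to unknown first-level {parent!r}"
                )
        for owner in self.attribute_slots:
            if (
                owner not in self.second_level_entities
                and owner not in self.first_level_entities
            ):
                raise SchemaError(f"attribute owner {owner!r} is not a schema entity")
        for subj in self.select_subjects:
            if subj not in self.report_children:
                raise SchemaError(
                    f"select subject {subj!r} is not a report child"
                )
        return self

    # -- name classification helpers -------------------------------------

    def is_entity_name(self, name: str) -> bool:
        """True if *name* denotes a concept-layer entity (not an attribute value)."""
        return (
            name == "Report"
            or name in self.report_children
            or name in self.first_level_entities
            or name in self.second_level_entities
            or name in self.feature_type_map
        )

    def licensed_slots(self, owner: str) -> Sequence[str]:
        return self.attribute_slots.get(owner, ())


def _parse(doc: Mapping) -> ConceptLayer:
    try:
        first = [e["key"] for e in doc["first_level"]]
        zh = {e["key"]: e.get("zh", "") for e in doc["first_level"]}
        second = {}
        for name, meta in doc["second_level"].items():
            second[name] = meta["parent"]
            if "zh" in meta:
                zh[name] = meta["zh"]
        layer = ConceptLayer(
            first_level_entities=first,
            second_level_entities=second,
            attribute_slots={k: list(v) for k, v in doc["attributes"].items()},
            report_children=list(doc["report_children"]),
            predicates=set(doc["predicates"]),
            feature_type_map=dict(doc["feature_type_map"]),
            select_subjects=list(doc.get("select_subjects", [])),
            chinese_names=zh,
        )
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"malformed schema document: {exc}") from exc
    return layer.validate()


def load_schema(path) -> ConceptLayer:
    """Load and validate a concept-layer YAML file."""
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise SchemaError("schema file does not contain a mapping document")
    return _parse(doc)


def default_schema() -> ConceptLayer:
    """The packaged default concept layer (``data/concept_layer.yaml``)."""
    ref = importlib.resources.files("mammokg.data").joinpath("concept_layer.yaml")
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return _parse(doc)


def validate_triple(t: Triple, schema: ConceptLayer) -> bool:
    """Check a triple against the five licensed subject/predicate/object patterns.

    Patterns: a licensed report child ``select``-ing an attribute value;
    ``Report has_a`` report child; ``Mammography information instance_of``
    first-level entity; first-level ``part_of`` its second-level entities
    or mapped feature types; a second-level entity or feature type
    ``select``-ing an attribute value.  Unknown names yield ``False``,
    never an exception.
    """
    s, p, o = t.subject, t.predicate, t.object
    if p not in schema.predicates:
        return False
    if p == "has_a":
        return s == "Report" and o in schema.report_children
    if p == "instance_of":
        return s == "Mammography information" and o in schema.first_level_entities
    if p == "part_of":
        if s not in schema.first_level_entities:
            return False
        if o in schema.second_level_entities:
            return schema.second_level_entities[o] == s
        if o in schema.feature_type_map:
            return schema.feature_type_map[o] == s
        return False
    # p == "select": the object must be an attribute value, i.e. not an entity.
    if schema.is_entity_name(o) and o not in schema.feature_type_map:
        # Feature-type names double as attribute values only when they are
        # genuinely values; plain entity names are rejected.
        return False
    if s in schema.select_subjects:
        return True
    return s in schema.second_level_entities or s in schema.feature_type_map
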