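"""Schema core for the Study-Experiment-Assay (SEA) common data model.

The model has 13 classes: 10 core classes (Study, Experiment, Assay, Subject,
Sample, Group, Intervention, Occurrence, Analysis, Result) linked by foreign
keys, and 3 accessory classes (Material, Ontology, Documentation).  Each class
becomes a table in a relational store or a node type in a knowledge graph.
Attributes holding controlled terms are paired with a ``<name>_ontology_id``
column carrying the CURIE of the ontology term.

The canonical class definitions live in the machine-readable schema file
``data/sea_cdm_schema.yaml`` shipped with the package;
:func:`build_default_registry` loads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Any, Iterable, Mapping

import yaml

__all__ = [
    "AttributeDef",
    "ForeignKeyDef",
    "ClassDef",
    "SchemaRegistry",
    "Violation",
    "ValidationReport",
    "build_default_registry",
    "validate_record",
    "validate_bundle",
    "emit_ddl",
    "EXTENDED_TABLE",
    "CORE_CLASSES",
    "ACCESSORY_CLASSES",
]

#: Name of the side table holding attributes outside the fixed schema.
EXTENDED_TABLE = "extended_attribute"

#: Columns of the extended-attribute side table (long format).
EXTENDED_COLUMNS = ("class", "record_id", "name", "value", "ontology_id")

CORE_CLASSES = frozenset(
    {
        "Study",
        "Experiment",
        "Assay",
        "Subject",
        "Sample",
        "Group",
        "Intervention",
        "Occurrence",
        "Analysis",
        "Result",
    }
)
ACCESSORY_CLASSES = frozenset({"Material", "Ontology", "Documentation"})

VALUE_KINDS = frozenset({"text", "number", "date", "identifier", "controlled"})
CATEGORIES = frozenset({"process", "material_entity", "data_item"})


@dataclass(frozen=True)
class AttributeDef:
    """One attribute (column) of a model class.

    ``has_ontology_pair`` attributes own a companion column named
    ``<name>_ontology_id`` that stores the CURIE of the controlled term
    standardizing the value.
    """

    name: str
    value_kind: str = "text"
    has_ontology_pair: bool = False
    required: bool = False
    controlled_values: tuple[str, ...] | None = None
    provisional: bool = False

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r} for {self.name!r}")

    @property
    def ontology_column(self) -> str | None:
        return f"{self.name}_ontology_id" if self.has_ontology_pair else None


@dataclass(frozen=True)
class ForeignKeyDef:
    """A cross-link column: ``column`` references ``target_class.target_column``."""

    column: str
    target_class: str
    target_column: str


@dataclass(frozen=True)
class ClassDef:
    """One model class: a table in the relational store, a node type in the KG."""

    name: str
    kind: str  # "core" | "accessory"
    category: str  # "process" | "material_entity" | "data_item"
    primary_key: str
    attributes: tuple[AttributeDef, ...]
    foreign_keys: tuple[ForeignKeyDef, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("core", "accessory"):
            raise ValueError(f"{self.name}: kind must be core or accessory")
        if self.category not in CATEGORIES:
            raise ValueError(f"{self.name}: unknown category {self.category!r}")
        names = [a.name for a in self.attributes]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.name}: duplicate attribute names")
        if self.primary_key not in names:
            raise ValueError(f"{self.name}: primary key {self.primary_key!r} not an attribute")

    def attribute(self, name: str) -> AttributeDef | None:
        for a in self.attributes:
            if a.name == name:
                return a
        return None

    @property
    def columns(self) -> list[str]:
        """All physical columns: each attribute followed by its ontology pair."""
        cols: list[str] = []
        for a in self.attributes:
            cols.append(a.name)
            if a.has_ontology_pair:
                cols.append(a.ontology_column)  # type: ignore[arg-type]
        return cols


@dataclass
class SchemaRegistry:
    """The full class catalogue plus the derived relation graph."""

    classes: dict[str, ClassDef]

    def __post_init__(self) -> None:
        for cdef in self.classes.values():
            for fk in cdef.foreign_keys:
                target = self.classes.get(fk.target_class)
                if target is None:
                    raise ValueError(
                        f"{cdef.name}.{fk.column}: FK target class {fk.target_class!r} missing"
                    )
                if fk.target_column != target.primary_key:
                    raise ValueError(
                        f"{cdef.name}.{fk.column}: FK must reference the primary key "
                        f"of {fk.target_class} ({target.primary_key!r})"
                    )

    def __contains__(self, name: str) -> bool:
        return name in self.classes

    def __getitem__(self, name: str) -> ClassDef:
        return self.classes[name]

    @property
    def relations(self) -> list[tuple[str, str, str]]:
        """Directed edges (source class, fk column, target class)."""
        return [
            (cdef.name, fk.column, fk.target_class)
            for cdef in self.classes.values()
            for fk in cdef.foreign_keys
        ]

    @property
    def core_classes(self) -> set[str]:
        return {n for n, c in self.classes.items() if c.kind == "core"}

    @property
    def accessory_classes(self) -> set[str]:
        return {n for n, c in self.classes.items() if c.kind == "accessory"}


@dataclass(frozen=True)
class Violation:
    class_name: str
    row: int | None
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def add(self, class_name: str, row: int | None, rule: str, message: str) -> None:
        self.violations.append(Violation(class_name, row, rule, message))

    def extend(self, other: "ValidationReport") -> None:
        self.violations.extend(other.violations)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        status = "ok" if self.ok else f"{len(self.violations)} violation(s)"
        return f"<ValidationReport {status}>"


def _parse_class(name: str, raw: Mapping[str, Any]) -> ClassDef:
    attrs = tuple(
        AttributeDef(
            name=a["name"],
            value_kind=a.get("value_kind", "text"),
            has_ontology_pair=bool(a.get("ontology_pair", False)),
            required=bool(a.get("required", False)),
            controlled_values=tuple(a["controlled_values"]) if "controlled_values" in a else None,
            provisional=bool(a.get("provisional", False)),
        )
        for a in raw["attributes"]
    )
    fks = tuple(
        ForeignKeyDef(f["column"], f["target_class"], f["target_column"])
        for f in raw.get("foreign_keys", [])
    )
    return ClassDef(
        name=name,
        kind=raw["kind"],
        category=raw["category"],
        primary_key=raw["primary_key"],
        attributes=attrs,
        foreign_keys=fks,
    )


def load_registry(schema_mapping: Mapping[str, Any]) -> SchemaRegistry:
    """Build a registry from a parsed schema mapping (the YAML file's content)."""
    classes = {name: _parse_class(name, raw) for name, raw in schema_mapping["classes"].items()}
    return SchemaRegistry(classes=classes)


def build_default_registry() -> SchemaRegistry:
    """Load the canonical 13-class model from the shipped schema file.

    The registry has 10 core classes and 3 accessory classes (Material,
    Ontology, Documentation), with the relation graph
    Experiment→Study, Subject→Experiment/Group, Sample→Subject,
    Intervention→Subject/Material, Occurrence→Subject,
    Assay→Experiment/Sample, Result→Assay, Analysis→Group/Result.
    """
    text = resources.files("seacdm.data").joinpath("sea_cdm_schema.yaml").read_text()
    registry = load_registry(yaml.safe_load(text))
    # sanity: the canonical model is fixed at 13 = 10 core + 3 accessory
    assert len(registry.classes) == 13
    assert registry.core_classes == set(CORE_CLASSES)
    assert registry.accessory_classes == set(ACCESSORY_CLASSES)
    return registry


def _is_null(value: Any) -> bool:
    return value is None or (isinstance(value, str) and value == "")


def validate_record(
    registry: SchemaRegistry,
    class_name: str,
    record: Mapping[str, Any],
    row: int | None = None,
    allow_extended: bool = True,
) -> ValidationReport:
    """Check one record against its class definition.

    Rules: required attributes present and non-null; ontology-id pair columns
    must not carry an id for an empty attribute value; controlled attributes
    must take values from their enumerated set; fields outside the schema are
    accepted as extended attributes when ``allow_extended`` (the default) and
    flagged otherwise.

    Raises ``KeyError`` for an unknown class name (an unknown class is a
    caller bug, not a data problem).
    """
    if class_name not in registry:
        raise KeyError(f"unknown class {class_name!r}")
    cdef = registry[class_name]
    report = ValidationReport()
    known = set(cdef.columns)

    for attr in cdef.attributes:
        value = record.get(attr.name)
        if attr.required and _is_null(value):
            report.add(class_name, row, "required", f"missing required field {attr.name!r}")
        if (
            attr.controlled_values is not None
            and not _is_null(value)
            and str(value) not in attr.controlled_values
        ):
            report.add(
                class_name,
                row,
                "controlled",
                f"{attr.name}={value!r} not in {sorted(attr.controlled_values)}",
            )
        if attr.has_ontology_pair:
            oid = record.get(attr.ontology_column)
            if not _is_null(oid) and _is_null(value):
                report.add(
                    class_name,
                    row,
                    "ontology_pair",
                    f"{attr.ontology_column}={oid!r} given but {attr.name!r} is empty",
                )
    if not allow_extended:
        for key in record:
            if key not in known:
                report.add(class_name, row, "unknown_field", f"unknown field {key!r}")
    return report


def validate_bundle(registry: SchemaRegistry, bundle: "RecordBundle") -> ValidationReport:
    """Validate a whole bundle: per-record rules, primary-key uniqueness, and
    referential integrity of every non-null foreign-key value."""
    from .bundle import RecordBundle  # local import: bundle depends on schema

    assert isinstance(bundle, RecordBundle)
    report = ValidationReport()

    for class_name in bundle.tables:
        if class_name == EXTENDED_TABLE:
            continue
        if class_name not in registry:
            report.add(class_name, None, "unknown_class", f"class {class_name!r} not in registry")

    # primary-key index per class, for FK resolution
    key_index: dict[str, set[str]] = {}
    for class_name, records in bundle.tables.items():
        if class_name not in registry:
            continue
        cdef = registry[class_name]
        seen: set[str] = set()
        for i, record in enumerate(records):
            report.extend(validate_record(registry, class_name, record, row=i))
            pk = record.get(cdef.primary_key)
            if not _is_null(pk):
                if str(pk) in seen:
                    report.add(class_name, i, "pk_unique", f"duplicate primary key {pk!r}")
                seen.add(str(pk))
        key_index[class_name] = seen

    for class_name, records in bundle.tables.items():
        if class_name not in registry:
            continue
        for fk in registry[class_name].foreign_keys:
            targets = key_index.get(fk.target_class, set())
            for i, record in enumerate(records):
                value = record.get(fk.column)
                if not _is_null(value) and str(value) not in targets:
                    report.add(
                        class_name,
                        i,
                        "dangling_fk",
                        f"{fk.column}={value!r} has no matching "
                        f"{fk.target_class}.{fk.target_column}",
                    )
    return report


# --- DDL -----------------------------------------------------------------

_SQL_TYPES = {
    "text": "TEXT",
    "identifier": "VARCHAR(255)",
    "controlled": "VARCHAR(255)",
    "number": "DOUBLE PRECISION",
    "date": "DATE",
}
_SQLITE_TYPES = {
    "text": "TEXT",
    "identifier": "TEXT",
    "controlled": "TEXT",
    "number": "REAL",
    "date": "TEXT",
}


def emit_ddl(registry: SchemaRegistry, dialect: str = "portable") -> str:
    """Emit idempotent CREATE TABLE statements for every class plus the
    extended-attribute side table.

    ``portable`` targets embedded engines (SQLite-compatible); ``mysql`` emits
    MySQL-flavoured types and table options.  Scripts use
    ``CREATE TABLE IF NOT EXISTS`` so re-running them is safe.
    """
    if dialect not in ("portable", "mysql"):
        raise ValueError(f"unknown dialect {dialect!r}")
    types = _SQLITE_TYPES if dialect == "portable" else _SQL_TYPES
    suffix = " ENGINE=InnoDB DEFAULT CHARSET=utf8mb4" if dialect == "mysql" else ""
    quote = "`" if dialect == "mysql" else '"'

    def q(ident: str) -> str:
        return f"{quote}{ident}{quote}"

    statements: list[str] = []
    # emit targets before referencing tables so FK constraints resolve in order
    ordered = _topological_classes(registry)
    for cdef in ordered:
        lines: list[str] = []
        for attr in cdef.attributes:
            col_type = types[attr.value_kind]
            null = " NOT NULL" if attr.name == cdef.primary_key else ""
            lines.append(f"  {q(attr.name)} {col_type}{null}")
            if attr.has_ontology_pair:
                lines.append(f"  {q(attr.ontology_column)} {types['identifier']}")
        lines.append(f"  PRIMARY KEY ({q(cdef.primary_key)})")
        for fk in cdef.foreign_keys:
            lines.append(
                f"  FOREIGN KEY ({q(fk.column)}) REFERENCES "
                f"{q(fk.target_class)} ({q(fk.target_column)})"
            )
        body = ",\n".join(lines)
        statements.append(f"CREATE TABLE IF NOT EXISTS {q(cdef.name)} (\n{body}\n){suffix};")

    ext_cols = ",\n".join(f"  {q(c)} {types['text']}" for c in EXTENDED_COLUMNS)
    statements.append(f"CREATE TABLE IF NOT EXISTS {q(EXTENDED_TABLE)} (\n{ext_cols}\n){suffix};")
    return "\n\n".join(statements) + "\n"


def _topological_classes(registry: SchemaRegistry) -> list[ClassDef]:
    """Classes ordered so that FK targets precede their referencing classes."""
    order: list[ClassDef] = []
    placed: set[str] = set()
    remaining = dict(registry.classes)
    while remaining:
        progressed = False
        for name in list(remaining):
            cdef = remaining[name]
            deps = {fk.target_class for fk in cdef.foreign_keys} - {name}
            if deps <= placed:
                order.append(cdef)
                placed.add(name)
                del remaining[name]
                progressed = True
        if not progressed:  # FK cycle: emit the rest in name order
            for name in sorted(remaining):
                order.append(remaining[name])
            break
    return order
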