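"""The in-memory record container shared by all modules.

A :class:`RecordBundle` holds one table of records per model class, keyed by
class name.  Records are plain field→value mappings; fields outside the class
schema are allowed and travel to the long-format ``extended_attribute`` side
table on serialization, so heterogeneous sources never lose author-specific
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

__all__ = ["RecordBundle", "merge_bundles"]

Record = dict[str, Any]


def _norm_value(value: Any) -> str | None:
    """Canonical serialized form: None/empty → None, bool → true/false, rest → str."""
    if value is None or (isinstance(value, str) and value == ""):
        return None
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


@dataclass
class RecordBundle:
    """Per-class record tables forming one or more complete studies."""

    tables: dict[str, list[Record]] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def table(self, class_name: str) -> list[Record]:
        return self.tables.setdefault(class_name, [])

    def add(self, class_name: str, record: Mapping[str, Any], source: str = "synthetic") -> Record:
        rec = dict(record)
        self.table(class_name).append(rec)
        self.provenance.setdefault(class_name, source)
        return rec

    def n_records(self, class_name: str | None = None) -> int:
        if class_name is not None:
            return len(self.tables.get(class_name, []))
        return sum(len(rows) for rows in self.tables.values())

    def keys_of(self, class_name: str, key_column: str) -> set[str]:
        out: set[str] = set()
        for rec in self.tables.get(class_name, []):
            v = _norm_value(rec.get(key_column))
            if v is not None:
                out.add(v)
        return out

    def normalized(self) -> dict[str, list[dict[str, str]]]:
        """Canonical form for equality checks: stringified values, nulls dropped,
        rows sorted by their serialized items."""
        out: dict[str, list[dict[str, str]]] = {}
        for class_name, rows in self.tables.items():
            norm_rows = []
            for rec in rows:
                norm = {k: v for k, v in ((k, _norm_value(v)) for k, v in rec.items()) if v is not None}
                norm_rows.append(norm)
            out[class_name] = sorted(norm_rows, key=lambda r: sorted(r.items()))
        # drop empty tables so "absent" and "present but empty" compare equal
        return {k: v for k, v in out.items() if v}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RecordBundle):
            return NotImplemented
        return self.normalized() == other.normalized()


def merge_bundles(bundles: Iterable[RecordBundle]) -> RecordBundle:
    """Concatenate bundles table-wise.

    Sources with disjoint id namespaces (connectors prefix their primary keys
    with ``VIGET:``, ``IMMPORT:``, ``CXG:``) merge without key collisions, so
    several converted resources can be loaded into a single store.
    """
    merged = RecordBundle()
    for bundle in bundles:
        for class_name, rows in bundle.tables.items():
            merged.table(class_name).extend(dict(r) for r in rows)
        for class_name, src in bundle.provenance.items():
            if class_name in merged.provenance and merged.provenance[class_name] != src:
                merged.provenance[class_name] = f"{merged.provenance[class_name]}+{src}"
            else:
                merged.provenance.setdefault(class_name, src)
    return merged
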