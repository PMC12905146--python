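"""CSV template reading and writing.

One template file per model class, named ``<Class>.csv``.  The header row
lists the primary key, foreign keys, and attributes, with each ontology-paired
attribute immediately followed by its ``<attr>_ontology_id`` column.  Data
entries go one per row.  Fields outside the fixed schema are serialized to a
long-format ``extended_attribute.csv`` side table with columns
(class, record_id, name, value, ontology_id).

Dialect: UTF-8, comma-delimited, RFC 4180 quoting, header in the first row.
Nulls are written as empty strings; booleans as ``true``/``false``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Any

from .bundle import RecordBundle, _norm_value
from .schema import EXTENDED_COLUMNS, EXTENDED_TABLE, SchemaRegistry, validate_bundle

__all__ = ["write_templates", "read_bundle", "write_bundle", "TemplateError"]


class TemplateError(ValueError):
    """Malformed template input (ragged row, unknown class file)."""


def _header(registry: SchemaRegistry, class_name: str) -> list[str]:
    return registry[class_name].columns


def write_templates(registry: SchemaRegistry, out_dir: str | Path) -> list[Path]:
    """Write one empty (header-only) CSV template per class, plus the
    extended-attribute side table template."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    for class_name in registry.classes:
        path = out / f"{class_name}.csv"
        with path.open("w", newline="", encoding="utf-8") as fh:
            csv.writer(fh).writerow(_header(registry, class_name))
        paths.append(path)
    ext = out / f"{EXTENDED_TABLE}.csv"
    with ext.open("w", newline="", encoding="utf-8") as fh:
        csv.writer(fh).writerow(EXTENDED_COLUMNS)
    paths.append(ext)
    return paths


def write_bundle(registry: SchemaRegistry, bundle: RecordBundle, out_dir: str | Path) -> list[Path]:
    """Serialize a bundle to per-class template CSVs.

    Every class in the registry gets a file (header-only when empty), so the
    output is always a complete template set.  Record fields outside the class
    schema go to ``extended_attribute.csv`` keyed by (class, primary key,
    field name), with ``<field>_ontology_id`` companions carried in the
    ``ontology_id`` column.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    extended_rows: list[tuple[str, str, str, str, str]] = []

    for class_name, cdef in registry.classes.items():
        header = cdef.columns
        known = set(header)
        path = out / f"{class_name}.csv"
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(header)
            for rec in bundle.tables.get(class_name, []):
                writer.writerow([_norm_value(rec.get(col)) or "" for col in header])
                extras = [k for k in rec if k not in known and not k.endswith("_ontology_id")]
                for name in extras:
                    value = _norm_value(rec.get(name))
                    if value is None:
                        continue
                    oid = _norm_value(rec.get(f"{name}_ontology_id")) or ""
                    pk = _norm_value(rec.get(cdef.primary_key)) or ""
                    extended_rows.append((class_name, pk, name, value, oid))
        paths.append(path)

    ext = out / f"{EXTENDED_TABLE}.csv"
    with ext.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(EXTENDED_COLUMNS)
        writer.writerows(extended_rows)
    paths.append(ext)
    return paths


def _read_csv(path: Path) -> tuple[list[str], list[list[str]]]:
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            return [], []
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(header):
                raise TemplateError(
                    f"{path.name}: line {lineno}: expected {len(header)} fields, got {len(row)}"
                )
            rows.append(row)
    return header, rows


def read_bundle(
    registry: SchemaRegistry, in_dir: str | Path, validate: bool = True
) -> RecordBundle:
    """Read a directory of per-class template CSVs back into a bundle.

    Empty cells become absent fields; unknown columns in a class file are kept
    on the record as extended attributes; ``extended_attribute.csv`` rows are
    re-attached to their records.  A CSV named after a class the registry does
    not know is an error.  When ``validate`` is set the assembled bundle is
    checked and the report attached as ``bundle.validation``.
    """
    src = Path(in_dir)
    bundle = RecordBundle()
    index: dict[tuple[str, str], dict[str, Any]] = {}

    for path in sorted(src.glob("*.csv")):
        class_name = path.stem
        if class_name == EXTENDED_TABLE:
            continue
        if class_name not in registry:
            if class_name[:1].isupper():
                raise TemplateError(f"{path.name}: class {class_name!r} not in the registry")
            continue  # lowercase stems are auxiliary artifacts (matrices, truth files)
        header, rows = _read_csv(path)
        pk_col = registry[class_name].primary_key
        records: list[dict[str, Any]] = []
        for row in rows:
            rec = {k: v for k, v in zip(header, row) if v != ""}
            records.append(rec)
            pk = rec.get(pk_col)
            if pk is not None:
                index[(class_name, str(pk))] = rec
        bundle.tables[class_name] = records
        bundle.provenance[class_name] = str(path)

    ext_path = src / f"{EXTENDED_TABLE}.csv"
    if ext_path.exists():
        header, rows = _read_csv(ext_path)
        for row in rows:
            entry = dict(zip(header, row))
            rec = index.get((entry.get("class", ""), entry.get("record_id", "")))
            if rec is None:
                continue
            name, value = entry.get("name", ""), entry.get("value", "")
            if name and value != "":
                rec[name] = value
                if entry.get("ontology_id"):
                    rec[f"{name}_ontology_id"] = entry["ontology_id"]

    # drop empty tables: a header-only file and an absent file are equivalent
    bundle.tables = {k: v for k, v in bundle.tables.items() if v}
    if validate:
        bundle.validation = validate_bundle(registry, bundle)  # type: ignore[attr-defined]
    return bundle
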