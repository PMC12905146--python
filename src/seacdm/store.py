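"""Embedded relational store for SEA CDM bundles.

Tables are created from :func:`seacdm.schema.emit_ddl` (portable dialect) in
an embedded SQLite database — in-memory for tests, on-disk for tools.  The
MySQL-dialect DDL emitted by the same function can provision a server-hosted
database with an identical layout, but nothing here requires a server.
"""

from __future__ import annotations

import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Any, Iterable, Sequence

from .bundle import RecordBundle, _norm_value
from .schema import (
    EXTENDED_COLUMNS,
    EXTENDED_TABLE,
    SchemaRegistry,
    emit_ddl,
    validate_bundle,
)

__all__ = ["StoreHandle", "MaterialSummary", "init_store", "load_bundle", "material_summary", "dump_bundle"]


@dataclass
class StoreHandle:
    connection: sqlite3.Connection
    registry: SchemaRegistry
    target: str
    dialect: str = "portable"

    def execute(self, sql: str, params: Sequence[Any] = ()) -> sqlite3.Cursor:
        return self.connection.execute(sql, params)

    def table_names(self) -> set[str]:
        rows = self.execute("SELECT name FROM sqlite_master WHERE type='table'").fetchall()
        return {r[0] for r in rows}

    def close(self) -> None:
        self.connection.close()


@dataclass(frozen=True)
class MaterialSummary:
    """Distinct-count summary over the Sample⋈Subject⋈Intervention⋈Experiment join.

    Field order follows the summary query's column order:
    (biosample reference names, study ids, expsample reference names).  Note
    that some published prose swaps the biosample/expsample figures relative
    to this column order; the query order is authoritative here.
    """

    n_biosamples: int
    n_studies: int
    n_expsamples: int


def init_store(registry: SchemaRegistry, target: str | Path = ":memory:") -> StoreHandle:
    """Create (or re-open) a store with one table per class plus the
    extended-attribute side table.  Idempotent: existing tables and their
    data are preserved."""
    try:
        conn = sqlite3.connect(str(target))
    except sqlite3.Error as exc:  # pragma: no cover - path errors are environment-specific
        raise ConnectionError(f"cannot open store at {target!r}: {exc}") from exc
    conn.executescript(emit_ddl(registry, "portable"))
    conn.commit()
    return StoreHandle(connection=conn, registry=registry, target=str(target))


def load_bundle(handle: StoreHandle, bundle: RecordBundle, validate: bool = True) -> dict[str, int]:
    """Append a bundle's records to the store, atomically.

    The bundle is validated first; a dangling foreign key or any other
    violation rejects the whole load before a single row is written.
    Duplicate primary keys (within the bundle or against rows already
    stored) raise with the class and key named.  Returns rows-per-table.
    """
    registry = handle.registry
    if validate:
        report = validate_bundle(registry, bundle)
        if not report.ok:
            first = report.violations[0]
            raise ValueError(
                f"bundle failed validation ({len(report.violations)} violations; "
                f"first: {first.class_name} row {first.row}: {first.message})"
            )
    counts: dict[str, int] = {name: 0 for name in registry.classes}
    counts[EXTENDED_TABLE] = 0
    cur = handle.connection.cursor()
    try:
        cur.execute("BEGIN")
        for class_name, cdef in registry.classes.items():
            columns = cdef.columns
            known = set(columns)
            placeholders = ",".join("?" for _ in columns)
            collist = ",".join(f'"{c}"' for c in columns)
            sql = f'INSERT INTO "{class_name}" ({collist}) VALUES ({placeholders})'
            for rec in bundle.tables.get(class_name, []):
                values = [_norm_value(rec.get(c)) for c in columns]
                try:
                    cur.execute(sql, values)
                except sqlite3.IntegrityError as exc:
                    raise ValueError(
                        f"duplicate primary key in {class_name}: "
                        f"{rec.get(cdef.primary_key)!r}"
                    ) from exc
                counts[class_name] += 1
                pk = _norm_value(rec.get(cdef.primary_key)) or ""
                for name in rec:
                    if name in known or name.endswith("_ontology_id"):
                        continue
                    value = _norm_value(rec.get(name))
                    if value is None:
                        continue
                    oid = _norm_value(rec.get(f"{name}_ontology_id")) or ""
                    cur.execute(
                        f'INSERT INTO "{EXTENDED_TABLE}" '
                        f'({",".join(EXTENDED_COLUMNS)}) VALUES (?,?,?,?,?)',
                        (class_name, pk, name, value, oid),
                    )
                    counts[EXTENDED_TABLE] += 1
        handle.connection.commit()
    except Exception:
        handle.connection.rollback()
        raise
    return counts


def material_summary(handle: StoreHandle, materials: Iterable[str]) -> MaterialSummary:
    """Count distinct biosample references, studies, and expsample references
    for samples whose subject received an intervention with one of the given
    materials (exact, case-sensitive string match).

    Implements the canonical summary join: Sample joined to Subject, the
    subject's Intervention filtered by material, and the subject's Experiment
    supplying the study id.
    """
    material_list = list(materials)
    if not material_list:
        return MaterialSummary(0, 0, 0)
    placeholders = ",".join("?" for _ in material_list)
    sql = f"""
        SELECT COUNT(DISTINCT sa.biosample_reference_name),
               COUNT(DISTINCT e.study_id),
               COUNT(DISTINCT sa.expsample_reference_name)
        FROM Sample sa
        JOIN Subject su ON sa.subject_id = su.subject_id
        JOIN Intervention i ON i.subject_id = su.subject_id
        JOIN Experiment e ON e.experiment_id = su.experiment_id
        WHERE i.material IN ({placeholders})
    """
    row = handle.execute(sql, material_list).fetchone()
    return MaterialSummary(n_biosamples=row[0], n_studies=row[1], n_expsamples=row[2])


def dump_bundle(handle: StoreHandle) -> RecordBundle:
    """Read every class table back into a bundle (inverse of load_bundle)."""
    registry = handle.registry
    bundle = RecordBundle()
    index: dict[tuple[str, str], dict[str, Any]] = {}
    for class_name, cdef in registry.classes.items():
        columns = cdef.columns
        collist = ",".join(f'"{c}"' for c in columns)
        rows = handle.execute(f'SELECT {collist} FROM "{class_name}"').fetchall()
        records = []
        for row in rows:
            rec = {c: v for c, v in zip(columns, row) if v is not None and v != ""}
            records.append(rec)
            pk = rec.get(cdef.primary_key)
            if pk is not None:
                index[(class_name, str(pk))] = rec
        if records:
            bundle.tables[class_name] = records
            bundle.provenance[class_name] = handle.target
    for cls, rid, name, value, oid in handle.execute(
        f'SELECT "class","record_id","name","value","ontology_id" FROM "{EXTENDED_TABLE}"'
    ).fetchall():
        rec = index.get((cls, rid))
        if rec is not None and name:
            rec[name] = value
            if oid:
                rec[f"{name}_ontology_id"] = oid
    return bundle
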