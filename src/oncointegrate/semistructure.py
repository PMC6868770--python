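"""Horizontal integration of heterogeneous delimited files.

Records of one data type (clinical, expression, copy number) arrive from
several studies with different delimiters, header conventions and field
names.  This module parses them into :class:`RawRecord` objects, infers a
per-data-type *semi-structure* — the aggregate of field names with their
occurrence counts, built record by record — and projects each record
through the mandatory data schema (every stored document carries the
record ID and the Sample ID) into a line-delimited document store.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Iterable, Mapping, Optional, Sequence

from . import fields as fieldlib
from .errors import (
    DelimiterError,
    MissingAttributeHeaderError,
    SchemaViolationError,
    StoreFormatError,
)

logger = logging.getLogger(__name__)

DATA_TYPES = ("clinical", "expression", "cnv")

#: Candidate delimiters, in tie-break priority order.
DELIMITER_CANDIDATES = ("\t", ",", ";")

DEFAULT_HEADER_PREFIX = "#"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawRecord:
    """One parsed record of any data type.

    ``fields`` maps field name to the raw string value; typed coercion is
    deferred to consuming modules.
    """

    record_id: str
    sample_id: str
    data_type: str
    fields: Mapping[str, str]
    source_file: str = ""
    source_study: str = ""

    def __post_init__(self) -> None:
        if self.data_type not in DATA_TYPES:
            raise ValueError(f"unknown data type {self.data_type!r}")
        object.__setattr__(self, "fields", MappingProxyType(dict(self.fields)))


@dataclass(frozen=True)
class FileHeaderMeta:
    """Metadata carried by a file's header rows."""

    technology: str = ""
    attribute_names: Sequence[str] = ()
    referenced_file_ids: Sequence[str] = ()
    n_declared_attributes: int = 0


@dataclass(frozen=True)
class SemiStructure:
    """Aggregated field-name statistics for one data type.

    ``field_stats`` maps each field name ever seen to the number of records
    in which it occurred; ``record_count`` is the number of records folded
    in so far.
    """

    data_type: str
    field_stats: Mapping[str, int] = field(default_factory=dict)
    record_count: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "field_stats", MappingProxyType(dict(self.field_stats)))


def empty_semistructure(data_type: str) -> SemiStructure:
    if data_type not in DATA_TYPES:
        raise ValueError(f"unknown data type {data_type!r}")
    return SemiStructure(data_type=data_type)


# ---------------------------------------------------------------------------
# delimiter and header discovery
# ---------------------------------------------------------------------------

def detect_delimiter(
    raw_lines: Sequence[str],
    header_prefix: str = DEFAULT_HEADER_PREFIX,
    filename: str = "<unknown>",
    sample_size: int = 50,
) -> str:
    """Discover the delimiter separating attributes in *raw_lines*.

    The winning candidate must split every sampled non-header line into the
    same number of columns (>= 2); among consistent candidates the one with
    the most columns wins, ties broken by the fixed priority
    tab > comma > semicolon.
    """
    rows = [
        line.rstrip("\r\n")
        for line in raw_lines
        if line.strip() and not line.startswith(header_prefix)
    ]
    if len(rows) < 2:
        raise DelimiterError(
            f"undetectable delimiter in {filename}: need at least 2 data lines"
        )
    sample = rows[:sample_size]
    best: Optional[tuple[str, int]] = None
    for cand in DELIMITER_CANDIDATES:
        counts = {line.count(cand) + 1 for line in sample}
        if len(counts) != 1:
            continue
        ncol = counts.pop()
        if ncol >= 2 and (best is None or ncol > best[1]):
            best = (cand, ncol)
    if best is None:
        raise DelimiterError(
            f"undetectable delimiter in {filename}: no candidate in "
            f"{DELIMITER_CANDIDATES!r} splits consistently into >=2 columns"
        )
    return best[0]


def parse_header(
    raw_lines: Sequence[str],
    header_prefix: str = DEFAULT_HEADER_PREFIX,
    delimiter: Optional[str] = None,
    filename: str = "<unknown>",
) -> FileHeaderMeta:
    """Extract header metadata.

    Lines starting with *header_prefix* are ``key=value`` metadata; the
    first unprefixed line is the attribute row.  Recognized keys:
    ``technology``, ``ref`` (repeatable) / ``refs`` (comma separated) and
    ``n_attributes``.
    """
    technology = ""
    refs: list[str] = []
    declared: Optional[int] = None
    attr_row: Optional[str] = None
    for line in raw_lines:
        text = line.rstrip("\r\n")
        if not text.strip():
            continue
        if text.startswith(header_prefix):
            entry = text[len(header_prefix):].strip()
            if "=" not in entry:
                continue
            key, _, value = entry.partition("=")
            key = key.strip().lower()
            value = value.strip()
            if key == "technology":
                if technology and value != technology:
                    logger.warning(
                        "%s: conflicting technology header, keeping first (%r)",
                        filename, technology,
                    )
                else:
                    technology = technology or value
            elif key == "ref":
                refs.append(value)
            elif key == "refs":
                refs.extend(v.strip() for v in value.split(",") if v.strip())
            elif key == "n_attributes":
                try:
                    declared = int(value)
                except ValueError:
                    logger.warning("%s: non-integer n_attributes %r", filename, value)
        else:
            attr_row = text
            break
    if attr_row is None:
        raise MissingAttributeHeaderError(f"missing attribute header in {filename}")
    if delimiter is None:
        delimiter = detect_delimiter(raw_lines, header_prefix, filename)
    names = [c.strip() for c in attr_row.split(delimiter)]
    return FileHeaderMeta(
        technology=technology,
        attribute_names=tuple(names),
        referenced_file_ids=tuple(refs),
        n_declared_attributes=declared if declared is not None else len(names),
    )


# ---------------------------------------------------------------------------
# record parsing
# ---------------------------------------------------------------------------

def _rows(raw_lines: Sequence[str], header_prefix: str) -> list[str]:
    return [
        line.rstrip("\r\n")
        for line in raw_lines
        if line.strip() and not line.startswith(header_prefix)
    ]


def read_records(
    path: str | Path,
    data_type: str,
    study: str,
    header_prefix: str = DEFAULT_HEADER_PREFIX,
) -> list[RawRecord]:
    """Parse one delimited file into :class:`RawRecord` objects.

    Clinical files hold one row per patient.  Expression and copy-number
    files are matrices with protein identifiers (Hugo symbols) in the first
    column and one column per patient; each patient column becomes one
    record whose fields map protein symbol to the raw value string.
    """
    path = Path(path)
    raw_lines = path.read_text().splitlines()
    delim = detect_delimiter(raw_lines, header_prefix, path.name)
    meta = parse_header(raw_lines, header_prefix, delim, path.name)
    data_rows = _rows(raw_lines, header_prefix)[1:]  # skip attribute row
    names = list(meta.attribute_names)

    records: list[RawRecord] = []
    if data_type == "clinical":
        sample_key = fieldlib.find_field({n: None for n in names}, fieldlib.SAMPLE_ID_ALIASES)
        id_key = fieldlib.find_field({n: None for n in names}, fieldlib.RECORD_ID_ALIASES)
        if sample_key is None:
            raise SchemaViolationError(
                f"schema violation: missing ID/Sample ID column in {path.name}"
            )
        for i, row in enumerate(data_rows):
            values = [v.strip() for v in row.split(delim)]
            if len(values) != len(names):
                logger.warning(
                    "%s: row %d has %d columns, expected %d; skipped",
                    path.name, i + 1, len(values), len(names),
                )
                continue
            rec_fields = dict(zip(names, values))
            sample_id = rec_fields.get(sample_key, "")
            record_id = rec_fields.get(id_key, "") if id_key else ""
            if not record_id:
                record_id = f"{study}:{path.stem}:{i}"
            records.append(
                RawRecord(
                    record_id=record_id,
                    sample_id=sample_id,
                    data_type=data_type,
                    fields=rec_fields,
                    source_file=path.name,
                    source_study=study,
                )
            )
    elif data_type in ("expression", "cnv"):
        sample_ids = names[1:]
        columns: dict[str, dict[str, str]] = {sid: {} for sid in sample_ids}
        for i, row in enumerate(data_rows):
            values = [v.strip() for v in row.split(delim)]
            if len(values) != len(names):
                logger.warning(
                    "%s: row %d has %d columns, expected %d; skipped",
                    path.name, i + 1, len(values), len(names),
                )
                continue
            symbol = values[0].strip().upper()
            for sid, value in zip(sample_ids, values[1:]):
                columns[sid][symbol] = value
        for sid in sample_ids:
            records.append(
                RawRecord(
                    record_id=f"{study}:{path.stem}:{sid}",
                    sample_id=sid,
                    data_type=data_type,
                    fields=columns[sid],
                    source_file=path.name,
                    source_study=study,
                )
            )
    else:
        raise ValueError(f"unknown data type {data_type!r}")
    return records


# ---------------------------------------------------------------------------
# semi-structure inference
# ---------------------------------------------------------------------------

def fold_record(semi: SemiStructure, record: RawRecord) -> SemiStructure:
    """Fold one record into the semi-structure, returning a new value.

    Each field name present in the record has its occurrence count
    incremented (inserted at 1 if new); the input semi-structure is not
    mutated.
    """
    if record.data_type != semi.data_type:
        raise ValueError(
            f"data type mismatch: record is {record.data_type!r}, "
            f"semi-structure is {semi.data_type!r}"
        )
    stats = dict(semi.field_stats)
    for name in record.fields:
        stats[name] = stats.get(name, 0) + 1
    return SemiStructure(
        data_type=semi.data_type,
        field_stats=stats,
        record_count=semi.record_count + 1,
    )


def fold_records(semi: SemiStructure, records: Iterable[RawRecord]) -> SemiStructure:
    for record in records:
        semi = fold_record(semi, record)
    return semi


# ---------------------------------------------------------------------------
# schema application and the document store
# ---------------------------------------------------------------------------

def apply_schema(record: RawRecord, semi: SemiStructure) -> dict:
    """Validate *record* against the data schema derived from *semi*.

    The returned document always carries the record ID and the Sample ID;
    fields not present in the semi-structure are dropped (projection) with
    a logged warning.
    """
    if not record.record_id or not record.sample_id:
        raise SchemaViolationError(
            f"schema violation: missing ID/Sample ID in record from "
            f"{record.source_file or '<memory>'}"
        )
    if record.data_type != semi.data_type:
        raise ValueError(
            f"data type mismatch: record is {record.data_type!r}, "
            f"semi-structure is {semi.data_type!r}"
        )
    kept = {k: v for k, v in record.fields.items() if k in semi.field_stats}
    dropped = set(record.fields) - set(kept)
    if dropped:
        logger.warning(
            "record %s: dropped %d field(s) outside the semi-structure: %s",
            record.record_id, len(dropped), sorted(dropped),
        )
    return {
        "record_id": record.record_id,
        "sample_id": record.sample_id,
        "data_type": record.data_type,
        "source_file": record.source_file,
        "source_study": record.source_study,
        "fields": kept,
    }


def store_documents(documents: Sequence[Mapping], path: str | Path) -> None:
    """Write documents as canonical line-delimited JSON (sorted keys)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w") as fh:
        for doc in documents:
            fh.write(json.dumps(doc, sort_keys=True, separators=(",", ":")))
            fh.write("\n")


def load_documents(path: str | Path) -> list[dict]:
    path = Path(path)
    documents = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                documents.append(json.loads(line))
            except json.JSONDecodeError as exc:
                raise StoreFormatError(
                    f"{path.name}: malformed line {lineno}: {exc}"
                ) from exc
    return documents


def semistructure_to_json(semi: SemiStructure, path: str | Path) -> None:
    payload = {
        "data_type": semi.data_type,
        "record_count": semi.record_count,
        "field_stats": dict(sorted(semi.field_stats.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


class DocumentStore:
    """Directory-backed store: one JSON-lines file per data type."""

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.root.mkdir(parents=True, exist_ok=True)

    def path_for(self, data_type: str) -> Path:
        return self.root / f"{data_type}.jsonl"

    def write(self, data_type: str, documents: Sequence[Mapping]) -> Path:
        path = self.path_for(data_type)
        store_documents(documents, path)
        return path

    def read(self, data_type: str) -> list[dict]:
        path = self.path_for(data_type)
        return load_documents(path) if path.exists() else []

    def read_all(self) -> list[dict]:
        docs: list[dict] = []
        for data_type in DATA_TYPES:
            docs.extend(self.read(data_type))
        return docs


def ingest_files(
    paths: Sequence[str | Path],
    data_type: str,
    study: str,
    store: Optional[DocumentStore] = None,
    header_prefix: str = DEFAULT_HEADER_PREFIX,
) -> tuple[list[dict], SemiStructure]:
    """Parse files, infer the semi-structure incrementally and validate.

    Returns the schema-validated documents and the final semi-structure;
    when *store* is given the documents are appended to the store file for
    the data type (merging with documents already present).
    """
    records: list[RawRecord] = []
    for path in paths:
        records.extend(read_records(path, data_type, study, header_prefix))
    semi = fold_records(empty_semistructure(data_type), records)
    documents = [apply_schema(record, semi) for record in records]
    if store is not None:
        existing = store.read(data_type)
        store.write(data_type, existing + documents)
        semistructure_to_json(semi, store.root / f"{data_type}.semistructure.json")
    return documents, semi
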