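"""Annotation schema for the RT-qPCR publication audit.

A surveyed publication is reduced to a flat annotation record: when it was
published and where, whether its internal control genes (ICG) were chosen by
a validated stability algorithm (geNorm, NormFinder, BestKeeper, ...), which
gene symbols were tested and which entered the normalization factor, and a
handful of MIQE reporting flags (stability output, 260/280 purity ratio, RNA
integrity). Datasets are ordered, immutable collections of such records with
CSV round-tripping and subgroup filtering (validated vs. not, exclusion of
technical reference-gene articles).

Gene symbols are normalized to HUGO-style canonical form through a small,
user-extensible alias table before any counting happens, so that
"beta-actin" and "ACTB" are the same gene to every downstream module.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

logger = logging.getLogger(__name__)

__all__ = [
    "SchemaError",
    "RowParseError",
    "GeneAliasTable",
    "DEFAULT_ALIAS_TABLE",
    "normalize_symbol",
    "PublicationRecord",
    "AuditDataset",
    "read_dataset",
    "write_dataset",
    "CSV_COLUMNS",
]

#: Canonical column order of the dataset CSV dialect (UTF-8, comma-separated,
#: RFC-4180 quoting, header row; booleans "yes"/"no"; gene lists ";"-joined).
CSV_COLUMNS = (
    "id",
    "year",
    "journal",
    "is_technical",
    "validated",
    "algorithm",
    "icg_tested",
    "icg_used",
    "reported_stability",
    "reported_260_280",
    "reported_integrity",
    "species",
)

GENE_LIST_DELIMITER = ";"


class SchemaError(ValueError):
    """The file does not conform to the dataset schema (e.g. missing column)."""


class RowParseError(ValueError):
    """A data row could not be parsed; carries the 1-based data-row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


def _alias_key(raw: str) -> str:
    # case-insensitive, whitespace- and hyphen-insensitive lookup key
    return re.sub(r"[\s\-_]+", "", raw).casefold()


class GeneAliasTable:
    """Deterministic alias -> canonical gene-symbol mapping.

    Canonical symbols always map to themselves; lookups ignore case,
    whitespace and hyphens. Extensible via :meth:`extended` or loadable from
    a two-column ``alias,canonical`` CSV.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._map: dict[str, str] = {}
        for alias, canonical in mapping.items():
            canonical = canonical.strip().upper()
            self._map[_alias_key(alias)] = canonical
            # canonical symbols map to themselves
            self._map.setdefault(_alias_key(canonical), canonical)

    def lookup(self, raw: str) -> str | None:
        return self._map.get(_alias_key(raw))

    def extended(self, extra: Mapping[str, str]) -> "GeneAliasTable":
        merged = {k: v for k, v in self._map.items()}
        table = GeneAliasTable(extra)
        merged.update(table._map)
        return GeneAliasTable(merged)

    @classmethod
    def from_csv(cls, path: str | Path) -> "GeneAliasTable":
        mapping: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for i, row in enumerate(csv.reader(fh)):
                if not row or (i == 0 and [c.lower() for c in row[:2]] == ["alias", "canonical"]):
                    continue
                if len(row) < 2:
                    raise SchemaError(f"alias table row {i + 1}: expected 2 columns")
                mapping[row[0]] = row[1]
        return cls(mapping)

    def __len__(self) -> int:
        return len(self._map)


#: Ships the long-form names of the commonly audited reference genes.
DEFAULT_ALIAS_TABLE = GeneAliasTable(
    {
        "Beta-actin": "ACTB",
        "Glyceraldehyde 3-phosphate dehydrogenase": "GAPDH",
        "18S ribosomal RNA": "RNA18S",
        "18S rRNA": "RNA18S",
        "18S": "RNA18S",
        "Eukaryotic Translation Initiation Factor 3 Subunit K": "EIF3K",
        "Peptidylprolyl Isomerase A": "PPIA",
        "Ribosomal Protein L19": "RPL19",
        "Ribosomal Protein S9": "RPS9",
        "TATA-Box Binding Protein": "TBP",
        "Ubiquitously Expressed Gene": "UXT",
    }
)


def normalize_symbol(
    raw: str, aliases: GeneAliasTable | None = None
) -> tuple[str, bool]:
    """Map a raw gene name to a canonical symbol.

    Returns ``(symbol, recognized)``. An alias-table hit returns the
    canonical symbol with ``recognized=True``; a miss falls back to the
    uppercased, trimmed input with ``recognized=False`` (unknown genes are
    kept, never dropped — usage counting must not silently lose genes).

    Raises ``ValueError`` on empty or whitespace-only input.
    """
    if aliases is None:
        aliases = DEFAULT_ALIAS_TABLE
    trimmed = raw.strip()
    if not trimmed:
        raise ValueError("gene symbol is empty")
    hit = aliases.lookup(trimmed)
    if hit is not None:
        return hit, True
    return trimmed.upper(), False


def _normalize_gene_list(
    symbols: Iterable[str], aliases: GeneAliasTable | None
) -> tuple[str, ...]:
    """Normalize and deduplicate, preserving first-occurrence order."""
    seen: dict[str, None] = {}
    for s in symbols:
        if not str(s).strip():
            continue
        sym, _ = normalize_symbol(str(s), aliases)
        seen.setdefault(sym, None)
    return tuple(seen)


@dataclass(frozen=True)
class PublicationRecord:
    """One annotated article.

    ``validated`` marks YAL membership (ICG chosen via a stability
    algorithm); ``reported_stability`` is the REPORT input and is only
    meaningful for validated records — quantifiable stability output comes
    from the validation software, so an unvalidated record cannot report it
    (invariant enforced here; the CSV reader coerces and warns).
    """

    id: str
    year: int
    journal: str
    is_technical: bool = False
    validated: bool = False
    algorithm: str | None = None
    icg_tested: tuple[str, ...] = ()
    icg_used: tuple[str, ...] = ()
    reported_stability: bool = False
    reported_260_280: bool = False
    reported_integrity: bool = False
    species: str | None = None
    year_range: tuple[int, int] = (2013, 2017)

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        lo, hi = self.year_range
        if not isinstance(self.year, int) or not lo <= self.year <= hi:
            raise ValueError(
                f"record {self.id!r}: year {self.year!r} outside allowed range {lo}-{hi}"
            )
        for fname in ("icg_tested", "icg_used"):
            vals = getattr(self, fname)
            if len(set(vals)) != len(vals):
                raise ValueError(f"record {self.id!r}: duplicate symbols in {fname}")
        if not self.validated and self.algorithm:
            raise ValueError(
                f"record {self.id!r}: algorithm given but validated is false"
            )
        if self.reported_stability and not self.validated:
            raise ValueError(
                f"record {self.id!r}: reported_stability requires validated"
            )

    @property
    def n_icg_used(self) -> int:
        """Number of distinct genes in the normalization factor."""
        return len(self.icg_used)


@dataclass(frozen=True)
class AuditDataset:
    """Ordered, immutable collection of :class:`PublicationRecord`."""

    records: tuple[PublicationRecord, ...]
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[PublicationRecord]:
        return iter(self.records)

    def subset(
        self,
        validated: bool | None = None,
        exclude_technical: bool = False,
    ) -> "AuditDataset":
        """Filter to a subgroup; never mutates the parent.

        ``validated=True`` selects the YAL subgroup, ``False`` NAL, ``None``
        keeps both. ``exclude_technical`` drops articles whose aim is itself
        reference-gene determination (circular-reasoning guard).
        """
        recs = tuple(
            r
            for r in self.records
            if (validated is None or r.validated == validated)
            and not (exclude_technical and r.is_technical)
        )
        note = f"subset(validated={validated}, exclude_technical={exclude_technical})"
        return AuditDataset(recs, self.provenance + (note,))

    def with_provenance(self, note: str) -> "AuditDataset":
        return replace(self, provenance=self.provenance + (note,))


def subset(
    ds: AuditDataset,
    validated: bool | None = None,
    exclude_technical: bool = False,
) -> AuditDataset:
    """Functional alias for :meth:`AuditDataset.subset`."""
    return ds.subset(validated=validated, exclude_technical=exclude_technical)


_BOOL = {"yes": True, "no": False, "true": True, "false": False, "1": True, "0": False}


def _parse_bool(raw: str, column: str, row_index: int) -> bool:
    try:
        return _BOOL[raw.strip().casefold()]
    except KeyError:
        raise RowParseError(
            row_index, f"column {column!r}: cannot parse boolean from {raw!r}"
        ) from None


def read_dataset(
    path: str | Path,
    aliases: GeneAliasTable | None = None,
    year_range: tuple[int, int] = (2013, 2017),
    delimiter: str = GENE_LIST_DELIMITER,
) -> AuditDataset:
    """Read a dataset CSV into a validated :class:`AuditDataset`.

    Gene-list cells are split on ``delimiter``, normalized through the alias
    table and deduplicated. A ``reported_stability=yes`` on an unvalidated
    row is coerced to ``no`` with a warning (the stability output only
    exists when validation software was run). Unknown columns are preserved
    in the provenance note.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in CSV_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
        extra = [c for c in header if c not in CSV_COLUMNS]
        records: list[PublicationRecord] = []
        seen_ids: set[str] = set()
        for i, row in enumerate(reader, start=1):
            rid = (row.get("id") or "").strip()
            if not rid:
                raise RowParseError(i, "empty id")
            if rid in seen_ids:
                raise RowParseError(i, f"duplicate id {rid!r}")
            seen_ids.add(rid)
            try:
                year = int(row["year"].strip())
            except (ValueError, AttributeError):
                raise RowParseError(
                    i, f"column 'year': cannot parse integer from {row.get('year')!r}"
                ) from None
            validated = _parse_bool(row["validated"], "validated", i)
            stability = _parse_bool(row["reported_stability"], "reported_stability", i)
            if stability and not validated:
                logger.warning(
                    "row %d (%s): reported_stability coerced to 'no' on an "
                    "unvalidated record (stability output requires validation software)",
                    i,
                    rid,
                )
                stability = False
            algorithm = (row.get("algorithm") or "").strip() or None
            if algorithm and not validated:
                raise RowParseError(
                    i, f"algorithm {algorithm!r} given but validated is 'no'"
                )
            try:
                rec = PublicationRecord(
                    id=rid,
                    year=year,
                    journal=(row["journal"] or "").strip(),
                    is_technical=_parse_bool(row["is_technical"], "is_technical", i),
                    validated=validated,
                    algorithm=algorithm,
                    icg_tested=_normalize_gene_list(
                        row["icg_tested"].split(delimiter) if row["icg_tested"] else [],
                        aliases,
                    ),
                    icg_used=_normalize_gene_list(
                        row["icg_used"].split(delimiter) if row["icg_used"] else [],
                        aliases,
                    ),
                    reported_stability=stability,
                    reported_260_280=_parse_bool(
                        row["reported_260_280"], "reported_260_280", i
                    ),
                    reported_integrity=_parse_bool(
                        row["reported_integrity"], "reported_integrity", i
                    ),
                    species=(row.get("species") or "").strip() or None,
                    year_range=year_range,
                )
            except ValueError as exc:
                raise RowParseError(i, str(exc)) from None
            records.append(rec)
    prov = [f"read from {path.name}"]
    if extra:
        prov.append(f"unknown columns preserved as metadata: {', '.join(extra)}")
    return AuditDataset(tuple(records), tuple(prov))


def _bool_cell(value: bool) -> str:
    return "yes" if value else "no"


def write_dataset(ds: AuditDataset, path: str | Path) -> None:
    """Write the canonical CSV dialect; ``read_dataset`` round-trips it."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_COLUMNS)
        for r in ds.records:
            writer.writerow(
                [
                    r.id,
                    str(r.year),
                    r.journal,
                    _bool_cell(r.is_technical),
                    _bool_cell(r.validated),
                    r.algorithm or "",
                    GENE_LIST_DELIMITER.join(r.icg_tested),
                    GENE_LIST_DELIMITER.join(r.icg_used),
                    _bool_cell(r.reported_stability),
                    _bool_cell(r.reported_260_280),
                    _bool_cell(r.reported_integrity),
                    r.species or "",
                ]
            )
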