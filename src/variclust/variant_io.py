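"""Reading, validating, deduplicating and grouping variant-event tables.

Input tables follow the VariCarta CSV dialect: one row per literature-reported
variant observation in one individual, carrying at minimum the individual id,
the affected gene symbol, the sequencing type and the mutation category, plus
an optional genomic descriptor (chrom/pos/ref/alt) and a source-paper
reference.  Because the same variant in the same individual can be reported by
several papers, events are deduplicated before any downstream analysis.
"""

from __future__ import annotations

import csv
import enum
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "SequencingType",
    "VariantEvent",
    "IndividualGeneSet",
    "IngestionReport",
    "DEFAULT_COLUMN_MAP",
    "DEFAULT_SEQUENCING_VOCABULARY",
    "read_varicarta",
    "deduplicate_events",
    "filter_by_sequencing",
    "group_individuals",
    "write_events_tsv",
]


class SequencingType(enum.Enum):
    """Sequencing technology that produced a variant event."""

    WHOLE_GENOME = "whole_genome"
    EXOME = "exome"
    TARGETED = "targeted"
    OTHER = "other"


#: case-insensitive vocabulary mapping raw table strings onto the enum
DEFAULT_SEQUENCING_VOCABULARY: Mapping[str, SequencingType] = {
    "whole genome sequencing": SequencingType.WHOLE_GENOME,
    "whole-genome sequencing": SequencingType.WHOLE_GENOME,
    "genome sequencing": SequencingType.WHOLE_GENOME,
    "wgs": SequencingType.WHOLE_GENOME,
    "exome sequencing": SequencingType.EXOME,
    "whole exome sequencing": SequencingType.EXOME,
    "wes": SequencingType.EXOME,
    "targeted sequencing": SequencingType.TARGETED,
    "targeted": SequencingType.TARGETED,
}

#: logical field -> column header in the input table
DEFAULT_COLUMN_MAP: Mapping[str, str] = {
    "individual_id": "individual_id",
    "gene_symbol": "gene_symbol",
    "sequencing_type": "sequencing_type",
    "variant_category": "variant_category",
    "chrom": "chromosome",
    "pos": "position",
    "ref": "ref",
    "alt": "alt",
    "source_ref": "source",
}

_REQUIRED_FIELDS = ("individual_id", "gene_symbol", "sequencing_type", "variant_category")
_OPTIONAL_FIELDS = ("chrom", "pos", "ref", "alt", "source_ref")


@dataclass(frozen=True)
class VariantEvent:
    """One literature-reported variant observation in one individual."""

    individual_id: str
    gene_symbol: str
    sequencing_type: SequencingType
    variant_category: str
    chrom: str = ""
    pos: str = ""
    ref: str = ""
    alt: str = ""
    source_ref: str = ""

    def __post_init__(self) -> None:
        if not self.individual_id:
            raise ValueError("VariantEvent.individual_id must be non-empty")
        if not self.gene_symbol:
            raise ValueError("VariantEvent.gene_symbol must be non-empty")

    @property
    def has_genomic_descriptor(self) -> bool:
        return bool(self.chrom and self.pos and self.ref and self.alt)

    def duplicate_key(self) -> tuple:
        """Identity of the underlying event, for cross-paper deduplication.

        Uses the genomic coordinates when the descriptor is complete, since
        coordinates are the most faithful notion of "the same variant";
        otherwise falls back to (individual, gene, category).
        """
        if self.has_genomic_descriptor:
            return (self.individual_id, self.chrom, self.pos, self.ref, self.alt)
        return (self.individual_id, self.gene_symbol, self.variant_category)


@dataclass(frozen=True)
class IndividualGeneSet:
    """The set of genes hit by at least one variant event in one individual."""

    individual_id: str
    genes: frozenset[str]


@dataclass
class IngestionReport:
    """Bookkeeping emitted by the ingestion and filtering steps."""

    rows_read: int = 0
    unmapped_sequencing: Counter = field(default_factory=Counter)
    sequencing_counts: Counter = field(default_factory=Counter)
    duplicates_removed: int = 0
    events_after_dedup: int = 0
    events_after_filter: int = 0
    retained_fraction: float | None = None
    n_individuals: int = 0
    empty_gene_set_individuals: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "rows_read": self.rows_read,
            "unmapped_sequencing": dict(self.unmapped_sequencing),
            "sequencing_counts": {k.value: v for k, v in self.sequencing_counts.items()},
            "duplicates_removed": self.duplicates_removed,
            "events_after_dedup": self.events_after_dedup,
            "events_after_filter": self.events_after_filter,
            "retained_fraction": self.retained_fraction,
            "n_individuals": self.n_individuals,
            "empty_gene_set_individuals": list(self.empty_gene_set_individuals),
        }


def _normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


def read_varicarta(
    path: str | Path,
    *,
    column_map: Mapping[str, str] | None = None,
    sequencing_vocabulary: Mapping[str, SequencingType] | None = None,
    delimiter: str = ",",
    report: IngestionReport | None = None,
) -> list[VariantEvent]:
    """Parse a variant-event table into :class:`VariantEvent` records.

    Parameters
    ----------
    path
        CSV (or TSV via ``delimiter``) file with a header row.
    column_map
        Logical field -> header name; defaults to :data:`DEFAULT_COLUMN_MAP`.
    sequencing_vocabulary
        Raw string -> :class:`SequencingType`, matched case-insensitively.
        Rows whose sequencing string is not in the vocabulary are mapped to
        ``OTHER`` and counted in the report, never silently dropped.
    report
        Optional report object to fill in; a fresh one is created otherwise
        (retrieve it via the function attribute ``read_varicarta.last_report``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    vocab = {
        k.strip().lower(): v
        for k, v in (sequencing_vocabulary or DEFAULT_SEQUENCING_VOCABULARY).items()
    }
    rep = report if report is not None else IngestionReport()

    events: list[VariantEvent] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            read_varicarta.last_report = rep
            return []
        for logical in _REQUIRED_FIELDS:
            if cmap[logical] not in reader.fieldnames:
                raise ValueError(
                    f"required column {cmap[logical]!r} (field {logical!r}) "
                    f"missing from {path}"
                )
        for row in reader:
            rep.rows_read += 1
            raw_seq = (row.get(cmap["sequencing_type"]) or "").strip()
            seq = vocab.get(raw_seq.lower())
            if seq is None:
                rep.unmapped_sequencing[raw_seq] += 1
                seq = SequencingType.OTHER
            rep.sequencing_counts[seq] += 1
            kwargs = {
                "individual_id": (row.get(cmap["individual_id"]) or "").strip(),
                "gene_symbol": _normalize_symbol(row.get(cmap["gene_symbol"]) or ""),
                "sequencing_type": seq,
                "variant_category": (row.get(cmap["variant_category"]) or "").strip(),
            }
            for logical in _OPTIONAL_FIELDS:
                col = cmap.get(logical)
                kwargs[logical] = (row.get(col) or "").strip() if col else ""
            events.append(VariantEvent(**kwargs))
    read_varicarta.last_report = rep
    return events


read_varicarta.last_report = None  # type: ignore[attr-defined]


def deduplicate_events(
    events: Sequence[VariantEvent], *, report: IngestionReport | None = None
) -> list[VariantEvent]:
    """Keep the first occurrence of each duplicate group, in input order."""
    seen: set[tuple] = set()
    kept: list[VariantEvent] = []
    for ev in events:
        key = ev.duplicate_key()
        if key in seen:
            continue
        seen.add(key)
        kept.append(ev)
    if report is not None:
        report.duplicates_removed = len(events) - len(kept)
        report.events_after_dedup = len(kept)
    return kept


def filter_by_sequencing(
    events: Sequence[VariantEvent],
    keep: Iterable[SequencingType],
    *,
    report: IngestionReport | None = None,
) -> list[VariantEvent]:
    """Retain events whose sequencing type is in ``keep`` (must be non-empty)."""
    keep = frozenset(keep)
    if not keep:
        raise ValueError("filter_by_sequencing: 'keep' must be non-empty")
    kept = [ev for ev in events if ev.sequencing_type in keep]
    if report is not None:
        report.events_after_filter = len(kept)
        report.retained_fraction = len(kept) / len(events) if events else None
    return kept


def group_individuals(
    events: Sequence[VariantEvent], *, report: IngestionReport | None = None
) -> list[IndividualGeneSet]:
    """Aggregate events into one gene set per individual, sorted by id."""
    by_ind: dict[str, set[str]] = {}
    for ev in events:
        by_ind.setdefault(ev.individual_id, set()).add(ev.gene_symbol)
    sets = [
        IndividualGeneSet(individual_id=ind, genes=frozenset(genes))
        for ind, genes in sorted(by_ind.items())
    ]
    if report is not None:
        report.n_individuals = len(sets)
    return sets


def write_events_tsv(events: Sequence[VariantEvent], path: str | Path) -> None:
    """Export events as TSV with the default logical column names."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(
            ["individual_id", "gene_symbol", "sequencing_type", "variant_category",
             "chrom", "pos", "ref", "alt", "source_ref"]
        )
        for ev in events:
            writer.writerow(
                [ev.individual_id, ev.gene_symbol, ev.sequencing_type.value,
                 ev.variant_category, ev.chrom, ev.pos, ev.ref, ev.alt, ev.source_ref]
            )
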