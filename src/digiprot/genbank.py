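"""Exon-resolved ingestion of GenBank annotation.

Every protein-coding gene in a GenBank flat file carries its exon structure in
the location of its CDS feature — a single span ``a..b`` for an intronless gene
or ``join(a..b, c..d, ...)`` (possibly wrapped in ``complement(...)``) for a
spliced one.  This module turns those features into :class:`CdsRecord` objects
with one :class:`ExonSpan` per exon, groups them into per-species proteomes,
and applies the quality-control filters used throughout the downstream
analyses: records with ambiguous exon boundaries, a non-methionine start,
a coding length not divisible by three, or a translation inconsistent with the
coding length are excluded, and species with fewer than a minimum number of
surviving records (default 500) are dropped entirely, since below that sample
size the mean and median of a lognormal length distribution are not estimated
reliably.

Coordinates follow the GenBank convention: 1-based, inclusive at both ends, so
an exon ``a..b`` has length ``b - a + 1``.  Protein length is measured in
amino-acid residues and, for a complete CDS that includes its stop codon,
satisfies ``cds_nt = 3 * (protein_aa + 1)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    BetweenPosition,
    ExactPosition,
    Location,
    OneOfPosition,
    SeqFeature,
    UncertainPosition,
    UnknownPosition,
    WithinPosition,
)
from Bio.SeqFeature import LocationParserError as _BioLocationParserError

logger = logging.getLogger(__name__)

#: QC flags a record may carry.  A record with any flag set is excluded.
QC_FLAGS = (
    "non_met_start",
    "ambiguous_boundary",
    "length_not_multiple_of_3",
    "translation_mismatch",
    "pseudo",
    "unsupported_location",
)


class LocationParseError(ValueError):
    """The location text is not valid GenBank location syntax."""


class UnsupportedLocationError(ValueError):
    """Syntactically valid location that this pipeline does not support
    (cross-contig reference or an ``order(...)`` operator)."""


@dataclass(frozen=True)
class ExonSpan:
    """One exon of a CDS, in genomic coordinates (1-based, inclusive)."""

    start: int
    end: int
    ambiguous_start: bool = False
    ambiguous_end: bool = False

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"exon end {self.end} precedes start {self.start}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CdsRecord:
    """A single protein-coding gene with its exon architecture."""

    protein_id: str
    species: str
    group: str | None
    exons: list[ExonSpan]
    strand: str  # "forward" | "reverse"
    translation_length: int | None
    qc_flags: set[str] = field(default_factory=set)

    @property
    def cds_nt_length(self) -> int:
        return sum(e.length for e in self.exons)

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def protein_length(self) -> int | None:
        """Protein length in aa: the annotated translation when present,
        otherwise CDS arithmetic with the stop codon removed."""
        if self.translation_length is not None:
            return self.translation_length
        if self.cds_nt_length % 3 == 0:
            return self.cds_nt_length // 3 - 1
        return None

    @property
    def passes_qc(self) -> bool:
        return not self.qc_flags


@dataclass
class SpeciesProteome:
    """All CDS records of one species plus its retention status."""

    species: str
    group: str | None
    records: list[CdsRecord]
    retained: bool = True

    @property
    def n_records(self) -> int:
        return len(self.records)


@dataclass
class QcReport:
    """Reconciliation of a QC pass: input = retained + excluded."""

    n_input: int
    n_retained: int
    n_excluded: int
    flag_counts: dict[str, int]
    species_dropped: bool


def _is_ambiguous(pos) -> bool:
    if isinstance(pos, ExactPosition):
        return False
    return isinstance(
        pos,
        (
            BeforePosition,
            AfterPosition,
            UnknownPosition,
            WithinPosition,
            BetweenPosition,
            OneOfPosition,
            UncertainPosition,
        ),
    )


def parse_location(location_text: str) -> tuple[list[ExonSpan], str]:
    """Parse a GenBank feature-location string into exon spans.

    Returns the spans in translation order (reversed genomic order for
    ``complement(...)`` locations) and the strand as ``"forward"`` or
    ``"reverse"``.  Coordinates are 1-based inclusive.  Partial-boundary
    markers (``<`` / ``>``) are recorded on the affected span, not rejected.

    Raises
    ------
    LocationParseError
        For malformed syntax; the message names the offending text.
    UnsupportedLocationError
        For ``order(...)`` operators, cross-contig references
        (``accession:a..b``), or mixed-strand compound locations.
    """
    try:
        loc = Location.fromstring(location_text.strip())
    except _BioLocationParserError as exc:
        raise LocationParseError(
            f"malformed location {location_text!r}: {exc}"
        ) from exc
    if loc is None:
        raise LocationParseError(f"malformed location {location_text!r}")
    return _location_to_spans(loc, location_text)


def _location_to_spans(loc, location_text: str) -> tuple[list[ExonSpan], str]:
    if getattr(loc, "operator", "join") == "order":
        raise UnsupportedLocationError(
            f"order(...) locations are not supported: {location_text!r}"
        )
    parts = list(loc.parts)
    if any(p.ref for p in parts):
        raise UnsupportedLocationError(
            f"location references another contig: {location_text!r}"
        )
    strands = {p.strand for p in parts}
    if len(strands) != 1:
        raise UnsupportedLocationError(
            f"mixed-strand location: {location_text!r}"
        )
    strand_val = strands.pop()
    if strand_val not in (1, -1, None):
        raise UnsupportedLocationError(f"unstranded location: {location_text!r}")
    strand = "reverse" if strand_val == -1 else "forward"

    spans = []
    for p in parts:
        if isinstance(p.start, UnknownPosition) or isinstance(p.end, UnknownPosition):
            raise UnsupportedLocationError(
                f"location with unknown position: {location_text!r}"
            )
        spans.append(
            ExonSpan(
                start=int(p.start) + 1,  # Biopython is 0-based half-open
                end=int(p.end),
                ambiguous_start=_is_ambiguous(p.start),
                ambiguous_end=_is_ambiguous(p.end),
            )
        )
    # Biopython stores complement(join(...)) parts already in translation
    # order (descending genomic start); normalise in case they are not.
    if strand == "reverse" and len(spans) > 1 and spans[0].start < spans[-1].start:
        spans.reverse()
    return spans, strand


def _record_from_feature(
    feature: SeqFeature, species: str, group: str | None
) -> CdsRecord:
    quals = feature.qualifiers
    protein_id = quals.get("protein_id", [""])[0] or quals.get("locus_tag", [""])[0]
    translation = quals.get("translation", [None])[0]
    flags: set[str] = set()

    try:
        spans, strand = _location_to_spans(feature.location, str(feature.location))
    except UnsupportedLocationError:
        return CdsRecord(
            protein_id=protein_id,
            species=species,
            group=group,
            exons=[],
            strand="forward",
            translation_length=len(translation) if translation else None,
            qc_flags={"unsupported_location"},
        )

    if any(s.ambiguous_start or s.ambiguous_end for s in spans):
        flags.add("ambiguous_boundary")
    if "pseudo" in quals or "pseudogene" in quals:
        flags.add("pseudo")

    translation_length = len(translation) if translation else None
    if translation is not None and not translation.startswith("M"):
        flags.add("non_met_start")

    cds_nt = sum(s.length for s in spans)
    if cds_nt % 3 != 0:
        flags.add("length_not_multiple_of_3")
    elif translation_length is not None and cds_nt != 3 * (translation_length + 1):
        flags.add("translation_mismatch")

    return CdsRecord(
        protein_id=protein_id,
        species=species,
        group=group,
        exons=spans,
        strand=strand,
        translation_length=translation_length,
        qc_flags=flags,
    )


def qc_filter(
    proteome: SpeciesProteome, min_per_species: int = 500
) -> tuple[SpeciesProteome, QcReport]:
    """Apply record-level QC and the minimum-sample-size rule.

    Records carrying any QC flag are excluded.  The species as a whole is
    marked not retained when fewer than ``min_per_species`` records survive.
    The report reconciles exactly: input = retained + excluded.
    """
    if not proteome.records:
        logger.warning("empty proteome for species %s", proteome.species)
        return (
            SpeciesProteome(proteome.species, proteome.group, [], retained=False),
            QcReport(0, 0, 0, {f: 0 for f in QC_FLAGS}, species_dropped=True),
        )

    passing = [r for r in proteome.records if r.passes_qc]
    excluded = [r for r in proteome.records if not r.passes_qc]
    flag_counts = {f: 0 for f in QC_FLAGS}
    for r in excluded:
        for f in r.qc_flags:
            flag_counts[f] += 1
    dropped = len(passing) < min_per_species
    result = SpeciesProteome(
        species=proteome.species,
        group=proteome.group,
        records=passing,
        retained=not dropped,
    )
    report = QcReport(
        n_input=len(proteome.records),
        n_retained=len(passing),
        n_excluded=len(excluded),
        flag_counts=flag_counts,
        species_dropped=dropped,
    )
    return result, report


def ingest_genbank(
    source: str | Path | IO[str] | Iterable[str | Path],
    group_map: Mapping[str, str] | None = None,
) -> list[SpeciesProteome]:
    """Read GenBank flat file(s) into per-species proteomes.

    ``source`` may be a path, an open text handle, or an iterable of paths.
    The organism is taken from the record's ORGANISM/source annotation;
    ``group_map`` assigns a lineage label per species name.  Records without
    any CDS feature are skipped with a log entry.
    """
    by_species: dict[str, list[CdsRecord]] = {}
    n_seq_records = 0
    for rec in _iter_seq_records(source):
        n_seq_records += 1
        species = rec.annotations.get("organism") or rec.annotations.get(
            "source", "unknown"
        )
        cds_feats = [f for f in rec.features if f.type == "CDS"]
        if not cds_feats:
            logger.info("record %s has no CDS feature; skipped", rec.id)
            continue
        group = group_map.get(species) if group_map else None
        bucket = by_species.setdefault(species, [])
        for feat in cds_feats:
            bucket.append(_record_from_feature(feat, species, group))
    if n_seq_records == 0:
        logger.warning("no GenBank records found in input")
    logger.info(
        "ingested %d CDS records from %d species",
        sum(len(v) for v in by_species.values()),
        len(by_species),
    )
    return [
        SpeciesProteome(
            species=sp,
            group=(group_map.get(sp) if group_map else None),
            records=recs,
        )
        for sp, recs in sorted(by_species.items())
    ]


def _iter_seq_records(source) -> Iterator:
    if hasattr(source, "read"):
        yield from SeqIO.parse(source, "genbank")
        return
    if isinstance(source, (str, Path)):
        paths: Iterable[str | Path] = [source]
    else:
        paths = source
    for path in paths:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        with open(path) as handle:
            yield from SeqIO.parse(handle, "genbank")


def records_table(proteomes: Iterable[SpeciesProteome]) -> pd.DataFrame:
    """Tidy one-row-per-CDS table of the ingested (or QC-filtered) records."""
    rows = []
    for pt in proteomes:
        for r in pt.records:
            rows.append(
                {
                    "species": r.species,
                    "group": r.group if r.group is not None else "",
                    "protein_id": r.protein_id,
                    "n_exons": r.n_exons,
                    "exon_lengths": ",".join(str(e.length) for e in r.exons),
                    "cds_nt": r.cds_nt_length,
                    "protein_aa": r.protein_length if r.protein_length is not None else "",
                    "qc_flags": ";".join(sorted(r.qc_flags)),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "species",
            "group",
            "protein_id",
            "n_exons",
            "exon_lengths",
            "cds_nt",
            "protein_aa",
            "qc_flags",
        ],
    )


def write_records_tsv(proteomes: Iterable[SpeciesProteome], path: str | Path) -> None:
    records_table(proteomes).to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"exon_lengths": str, "qc_flags": str})
    df["qc_flags"] = df.get("qc_flags", "").fillna("")
    return df
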