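"""Barcode record ingestion and the curation filter chain.

Two repository dialects are read: a BOLD-style tab-separated specimen+sequence
dump, and a GenBank-style FASTA whose definition lines carry the accession and
the organism binomial.  Curation applies a fixed five-stage filter chain
(marker, sequence presence, country validity, exact species-name match against
the catalogue, and a species-level country-count sanity check) and reports
row/species counts for every stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .catalogue import TaxonCatalogue, fold_name, normalize_name
from .errors import FormatError

#: IUPAC nucleotide one-letter codes (ambiguity codes included).
IUPAC_NT = frozenset("ACGTRYWSMKHBVDN")

#: Definition-line substrings accepted as naming the ITS2 marker.
DEFAULT_ITS2_SYNONYMS = (
    "ITS2",
    "ITS-2",
    "ITS 2",
    "ITSII",
    "internal transcribed spacer 2",
)

#: Default column mapping for BOLD-style dumps (configurable per call).
BOLD_COLUMNS = {
    "record_id": "processid",
    "accession": "genbank_accession",
    "species_name": "species_name",
    "marker": "markercode",
    "country": "country",
    "latitude": "lat",
    "longitude": "lon",
    "sequence": "nucleotides",
}

_ACCESSION_RE = re.compile(
    r"^(?P<acc>[A-Za-z]{1,4}_?\d{5,10})(?:\.\d+)?$"
)
_DEFLINE_RE = re.compile(
    r"^(?P<acc>[A-Za-z]{1,4}_?\d{5,10})(?:\.\d+)?\s+"
    r"(?P<genus>[A-Z][a-z]+)\s+(?P<epithet>[a-z][a-z-]+)"
)


def clean_sequence(raw: str | None) -> str | None:
    """Uppercase, strip gap characters/whitespace, validate IUPAC codes.
    Empty input becomes None (absent sequence)."""
    if raw is None:
        return None
    s = "".join(str(raw).split()).replace("-", "").upper()
    if not s:
        return None
    bad = set(s) - IUPAC_NT
    if bad:
        raise FormatError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return s


def strip_accession_version(acc: str) -> str:
    """AB123456.1 -> AB123456, uppercased; reconciliation key."""
    return acc.strip().upper().split(".", 1)[0]


@dataclass(frozen=True)
class BarcodeRecord:
    """One specimen/sequence record from either repository."""

    record_id: str
    source: str  # "bold" | "genbank"
    accession: str | None = None
    species_name: str | None = None
    marker: str | None = None
    sequence: str | None = None
    country: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    definition: str | None = None
    parsed: bool = True  # False when a FASTA defline could not be interpreted

    @property
    def accession_key(self) -> str | None:
        return strip_accession_version(self.accession) if self.accession else None


def _opt(value: str) -> str | None:
    v = str(value).strip()
    return v or None


def _opt_float(value: str) -> float | None:
    v = str(value).strip()
    if not v:
        return None
    try:
        return float(v)
    except ValueError:
        return None


def read_bold_records(
    path: str | Path,
    columns: Mapping[str, str] = BOLD_COLUMNS,
) -> list[BarcodeRecord]:
    """Read a BOLD-style TSV dump into records, one per row, order preserved.

    Empty cells become absent fields.  Only the id column is mandatory;
    any other mapped column may be missing from the file.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FormatError(f"cannot read {path}: {exc}") from exc
    id_col = columns["record_id"]
    if id_col not in df.columns:
        raise FormatError(f"BOLD dump is missing mandatory id column {id_col!r}")

    def get(row, key):
        col = columns.get(key)
        return row.get(col, "") if col in df.columns else ""

    records = []
    for _, row in df.iterrows():
        records.append(
            BarcodeRecord(
                record_id=str(row[id_col]).strip(),
                source="bold",
                accession=_opt(get(row, "accession")),
                species_name=_opt(get(row, "species_name")),
                marker=_opt(get(row, "marker")),
                sequence=clean_sequence(_opt(get(row, "sequence"))),
                country=_opt(get(row, "country")),
                latitude=_opt_float(get(row, "latitude")),
                longitude=_opt_float(get(row, "longitude")),
            )
        )
    return records


def read_genbank_records(
    path: str | Path,
    defline_pattern: re.Pattern | str = _DEFLINE_RE,
) -> list[BarcodeRecord]:
    """Read a GenBank-style FASTA.

    The definition line is expected to start with the accession followed by
    the organism binomial (``>AB123456 Aedes albopictus cytochrome ...``).
    Records whose definition does not match the pattern are retained but
    flagged ``parsed=False`` rather than raising.
    """
    path = Path(path)
    pattern = re.compile(defline_pattern)
    with open(path) as fh:
        text_head = fh.read(1)
    if text_head and text_head != ">":
        raise FormatError(f"{path} does not look like FASTA (no leading '>')")
    records: list[BarcodeRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        definition = rec.description
        m = pattern.match(definition)
        if m:
            acc = strip_accession_version(m.group("acc"))
            species = f"{m.group('genus')} {m.group('epithet')}"
            records.append(
                BarcodeRecord(
                    record_id=acc,
                    source="genbank",
                    accession=acc,
                    species_name=species,
                    sequence=clean_sequence(str(rec.seq)),
                    definition=definition,
                )
            )
        else:
            records.append(
                BarcodeRecord(
                    record_id=f"unparsed_{i}",
                    source="genbank",
                    sequence=clean_sequence(str(rec.seq)),
                    definition=definition,
                    parsed=False,
                )
            )
    return records


def filter_its2_names(
    records: Iterable[BarcodeRecord],
    synonyms: Sequence[str] = DEFAULT_ITS2_SYNONYMS,
) -> tuple[list[BarcodeRecord], list[BarcodeRecord]]:
    """Name-based ITS2 filter: keep records whose definition mentions the
    internal transcribed spacer 2 under any configured synonym
    (case-insensitive substring match)."""
    pats = [s.casefold() for s in synonyms]
    kept, removed = [], []
    for rec in records:
        text = (rec.definition or "").casefold()
        (kept if any(p in text for p in pats) else removed).append(rec)
    return kept, removed


# ---------------------------------------------------------------------------
# curation chain
# ---------------------------------------------------------------------------

STAGE_NAMES = (
    "marker",
    "sequence_present",
    "country_valid",
    "species_in_catalogue",
    "country_count_sanity",
)


@dataclass(frozen=True)
class CurationStage:
    name: str
    rows_in: int
    rows_removed: int
    rows_out: int
    species_out: int

    def __post_init__(self):
        if self.rows_in != self.rows_removed + self.rows_out:
            raise ValueError(f"stage {self.name}: rows do not balance")
        if min(self.rows_in, self.rows_removed, self.rows_out) < 0:
            raise ValueError(f"stage {self.name}: negative count")


@dataclass
class CurationReport:
    """Stage-by-stage account of the filter chain."""

    stages: list[CurationStage] = field(default_factory=list)
    #: species dropped wholesale, with reasons (stage-5 exclusions,
    #: unmatched names seen at stage 4)
    excluded_species: list[tuple[str, str]] = field(default_factory=list)

    def validate(self) -> None:
        for a, b in zip(self.stages, self.stages[1:]):
            if a.rows_out != b.rows_in:
                raise ValueError(f"stage chain broken between {a.name} and {b.name}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(s) for s in self.stages])

    def __str__(self) -> str:
        lines = [
            f"{s.name}: {s.rows_in} -> {s.rows_out} "
            f"(-{s.rows_removed}; {s.species_out} species)"
            for s in self.stages
        ]
        for sp, why in self.excluded_species:
            lines.append(f"excluded species {sp}: {why}")
        return "\n".join(lines)


def _n_species(records: list[BarcodeRecord]) -> int:
    return len({fold_name(r.species_name) for r in records if r.species_name})


def curate_records(
    records: Sequence[BarcodeRecord],
    cat: TaxonCatalogue,
    marker: str,
    gazetteer: Iterable[str] | None = None,
) -> tuple[list[BarcodeRecord], CurationReport]:
    """Apply the five-stage filter chain and report each stage.

    Stages, in order: (1) keep only the requested marker; (2) drop rows
    without a sequence; (3) drop rows whose country is absent or fails the
    gazetteer lookup; (4) drop rows whose species name has no exact
    catalogue match; (5) drop *all* rows of any species whose distinct
    surviving country count exceeds its catalogue country count.

    Species names and countries in the output are rewritten to their
    canonical catalogue forms, so downstream coverage arithmetic can use
    plain equality.  The gazetteer defaults to the catalogue's own country
    set.  Re-running curation on its own output is a no-op.
    """
    report = CurationReport()
    if gazetteer is None:
        gaz_fold = {fold_name(c): c for c in cat.countries}
    else:
        gaz_fold = {fold_name(c): normalize_name(c) for c in gazetteer}

    current = list(records)

    def record_stage(name: str, survivors: list[BarcodeRecord]) -> list[BarcodeRecord]:
        nonlocal current
        report.stages.append(
            CurationStage(
                name=name,
                rows_in=len(current),
                rows_removed=len(current) - len(survivors),
                rows_out=len(survivors),
                species_out=_n_species(survivors),
            )
        )
        current = survivors
        return current

    # (1) marker
    record_stage("marker", [r for r in current if r.marker == marker])
    # (2) sequence available
    record_stage("sequence_present", [r for r in current if r.sequence])
    # (3) valid country
    survivors = []
    for r in current:
        canon = gaz_fold.get(fold_name(r.country)) if r.country else None
        if canon is not None:
            survivors.append(replace(r, country=canon))
    record_stage("country_valid", survivors)
    # (4) exact catalogue name match
    survivors, unmatched = [], set()
    for r in current:
        sp = cat.match_species(r.species_name) if r.species_name else None
        if sp is None:
            if r.species_name:
                unmatched.add(normalize_name(r.species_name))
        else:
            survivors.append(replace(r, species_name=sp))
    for name in sorted(unmatched):
        report.excluded_species.append((name, "no exact catalogue match"))
    record_stage("species_in_catalogue", survivors)
    # (5) species-atomic country-count sanity check
    db_countries: dict[str, set[str]] = {}
    for r in current:
        db_countries.setdefault(r.species_name, set()).add(r.country)
    bad = {
        sp
        for sp, cs in db_countries.items()
        if len(cs) > len(cat.countries_of[sp])
    }
    for sp in sorted(bad):
        report.excluded_species.append(
            (sp, "database country count exceeds catalogue country count")
        )
    record_stage(
        "country_count_sanity", [r for r in current if r.species_name not in bad]
    )

    report.validate()
    return current, report


# ---------------------------------------------------------------------------
# cross-repository reconciliation
# ---------------------------------------------------------------------------


@dataclass
class CrossReference:
    """Partition of two record sets by version-stripped accession."""

    shared: list[BarcodeRecord]
    unique_bold: list[BarcodeRecord]
    unique_genbank: list[BarcodeRecord]
    #: BOLD-style records carrying a GenBank accession that the GenBank set
    #: lacks — sequences mined from GenBank rather than deposited via BOLD
    mined_from_genbank: list[BarcodeRecord]

    def counts(self) -> dict[str, int]:
        def nsp(recs):
            return len({fold_name(r.species_name) for r in recs if r.species_name})

        union = self.shared + self.unique_bold + self.unique_genbank
        return {
            "shared_records": len(self.shared),
            "unique_bold_records": len(self.unique_bold),
            "unique_genbank_records": len(self.unique_genbank),
            "mined_from_genbank_records": len(self.mined_from_genbank),
            "shared_species": nsp(self.shared),
            "union_records": len(union),
            "union_species": nsp(union),
        }


def cross_reference_sources(
    bold_records: Sequence[BarcodeRecord],
    genbank_records: Sequence[BarcodeRecord],
) -> CrossReference:
    """Reconcile the two repositories by accession.

    Accessions are compared case-insensitively with the version suffix
    stripped.  ``shared`` holds records (from both sides) whose accession
    occurs in both sets; ``mined_from_genbank`` flags BOLD records whose
    GenBank accession is absent from the GenBank set.
    """
    bold_acc = {r.accession_key for r in bold_records if r.accession_key}
    gb_acc = {r.accession_key for r in genbank_records if r.accession_key}
    both = bold_acc & gb_acc

    shared = [r for r in bold_records if r.accession_key in both]
    shared += [r for r in genbank_records if r.accession_key in both]
    unique_bold = [r for r in bold_records if r.accession_key not in both]
    unique_genbank = [r for r in genbank_records if r.accession_key not in both]
    mined = [r for r in unique_bold if r.accession_key]
    return CrossReference(
        shared=shared,
        unique_bold=unique_bold,
        unique_genbank=unique_genbank,
        mined_from_genbank=mined,
    )


# ---------------------------------------------------------------------------
# output helpers
# ---------------------------------------------------------------------------


def records_to_frame(records: Iterable[BarcodeRecord]) -> pd.DataFrame:
    cols = [
        "record_id", "source", "accession", "species_name", "marker",
        "country", "latitude", "longitude", "sequence",
    ]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records],
                        columns=cols)


def records_to_bold_frame(records: Iterable[BarcodeRecord]) -> pd.DataFrame:
    """Record table under BOLD-style column names, re-readable with
    :func:`read_bold_records`."""
    df = records_to_frame(records).drop(columns="source")
    return df.rename(columns=BOLD_COLUMNS)


def write_records_fasta(records: Iterable[BarcodeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            if r.sequence:
                fh.write(f">{r.record_id}\n{r.sequence}\n")
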