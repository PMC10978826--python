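"""Coverage statistics and the country/species modelling tables.

Two statistics quantify how complete a barcode reference library is:

* **taxonomic coverage** — for a country or biogeographic region, the
  percentage of catalogue species of that unit that have at least one
  barcode record in the database;
* **geographic coverage** — for a species, the proportion of its catalogue
  countries in which the database holds at least one record.

Both are well defined only on curated records (species names canonical,
countries validated, the species-atomic country-count check applied), which
guarantees coverage never exceeds 100%.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd

from .catalogue import TaxonCatalogue
from .curation import BarcodeRecord
from .errors import ConfigurationError


def _round_half_up(x: float, ndigits: int) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def taxonomic_coverage(n_db_species: int, n_cat_species: int) -> float:
    """100 * n_db_species / n_cat_species, reported to two decimals
    (half-up).  Undefined when the catalogue holds no species for the unit.
    """
    if n_cat_species <= 0:
        raise ConfigurationError(
            "taxonomic coverage undefined: catalogue species count is zero"
        )
    return _round_half_up(100.0 * n_db_species / n_cat_species, 2)


COVERAGE_COLUMNS = [
    "unit", "region", "n_cat_species", "n_db_species", "coverage_pct",
    "n_sequences", "n_endemic", "n_medical",
]


def build_coverage_table(
    records: Sequence[BarcodeRecord],
    cat: TaxonCatalogue,
    unit: str = "country",
) -> pd.DataFrame:
    """One coverage row per country (or per biogeographic region).

    ``n_db_species`` counts distinct catalogue-matched species with at least
    one record in the unit; region rows aggregate member countries by set
    union, not by summing country counts.  Every record country must be in
    the catalogue's region map.
    """
    if unit not in ("country", "region"):
        raise ConfigurationError(f"unknown unit {unit!r}")

    for r in records:
        if r.country not in cat.region_of:
            raise ConfigurationError(
                f"record {r.record_id}: country {r.country!r} not in catalogue map"
            )

    if unit == "country":
        unit_of = {c: c for c in cat.region_of}
    else:
        unit_of = dict(cat.region_of)

    cat_species: dict[str, set[str]] = {}
    endemics: dict[str, set[str]] = {}
    medicals: dict[str, set[str]] = {}
    for sp, cs in cat.countries_of.items():
        units = {unit_of[c] for c in cs}
        for u in units:
            cat_species.setdefault(u, set()).add(sp)
            if cat.medical.get(sp, False):
                medicals.setdefault(u, set()).add(sp)
        if len(cs) == 1:
            (u,) = {unit_of[c] for c in cs}
            endemics.setdefault(u, set()).add(sp)

    db_species: dict[str, set[str]] = {}
    n_seqs: dict[str, int] = {}
    for r in records:
        u = unit_of[r.country]
        db_species.setdefault(u, set()).add(r.species_name)
        n_seqs[u] = n_seqs.get(u, 0) + 1

    rows = []
    for u in sorted(cat_species):
        n_cat = len(cat_species[u])
        n_db = len(db_species.get(u, ()))
        rows.append(
            {
                "unit": u,
                "region": cat.region_of[u] if unit == "country" else u,
                "n_cat_species": n_cat,
                "n_db_species": n_db,
                "coverage_pct": taxonomic_coverage(n_db, n_cat),
                "n_sequences": n_seqs.get(u, 0),
                "n_endemic": len(endemics.get(u, ())),
                "n_medical": len(medicals.get(u, ())),
            }
        )
    return pd.DataFrame(rows, columns=COVERAGE_COLUMNS)


SPECIES_COLUMNS = [
    "species", "n_sequences", "mean_seq_length", "n_db_countries",
    "n_cat_countries", "geographic_coverage", "medical",
]


def build_species_table(
    records: Sequence[BarcodeRecord],
    cat: TaxonCatalogue,
) -> pd.DataFrame:
    """Per-species predictors for the barcode-gap model: sequence count,
    mean sequence length (bases), distinct database countries, and
    geographic coverage (db countries / catalogue countries)."""
    by_sp: dict[str, list[BarcodeRecord]] = {}
    for r in records:
        by_sp.setdefault(r.species_name, []).append(r)

    rows = []
    for sp in sorted(by_sp):
        recs = by_sp[sp]
        n_cat = len(cat.countries_of[sp])
        n_db = len({r.country for r in recs})
        rows.append(
            {
                "species": sp,
                "n_sequences": len(recs),
                "mean_seq_length": sum(len(r.sequence) for r in recs) / len(recs),
                "n_db_countries": n_db,
                "n_cat_countries": n_cat,
                "geographic_coverage": n_db / n_cat,
                "medical": bool(cat.medical.get(sp, False)),
            }
        )
    return pd.DataFrame(rows, columns=SPECIES_COLUMNS)
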