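"""Taxonomic checklist handling.

The catalogue is the authority for which species names are valid, where each
species occurs (country-level occurrence sets), which species are medically
important, and how countries map onto biogeographic regions.  Everything
downstream — record curation, coverage statistics, the modelling tables — is
expressed relative to this catalogue.

A checklist is a flat table with one species-country row per line::

    species	country	region	medical
    Aedes albopictus	Italy	Palearctic	1

Species flagged as synonyms must not appear: the checklist is expected to
contain accepted binomials only.  A species is *endemic* when its full
catalogue distribution is a single country.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import CatalogueError, FormatError

#: The seven biogeographic realms used for region-level aggregation.
CANONICAL_REGIONS = frozenset(
    {
        "Afrotropical",
        "Australian",
        "Nearctic",
        "Neotropical",
        "Oceanian",
        "Oriental",
        "Palearctic",
    }
)

REQUIRED_COLUMNS = ("species", "country", "region", "medical")

_TRUTHY = {"1", "true", "yes", "y", "t"}
_FALSY = {"0", "false", "no", "n", "f", ""}


def normalize_name(name: str) -> str:
    """Collapse internal whitespace and strip; used for both species and
    country matching (matching is case-insensitive via :func:`fold_name`)."""
    return " ".join(str(name).split())


def fold_name(name: str) -> str:
    return normalize_name(name).casefold()


@dataclass(frozen=True)
class TaxonCatalogue:
    """Validated species checklist.

    Attributes
    ----------
    countries_of
        Mapping from species binomial to its set of catalogue countries.
    medical
        Mapping from species binomial to its medical-importance flag.
    region_of
        Mapping from country name to biogeographic region label.
    """

    countries_of: Mapping[str, frozenset[str]]
    medical: Mapping[str, bool]
    region_of: Mapping[str, str]
    _species_fold: Mapping[str, str] = field(repr=False, default=None)
    _country_fold: Mapping[str, str] = field(repr=False, default=None)

    def __post_init__(self) -> None:
        for sp, cs in self.countries_of.items():
            if not cs:
                raise CatalogueError(f"species {sp!r} has no countries")
            for c in cs:
                if c not in self.region_of:
                    raise CatalogueError(
                        f"country {c!r} (species {sp!r}) missing from region map"
                    )
        object.__setattr__(
            self, "_species_fold", {fold_name(s): s for s in self.countries_of}
        )
        object.__setattr__(
            self, "_country_fold", {fold_name(c): c for c in self.region_of}
        )

    # -- basic accessors -------------------------------------------------
    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.countries_of)

    @property
    def n_species(self) -> int:
        return len(self.countries_of)

    @property
    def countries(self) -> frozenset[str]:
        """Countries referenced by at least one species."""
        out: set[str] = set()
        for cs in self.countries_of.values():
            out |= cs
        return frozenset(out)

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    def endemic(self, species: str) -> bool:
        return len(self.countries_of[species]) == 1

    # -- normalising lookups ---------------------------------------------
    def match_species(self, name: str) -> str | None:
        """Exact (whitespace/case-normalised) species-name match, or None."""
        return self._species_fold.get(fold_name(name))

    def match_country(self, name: str) -> str | None:
        """Gazetteer lookup: canonical country name, or None if unknown."""
        return self._country_fold.get(fold_name(name))

    # -- serialisation ---------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "species": sp,
                "country": c,
                "region": self.region_of[c],
                "medical": int(self.medical.get(sp, False)),
            }
            for sp in sorted(self.countries_of)
            for c in sorted(self.countries_of[sp])
        ]
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _parse_medical(value: str, line: object) -> bool:
    v = str(value).strip().casefold()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise FormatError(f"unparsable medical flag {value!r} (row {line})")


def parse_catalogue(
    checklist_file: str | Path,
    region_map: str | Path | Mapping[str, str] | None = None,
    valid_regions: Iterable[str] = CANONICAL_REGIONS,
) -> TaxonCatalogue:
    """Load and validate a checklist table.

    Parameters
    ----------
    checklist_file
        TSV/CSV with header ``species, country, region, medical``.  The
        ``region`` column may be omitted when ``region_map`` is given.
    region_map
        Optional two-column TSV (country, region) or mapping, overriding or
        replacing the per-row region column.
    valid_regions
        Accepted region labels; defaults to the seven biogeographic realms.

    Duplicate (species, country) rows are deduplicated.  Unknown region
    labels and species with zero countries are rejected.
    """
    path = Path(checklist_file)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except OSError as exc:
        raise FormatError(f"cannot read checklist {path}: {exc}") from exc

    regions: dict[str, str] = {}
    if region_map is not None:
        if isinstance(region_map, Mapping):
            items = region_map.items()
        else:
            rm = pd.read_csv(region_map, sep="\t", dtype=str, keep_default_na=False)
            if rm.shape[1] < 2:
                raise FormatError("region map must have two columns: country, region")
            items = zip(rm.iloc[:, 0], rm.iloc[:, 1])
        regions = {normalize_name(c): normalize_name(r) for c, r in items}

    needed = {"species", "country"}
    if region_map is None:
        needed.add("region")
    if "medical" not in df.columns:
        raise FormatError("checklist is missing required column 'medical'")
    missing = needed - set(df.columns)
    if missing:
        raise FormatError(f"checklist is missing required column(s): {sorted(missing)}")

    valid = frozenset(valid_regions)
    countries_of: dict[str, set[str]] = {}
    medical: dict[str, bool] = {}
    # countries known only from the region map get entries (and zero rows in
    # the per-country summary); their regions are validated too
    region_of: dict[str, str] = {}
    for c, reg in regions.items():
        if reg not in valid:
            raise CatalogueError(f"unknown region {reg!r} for country {c!r}")
        region_of[c] = reg
    for i, row in enumerate(df.itertuples(index=False), start=2):
        sp = normalize_name(getattr(row, "species"))
        country = normalize_name(getattr(row, "country"))
        if not sp or not country:
            raise CatalogueError(f"empty species or country name at row {i}")
        reg = regions.get(country)
        if reg is None and hasattr(row, "region"):
            reg = normalize_name(getattr(row, "region"))
        if not reg:
            raise CatalogueError(f"no region for country {country!r} (row {i})")
        if reg not in valid:
            raise CatalogueError(f"unknown region {reg!r} for country {country!r}")
        prev = region_of.setdefault(country, reg)
        if prev != reg:
            raise CatalogueError(
                f"country {country!r} mapped to both {prev!r} and {reg!r}"
            )
        countries_of.setdefault(sp, set()).add(country)
        flag = _parse_medical(getattr(row, "medical"), i)
        medical[sp] = medical.get(sp, False) or flag

    if not countries_of:
        raise CatalogueError("checklist contains no species rows")
    return TaxonCatalogue(
        countries_of={s: frozenset(c) for s, c in countries_of.items()},
        medical=medical,
        region_of=region_of,
    )


def country_summary(cat: TaxonCatalogue) -> pd.DataFrame:
    """Per-country species richness, endemic richness and medically
    important richness, the three catalogue-side country predictors.

    One row per country in the region map (so a mapped country with no
    catalogue species reports zeros); a species counts as endemic for a
    country only when that country is its *entire* catalogue distribution.
    """
    rows = {
        c: {"country": c, "region": cat.region_of[c], "n_species": 0,
            "n_endemic": 0, "n_medical": 0}
        for c in sorted(cat.region_of)
    }
    for sp, cs in cat.countries_of.items():
        endemic = len(cs) == 1
        med = cat.medical.get(sp, False)
        for c in cs:
            rows[c]["n_species"] += 1
            rows[c]["n_endemic"] += int(endemic)
            rows[c]["n_medical"] += int(med)
    return pd.DataFrame(list(rows.values())).reset_index(drop=True)
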