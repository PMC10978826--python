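"""Shared fixtures: small hand-constructed catalogues and record sets."""

import pytest

from barcode_audit import BarcodeRecord, TaxonCatalogue


@pytest.fixture
def tiny_catalogue():
    """3 species over 2 countries; one endemic-pair country, one medical
    species."""
    return TaxonCatalogue(
        countries_of={
            "Aedes albopictus": frozenset({"Italy", "France"}),
            "Culex pipiens": frozenset({"Italy"}),
            "Anopheles gambiae": frozenset({"France"}),
        },
        medical={
            "Aedes albopictus": True,
            "Culex pipiens": False,
            "Anopheles gambiae": True,
        },
        region_of={"Italy": "Palearctic", "France": "Palearctic"},
    )


def _rec(rid, species, marker="COI-5P", seq="ACGT" * 20, country="Italy",
         accession=None):
    return BarcodeRecord(
        record_id=rid,
        source="bold",
        accession=accession,
        species_name=species,
        marker=marker,
        sequence=seq,
        country=country,
    )


@pytest.fixture
def make_record():
    return _rec


@pytest.fixture
def defect_catalogue():
    """Catalogue backing the 10-row curation fixture: the doomed species is
    catalogued in a single country so one stray record in a second valid
    country trips the country-count sanity check."""
    return TaxonCatalogue(
        countries_of={
            "Aedes albopictus": frozenset({"Italy", "France"}),
            "Culex pipiens": frozenset({"Italy"}),
            "Anopheles doomed": frozenset({"Italy"}),
        },
        medical={
            "Aedes albopictus": True,
            "Culex pipiens": False,
            "Anopheles doomed": False,
        },
        region_of={"Italy": "Palearctic", "France": "Palearctic"},
    )


@pytest.fixture
def defect_records():
    """10 rows constructed so each curation stage removes a known subset:
    2 wrong marker, 1 without sequence, 1 whose country fails the gazetteer,
    1 with an unmatched name, and one species whose surviving rows span two
    countries against a single-country catalogue distribution (both rows
    dropped wholesale at the sanity stage) -> 3 rows survive."""
    return [
        _rec("r01", "Aedes albopictus"),
        _rec("r02", "Aedes albopictus", country="France"),
        _rec("r03", "Culex pipiens"),
        _rec("r04", "Aedes albopictus", marker="ITS2"),
        _rec("r05", "Culex pipiens", marker="COI-3P"),
        _rec("r06", "Aedes albopictus", seq=None),
        _rec("r07", "Culex pipiens", country="Atlantis"),
        _rec("r08", "Culex unknownus"),
        _rec("r09", "Anopheles doomed", country="Italy"),
        _rec("r10", "Anopheles doomed", country="France"),
    ]
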