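"""Synthetic catalogues, barcode sequences and record tables with known truth.

Every pipeline stage is testable without repository downloads: the generator
produces (1) a taxonomic checklist with controlled richness, endemism and
medical-importance structure; (2) barcode sequences with controlled intra-
and interspecific divergence; and (3) BOLD-style record tables whose
country-level inclusion follows a logistic model with a region random
intercept, so coverage statistics and the binomial models have a recoverable
ground truth.

Sequences evolve under a Jukes-Cantor substitution process on a star
topology: a shared root, one centroid per species, and independent tip
branches.  ``intra_divergence`` and ``inter_divergence`` are the *expected
pairwise* substitutions per site between conspecific and heterospecific
sequences respectively (tip branch length ``intra/2`` from the centroid,
centroid branch length ``(inter - intra)/2`` from the root).  Setting
``intra == inter`` therefore collapses all centroids onto the root and makes
conspecific and heterospecific identity distributions coincide — the
no-barcode-gap regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .catalogue import CANONICAL_REGIONS, TaxonCatalogue
from .curation import BarcodeRecord
from .errors import ConfigurationError

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: defect kinds that corrupt only the injected copy of a row
ROW_DEFECTS = ("missing_sequence", "missing_country", "wrong_marker",
               "bad_species_name")
#: defect kind that places a species outside its catalogue range, which
#: sacrifices the whole species at the curation sanity stage
COUNTRY_INFLATION = "extra_country"


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults mirror the audited system: a 3570-species
    catalogue over 317 countries in 7 biogeographic regions, roughly half
    the species single-country endemics, 128 of medical importance, 658-bp
    barcodes, and species sequence counts geometric with mean 11 (so about
    62% of species carry 1-10 sequences)."""

    seed: int
    n_species: int = 3570
    n_countries: int = 317
    n_regions: int = 7
    endemic_frac: float = 0.5
    medical_frac: float = 128 / 3570
    sequence_length: int = 658
    #: expected pairwise substitutions/site between conspecific sequences
    intra_divergence: float = 0.01
    #: expected pairwise substitutions/site between heterospecific sequences
    inter_divergence: float = 0.15
    #: ("fixed", n) or ("geometric", mean) sequences per included pair
    seqs_per_species: tuple[str, float] = ("geometric", 11.0)
    #: logistic coefficients of the record-inclusion model (per covariate)
    coverage_betas: tuple[float, ...] = (-1.0, 0.8)
    coverage_intercept: float = 0.0
    #: SD of the between-region random intercept
    group_sigma: float = 1.0
    #: fraction of clean rows that receive an injected defective copy
    defect_frac: float = 0.0
    defect_types: tuple[str, ...] = ROW_DEFECTS
    marker: str = "COI-5P"

    def __post_init__(self) -> None:
        for name in ("endemic_frac", "medical_frac", "defect_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("intra_divergence", "inter_divergence"):
            v = getattr(self, name)
            if not 0.0 <= v < 0.75:
                raise ConfigurationError(f"{name} must be in [0, 0.75), got {v}")
        if self.inter_divergence < self.intra_divergence:
            raise ConfigurationError(
                "inter_divergence must be >= intra_divergence"
            )
        if self.n_countries < 2 and self.endemic_frac < 1.0:
            raise ConfigurationError(
                "need at least 2 countries unless every species is endemic"
            )
        if self.n_species < self.n_countries:
            raise ConfigurationError("need n_species >= n_countries")
        kind, _ = self.seqs_per_species
        if kind not in ("fixed", "geometric"):
            raise ConfigurationError(f"unknown seqs_per_species kind {kind!r}")
        unknown = set(self.defect_types) - set(ROW_DEFECTS) - {COUNTRY_INFLATION}
        if unknown:
            raise ConfigurationError(f"unknown defect types {sorted(unknown)}")


def _region_labels(n_regions: int) -> list[str]:
    if n_regions <= 7:
        return sorted(CANONICAL_REGIONS)[:n_regions]
    return [f"Region_{i + 1:02d}" for i in range(n_regions)]


def _draw_seq_count(rng: np.random.Generator, count_spec: tuple[str, float]) -> int:
    kind, value = count_spec
    if kind == "fixed":
        return int(value)
    # geometric on {1, 2, ...} with the given mean
    p = 1.0 / float(value)
    return int(rng.geometric(p))


def simulate_catalogue(
    cfg: SimulationConfig,
) -> tuple[TaxonCatalogue, pd.DataFrame]:
    """Generate a checklist with known richness/endemism/medical structure.

    The first ``round(endemic_frac * n_species)`` species are single-country
    endemics, so the realised endemic fraction matches the target to within
    one species.  Every country receives at least one species.  Returns the
    catalogue plus a per-species ground-truth table.
    """
    rng = np.random.default_rng(cfg.seed)
    countries = [f"Country_{i + 1:03d}" for i in range(cfg.n_countries)]
    regions = _region_labels(cfg.n_regions)
    region_of = {c: regions[i % len(regions)] for i, c in enumerate(countries)}
    species = [f"Genus species{i + 1:04d}" for i in range(cfg.n_species)]

    n_endemic = int(round(cfg.endemic_frac * cfg.n_species))
    countries_of: dict[str, frozenset[str]] = {}
    truth_rows = []
    for i, sp in enumerate(species):
        # round-robin over countries first so every country is referenced
        if i < cfg.n_countries:
            home = countries[i]
        else:
            home = countries[rng.integers(cfg.n_countries)]
        if i < n_endemic:
            cs = {home}
        else:
            extra = 1 + int(rng.geometric(0.5))  # 2+ countries, mean 3
            others = rng.choice(
                [c for c in countries if c != home],
                size=min(extra, cfg.n_countries - 1),
                replace=False,
            )
            cs = {home, *others}
        countries_of[sp] = frozenset(cs)
        truth_rows.append({"species": sp, "n_countries": len(cs),
                           "endemic": len(cs) == 1})

    n_medical = int(round(cfg.medical_frac * cfg.n_species))
    medical_species = set(rng.choice(species, size=n_medical, replace=False))
    medical = {sp: sp in medical_species for sp in species}
    for row in truth_rows:
        row["medical"] = medical[row["species"]]

    cat = TaxonCatalogue(
        countries_of=countries_of, medical=medical, region_of=region_of
    )
    return cat, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# sequence simulation
# ---------------------------------------------------------------------------

def _jc_mutate(
    seq: np.ndarray, branch_length: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve a sequence along a branch of the given expected substitutions
    per site under Jukes-Cantor (equal rates, equal base frequencies)."""
    if branch_length == 0.0:
        return seq.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * branch_length / 3.0))
    out = seq.copy()
    hit = rng.random(len(seq)) < p_change
    n_hit = int(hit.sum())
    if n_hit:
        # uniform among the three other bases
        shift = rng.integers(1, 4, size=n_hit)
        out[hit] = (out[hit] + shift) % 4
    return out


def expected_mismatch_fraction(divergence: float) -> float:
    """Expected raw mismatch fraction between two sequences separated by a
    total path of ``divergence`` substitutions/site under Jukes-Cantor."""
    return 0.75 * (1.0 - np.exp(-4.0 * divergence / 3.0))


def _decode(seq: np.ndarray) -> str:
    return _BASES[seq].tobytes().decode()


@dataclass
class BarcodeTruth:
    """Ground truth accompanying simulated barcodes."""

    species_of: Mapping[str, str]
    #: raw mismatch fraction for every unordered sequence pair
    pairwise_mismatch: pd.DataFrame
    #: per-species gap label computed from the raw mismatch fractions
    gap_labels: pd.DataFrame


def simulate_barcodes(
    cat: TaxonCatalogue,
    cfg: SimulationConfig,
    seqs_per_species: tuple[str, float] | None = None,
) -> tuple[dict[str, str], BarcodeTruth]:
    """Generate per-species barcode sequences on the star topology.

    Returns ``(sequences, truth)`` where ``sequences`` maps sequence id to
    DNA string and ``truth`` records the species map, every realised
    pairwise mismatch fraction, and per-species gap labels derived from
    those raw divergences (min conspecific identity vs max heterospecific
    identity, 100% identity for species with a single sequence).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    count_spec = seqs_per_species or cfg.seqs_per_species
    tip_branch = cfg.intra_divergence / 2.0
    centroid_branch = (cfg.inter_divergence - cfg.intra_divergence) / 2.0

    root = rng.integers(0, 4, size=cfg.sequence_length)
    seqs: dict[str, str] = {}
    arrays: list[np.ndarray] = []
    ids: list[str] = []
    species_of: dict[str, str] = {}
    for sp in sorted(cat.species):
        centroid = _jc_mutate(root, centroid_branch, rng)
        n = max(1, _draw_seq_count(rng, count_spec))
        for j in range(n):
            arr = _jc_mutate(centroid, tip_branch, rng)
            sid = f"{sp.replace(' ', '_')}_{j + 1:03d}"
            seqs[sid] = _decode(arr)
            arrays.append(arr)
            ids.append(sid)
            species_of[sid] = sp

    mat = np.stack(arrays)
    rows = []
    for i in range(len(ids)):
        diff = (mat[i + 1:] != mat[i]).mean(axis=1)
        for off, d in enumerate(diff):
            j = i + 1 + off
            rows.append(
                {
                    "id_a": ids[i],
                    "id_b": ids[j],
                    "conspecific": species_of[ids[i]] == species_of[ids[j]],
                    "mismatch_fraction": float(d),
                }
            )
    pw = pd.DataFrame(
        rows, columns=["id_a", "id_b", "conspecific", "mismatch_fraction"]
    )

    gap_rows = []
    for sp in sorted(cat.species):
        mine = {sid for sid, s in species_of.items() if s == sp}
        intra = pw[
            pw["conspecific"] & pw["id_a"].isin(mine)
        ]["mismatch_fraction"]
        inter = pw[
            ~pw["conspecific"]
            & (pw["id_a"].isin(mine) | pw["id_b"].isin(mine))
        ]["mismatch_fraction"]
        min_intra = 100.0 * (1.0 - intra.max()) if len(intra) else 100.0
        max_inter = 100.0 * (1.0 - inter.min()) if len(inter) else None
        gap_rows.append(
            {
                "species": sp,
                "n_sequences": len(mine),
                "min_intra_identity": min_intra,
                "max_inter_identity": max_inter,
                "gap_true": True if max_inter is None
                else (min_intra - max_inter) > 0.0,
            }
        )
    truth = BarcodeTruth(
        species_of=species_of,
        pairwise_mismatch=pw,
        gap_labels=pd.DataFrame(gap_rows),
    )
    return seqs, truth


# ---------------------------------------------------------------------------
# record-table simulation
# ---------------------------------------------------------------------------

@dataclass
class RecordTruth:
    """Ground truth accompanying a simulated record table."""

    #: per-country design and truth: covariates, random intercept, inclusion
    #: probability, catalogue richness and realised covered-species count
    country_table: pd.DataFrame
    coverage_betas: tuple[float, ...]
    coverage_intercept: float
    group_sigma: float
    #: record ids expected to survive curation
    clean_record_ids: frozenset[str]
    #: species sacrificed by country-inflation defects (dropped at curation)
    sacrificed_species: frozenset[str]


def simulate_records(
    cat: TaxonCatalogue,
    cfg: SimulationConfig,
    sequences: Mapping[str, str] | None = None,
) -> tuple[list[BarcodeRecord], RecordTruth]:
    """Generate a BOLD-style record table under the inclusion model.

    Each (species, country) catalogue pair is included with probability
    ``logit^-1(b0 + x_c . beta + u_region)`` where the covariates ``x_c``
    are independent standard normals per country and ``u_region ~
    N(0, group_sigma^2)``.  Included pairs receive a sequence count drawn
    from ``seqs_per_species``.  A ``defect_frac`` fraction of clean rows
    additionally get a corrupted *copy* appended (wrong marker, missing
    sequence, missing country or an unmatched species name), so curation
    should remove exactly the injected rows; the country-inflation defect,
    which makes curation drop a whole species, must be opted into via
    ``defect_types``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    countries = sorted(cat.countries)
    regions = sorted({cat.region_of[c] for c in countries})
    u_region = {
        r: rng.normal(0.0, cfg.group_sigma) for r in regions
    }
    n_cov = len(cfg.coverage_betas)
    X = rng.normal(size=(len(countries), n_cov))
    betas = np.asarray(cfg.coverage_betas)
    eta = {
        c: cfg.coverage_intercept + X[i] @ betas + u_region[cat.region_of[c]]
        for i, c in enumerate(countries)
    }

    records: list[BarcodeRecord] = []
    covered: dict[str, set[str]] = {c: set() for c in countries}
    counter = 0
    for sp in sorted(cat.species):
        for c in sorted(cat.countries_of[sp]):
            if rng.random() >= special.expit(eta[c]):
                continue
            covered[c].add(sp)
            n = max(1, _draw_seq_count(rng, cfg.seqs_per_species))
            for _ in range(n):
                counter += 1
                rid = f"SIM{counter:07d}"
                if sequences:
                    seq = sequences.get(rid)
                else:
                    seq = None
                if seq is None:
                    seq = _decode(rng.integers(0, 4, size=cfg.sequence_length))
                records.append(
                    BarcodeRecord(
                        record_id=rid,
                        source="bold",
                        species_name=sp,
                        marker=cfg.marker,
                        sequence=seq,
                        country=c,
                    )
                )

    clean_ids = frozenset(r.record_id for r in records)

    # --- defect injection: corrupted copies appended after the clean rows
    sacrificed: set[str] = set()
    db_countries: dict[str, set[str]] = {}
    for r in records:
        db_countries.setdefault(r.species_name, set()).add(r.country)
    n_defects = int(round(cfg.defect_frac * len(records)))
    defect_rows: list[BarcodeRecord] = []
    if n_defects and records:
        victims = rng.choice(len(records), size=n_defects, replace=False)
        for v in victims:
            base = records[int(v)]
            kind = cfg.defect_types[int(rng.integers(len(cfg.defect_types)))]
            counter += 1
            bad = replace(base, record_id=f"DEF{counter:07d}")
            if kind == "missing_sequence":
                bad = replace(bad, sequence=None)
            elif kind == "missing_country":
                bad = replace(bad, country=None)
            elif kind == "wrong_marker":
                bad = replace(bad, marker="ITS2")
            elif kind == "bad_species_name":
                bad = replace(bad, species_name="Genus nonexistens")
            elif kind == COUNTRY_INFLATION:
                # the sanity stage compares distinct-country *counts*, so a
                # single stray country only dooms an already fully covered
                # species; inject enough out-of-range countries to push the
                # species past its catalogue count whatever its coverage
                sp = base.species_name
                if sp in sacrificed:
                    continue
                pool = sorted(set(countries) - cat.countries_of[sp]
                              - db_countries[sp])
                needed = len(cat.countries_of[sp]) - len(db_countries[sp]) + 1
                if len(pool) < needed:
                    continue
                picked = [
                    pool[int(i)]
                    for i in rng.choice(len(pool), size=needed, replace=False)
                ]
                for extra_c in picked:
                    counter += 1
                    defect_rows.append(
                        replace(base, record_id=f"DEF{counter:07d}",
                                country=extra_c)
                    )
                    db_countries[sp].add(extra_c)
                sacrificed.add(sp)
                continue
            defect_rows.append(bad)
    records = records + defect_rows

    surviving = frozenset(
        r.record_id
        for r in records
        if r.record_id in clean_ids and r.species_name not in sacrificed
    )

    country_rows = []
    for i, c in enumerate(countries):
        n_cat = sum(1 for cs in cat.countries_of.values() if c in cs)
        row = {
            "country": c,
            "region": cat.region_of[c],
            "u_region": u_region[cat.region_of[c]],
            "p_include": float(special.expit(eta[c])),
            "n_cat_species": n_cat,
            "n_covered_true": len(covered[c]),
        }
        for j in range(n_cov):
            row[f"x{j + 1}"] = X[i, j]
        country_rows.append(row)

    truth = RecordTruth(
        country_table=pd.DataFrame(country_rows),
        coverage_betas=cfg.coverage_betas,
        coverage_intercept=cfg.coverage_intercept,
        group_sigma=cfg.group_sigma,
        clean_record_ids=surviving,
        sacrificed_species=frozenset(sacrificed),
    )
    return records, truth


def write_fasta(sequences: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for sid in sorted(sequences):
            fh.write(f">{sid}\n{sequences[sid]}\n")


def write_species_map(species_of: Mapping[str, str], path) -> None:
    pd.DataFrame(
        sorted(species_of.items()), columns=["record_id", "species"]
    ).to_csv(path, sep="\t", index=False)
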