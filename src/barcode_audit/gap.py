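"""All-vs-all pairwise identity search and the DNA barcode gap decision.

The barcode gap for a species is the difference between its minimum
intraspecific identity and its maximum interspecific identity, both taken
from a top-k identity search of every sequence against the full database.
A positive difference means the species' sequences are mutually more similar
than to any other species' — the species is distinguishable by the marker.
A difference of zero or less means at least one heterospecific sequence is
as close as (or closer than) the most divergent conspecific pair.

Identities come from best local alignments over both strands under an
affine-gap scoring scheme (defaults mimic megablast: match +2, mismatch -3,
gap open -5, gap extend -2).  ``pident`` follows the BLAST convention:
identical columns over alignment length, gap columns counted in the
denominator, and only exact-base equality (A/C/G/T) counts as identity —
``N`` never matches.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.sequence as bseq
import biotite.sequence.align as balign

from .curation import IUPAC_NT, BarcodeRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine local-alignment scoring; defaults approximate megablast."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def substitution_matrix(self) -> balign.SubstitutionMatrix:
        alph = bseq.NucleotideSequence.alphabet_amb
        n = len(alph)
        mat = np.full((n, n), self.mismatch, dtype=np.int32)
        for b in "ACGT":
            i = alph.encode(b)
            mat[i, i] = self.match
        return balign.SubstitutionMatrix(alph, alph, mat)


DEFAULT_SCORING = AlignmentScoring()

# encodings of the four unambiguous bases in the ambiguous alphabet
_EXACT_CODES = frozenset(
    bseq.NucleotideSequence.alphabet_amb.encode(b) for b in "ACGT"
)


@dataclass(frozen=True)
class IdentityHit:
    query_id: str
    subject_id: str
    pident: float
    alignment_length: int
    strand: str  # "+" or "-"


def _as_nt(sequence: str, label: str) -> bseq.NucleotideSequence:
    if not sequence:
        raise ValueError(f"{label} sequence is empty")
    bad = set(sequence.upper()) - IUPAC_NT
    if bad:
        raise ValueError(f"{label} sequence has non-IUPAC characters {sorted(bad)}")
    return bseq.NucleotideSequence(sequence.upper(), ambiguous=True)


def _pident_from_alignment(aln: balign.Alignment) -> tuple[float, int]:
    codes = balign.get_codes(aln)
    length = codes.shape[1]
    a, b = codes[0], codes[1]
    ident = int(
        np.sum((a == b) & np.isin(a, list(_EXACT_CODES)))
    )
    return 100.0 * ident / length, length


def _align_pair(a, b, b_rc, matrix, gap_penalty) -> tuple[float, int, str]:
    fwd = balign.align_optimal(a, b, matrix, gap_penalty=gap_penalty,
                               local=True, max_number=1)[0]
    rev = balign.align_optimal(a, b_rc, matrix, gap_penalty=gap_penalty,
                               local=True, max_number=1)[0]
    if rev.score > fwd.score:
        pident, length = _pident_from_alignment(rev)
        return pident, length, "-"
    pident, length = _pident_from_alignment(fwd)
    return pident, length, "+"


def align_identity(
    seq_a: str,
    seq_b: str,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> tuple[float, int, str]:
    """Best local alignment of ``seq_a`` against ``seq_b`` over both strands.

    Returns ``(pident, alignment_length, strand)``.  The higher-scoring
    strand wins; on a score tie the plus strand is reported.
    """
    a = _as_nt(seq_a, "query")
    b = _as_nt(seq_b, "subject")
    return _align_pair(
        a,
        b,
        b.reverse(copy=False).complement(),
        scoring.substitution_matrix(),
        (scoring.gap_open, scoring.gap_extend),
    )


def _sequences_of(
    records: Sequence[BarcodeRecord] | Mapping[str, str],
) -> dict[str, str]:
    if isinstance(records, Mapping):
        return dict(records)
    out = {}
    for r in records:
        if not r.sequence:
            raise ValueError(f"record {r.record_id} has no sequence")
        out[r.record_id] = r.sequence
    return out


def identity_search(
    records: Sequence[BarcodeRecord] | Mapping[str, str],
    top_k: int = 100,
    scoring: AlignmentScoring = DEFAULT_SCORING,
) -> list[IdentityHit]:
    """All-vs-all identity search, keeping the ``top_k`` best hits per query.

    The database and the query set are the same sequences (each sequence is
    queried against the full set including itself, so the self-hit at
    pident 100 is always present).  Hits per query are sorted by pident
    descending, ties broken by alignment length descending (a full-length
    match outranks a trivially short perfect local match) and then by
    subject id, making the output deterministic under input permutation.

    pident is symmetric under the symmetric scoring scheme, so each
    unordered pair is aligned once and reused for both query directions.
    """
    seqs = _sequences_of(records)
    if len(seqs) < 2:
        raise ValueError("identity search needs at least 2 sequences")
    ids = sorted(seqs)

    matrix = scoring.substitution_matrix()
    gp = (scoring.gap_open, scoring.gap_extend)
    objs = {i: _as_nt(seqs[i], i) for i in ids}
    rcs = {i: objs[i].reverse(copy=False).complement() for i in ids}

    pair: dict[tuple[str, str], tuple[float, int, str]] = {}
    for i, qid in enumerate(ids):
        pair[(qid, qid)] = (100.0, len(seqs[qid]), "+")
        for sid in ids[i + 1:]:
            res = _align_pair(objs[qid], objs[sid], rcs[sid], matrix, gp)
            pair[(qid, sid)] = res
            pair[(sid, qid)] = res

    hits: list[IdentityHit] = []
    for qid in ids:
        row = [
            IdentityHit(qid, sid, *pair[(qid, sid)])
            for sid in ids
        ]
        row.sort(key=lambda h: (-h.pident, -h.alignment_length, h.subject_id))
        hits.extend(row[:top_k])
    return hits


def hits_to_frame(hits: Iterable[IdentityHit]) -> pd.DataFrame:
    """BLAST outfmt-6-like hit table (query, subject, pident, length, strand)."""
    return pd.DataFrame(
        [
            {
                "query_id": h.query_id,
                "subject_id": h.subject_id,
                "pident": h.pident,
                "alignment_length": h.alignment_length,
                "strand": h.strand,
            }
            for h in hits
        ],
        columns=["query_id", "subject_id", "pident", "alignment_length", "strand"],
    )


@dataclass(frozen=True)
class SpeciesGapResult:
    species: str
    n_sequences: int
    min_intra: float | None
    max_inter: float | None
    gap_present: bool
    singleton: bool
    #: no heterospecific hit survived top-k truncation for this species
    no_inter_hit: bool = False


def call_species_gap(
    hits: Sequence[IdentityHit],
    species_of: Mapping[str, str],
    include_self_hits: bool = True,
) -> list[SpeciesGapResult]:
    """Per-species barcode-gap decision from a retained hit table.

    ``min_intra`` is the minimum pident over conspecific hits (self-hits
    included by default, so a singleton species gets min_intra = 100 and the
    total-match rule for singletons — gap absent iff some heterospecific
    identity reaches 100 — emerges without a special case).  ``max_inter``
    is the maximum pident over heterospecific hits.  The gap is present iff
    ``min_intra - max_inter > 0``.  A species with no heterospecific hit in
    the retained table is called gap-present and flagged ``no_inter_hit``:
    nothing in its searched neighbourhood is confusable with it.
    """
    for h in hits:
        if h.query_id not in species_of:
            raise ValueError(f"record {h.query_id} has no species mapping")
        if h.subject_id not in species_of:
            raise ValueError(f"record {h.subject_id} has no species mapping")

    n_seq: dict[str, int] = {}
    for rid, sp in species_of.items():
        n_seq[sp] = n_seq.get(sp, 0) + 1

    min_intra: dict[str, float] = {}
    max_inter: dict[str, float] = {}
    n_intra_hits: dict[str, int] = {}
    for h in hits:
        qs = species_of[h.query_id]
        if h.query_id == h.subject_id and not include_self_hits:
            continue
        if qs == species_of[h.subject_id]:
            min_intra[qs] = min(min_intra.get(qs, 100.0), h.pident)
            n_intra_hits[qs] = n_intra_hits.get(qs, 0) + 1
        else:
            max_inter[qs] = max(max_inter.get(qs, 0.0), h.pident)

    results = []
    for sp in sorted(n_seq):
        n = n_seq[sp]
        mi = min_intra.get(sp)
        mx = max_inter.get(sp)
        # more conspecific pairs exist than hits retained: top-k truncation
        # can only have discarded the *lowest* conspecific identities
        expected_pairs = n * n if include_self_hits else n * (n - 1)
        if n_intra_hits.get(sp, 0) < expected_pairs:
            logger.warning(
                "species %s: conspecific hits truncated by top-k; "
                "min_intra may be overestimated", sp,
            )
        if mx is None:
            gap = True
        elif mi is None:
            # no conspecific hit retained (self-hits excluded or truncated):
            # fall back to the singleton total-match rule
            gap = mx < 100.0
        else:
            gap = (mi - mx) > 0.0
        results.append(
            SpeciesGapResult(
                species=sp,
                n_sequences=n,
                min_intra=mi,
                max_inter=mx,
                gap_present=gap,
                singleton=(n == 1),
                no_inter_hit=(mx is None),
            )
        )
    return results


def gap_prevalence(results: Sequence[SpeciesGapResult]) -> float:
    """Percentage of species with the barcode gap present, one decimal."""
    if not results:
        raise ValueError("no species gap results")
    pct = 100.0 * sum(r.gap_present for r in results) / len(results)
    from .coverage import _round_half_up

    return _round_half_up(pct, 1)


def gap_results_to_frame(results: Iterable[SpeciesGapResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])
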