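"""Candidate paralog-pair universe from all-vs-all protein similarity.

Hits come either from standard 12-column tabular output (BLAST outfmt 6)
or from the internal pairwise aligner.  The default thresholds are the
printed filter set: e-value <= 1e-20, identity >= 50%, alignment length
> 300 bp (aligned columns x 3 for protein alignments), mismatches < 550,
gap opens < 30; self hits are removed and both genes of a pair must share
a gene family.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, TextIO

from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "HomologyHit",
    "CandidatePair",
    "FilterThresholds",
    "parse_hits",
    "filter_hits",
    "build_candidate_pairs",
    "align_all_vs_all",
]

# Karlin-Altschul parameters for gapped BLOSUM62 (11/1), as published in
# the BLAST documentation; used only for the internal e-value surrogate.
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass(frozen=True)
class HomologyHit:
    query: str
    subject: str
    percent_identity: float
    alignment_length: int  # aligned columns (residues)
    mismatches: int
    gap_opens: int
    evalue: float
    bitscore: float


@dataclass(frozen=True)
class CandidatePair:
    gene_a: str  # lexicographically smaller
    gene_b: str
    family: str
    source_hit: HomologyHit


@dataclass(frozen=True)
class FilterThresholds:
    max_evalue: float = 1e-20
    min_identity: float = 50.0
    min_aln_bp: int = 300  # strict >; protein columns are converted x3
    max_mismatches: int = 550  # strict <
    max_gap_opens: int = 30  # strict <
    aln_units: str = "aa"  # "aa": columns x 3 vs min_aln_bp; "nt": columns x 1


def parse_hits(stream: Iterable[str] | TextIO) -> list[HomologyHit]:
    """Parse 12-column tabular hits (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore)."""
    hits = []
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 12:
            raise ValueError(
                f"line {lineno}: expected 12 tab-separated columns, got {len(fields)}"
            )
        try:
            hits.append(
                HomologyHit(
                    query=fields[0],
                    subject=fields[1],
                    percent_identity=float(fields[2]),
                    alignment_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    evalue=float(fields[10]),
                    bitscore=float(fields[11]),
                )
            )
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
    return hits


def filter_hits(
    hits: Iterable[HomologyHit], thresholds: FilterThresholds | None = None
) -> list[HomologyHit]:
    """Apply the five hit filters and drop self hits.  Total and idempotent."""
    t = thresholds or FilterThresholds()
    scale = 3 if t.aln_units == "aa" else 1
    kept = []
    for h in hits:
        if h.query == h.subject:
            continue
        if h.evalue > t.max_evalue:
            continue
        if h.percent_identity < t.min_identity:
            continue
        if h.alignment_length * scale <= t.min_aln_bp:
            continue
        if h.mismatches >= t.max_mismatches:
            continue
        if h.gap_opens >= t.max_gap_opens:
            continue
        kept.append(h)
    return kept


def _better_hit(a: HomologyHit, b: HomologyHit) -> HomologyHit:
    """Lower e-value wins; ties by higher bitscore, then by (query, subject)."""
    ka = (a.evalue, -a.bitscore, a.query, a.subject)
    kb = (b.evalue, -b.bitscore, b.query, b.subject)
    return a if ka <= kb else b


def build_candidate_pairs(
    hits: Iterable[HomologyHit], families: Mapping[str, str]
) -> list[CandidatePair]:
    """Unordered-unique same-family pairs; reciprocal hits are collapsed to
    the better one.  Genes without a family assignment are dropped."""
    best: dict[tuple[str, str], HomologyHit] = {}
    n_no_family = 0
    for h in hits:
        if h.query == h.subject:
            continue
        fq = families.get(h.query)
        fs = families.get(h.subject)
        if fq is None or fs is None:
            n_no_family += 1
            continue
        if fq != fs:
            continue
        key = (h.query, h.subject) if h.query < h.subject else (h.subject, h.query)
        best[key] = _better_hit(best[key], h) if key in best else h
    if n_no_family:
        logger.info("dropped %d hits lacking a family assignment", n_no_family)
    return [
        CandidatePair(a, b, families[a], hit)
        for (a, b), hit in sorted(best.items())
    ]


def _aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _summarize_alignment(
    query: str, subject: str, seq_q: str, seq_s: str, db_residues: int, aligner=None
) -> HomologyHit:
    aligner = aligner or _aligner()
    aln = aligner.align(seq_q, seq_s)[0]
    counts = aln.counts()
    identities = counts.identities
    mismatches = counts.mismatches
    gap_opens = (
        counts.open_left_insertions
        + counts.open_left_deletions
        + counts.open_internal_insertions
        + counts.open_internal_deletions
        + counts.open_right_insertions
        + counts.open_right_deletions
    )
    length = aln.length  # columns including gaps, as BLAST reports
    pident = 100.0 * identities / length if length else 0.0
    bitscore = (_KA_LAMBDA * aln.score - math.log(_KA_K)) / math.log(2.0)
    evalue = len(seq_q) * db_residues * math.pow(2.0, -bitscore)
    return HomologyHit(
        query=query,
        subject=subject,
        percent_identity=round(pident, 2),
        alignment_length=length,
        mismatches=int(mismatches),
        gap_opens=int(gap_opens),
        evalue=evalue,
        bitscore=round(bitscore, 1),
    )


def align_all_vs_all(
    proteins: Mapping[str, str],
    families: Mapping[str, str] | None = None,
    include_self: bool = True,
) -> list[HomologyHit]:
    """Summarize a global affine-gap BLOSUM62 alignment for every ordered
    gene pair into BLAST-like hit records.

    With ``families`` given, only same-family pairs are aligned — the
    downstream same-family constraint discards the others anyway, and the
    e-value surrogate still uses the full search-space size.
    """
    names = sorted(proteins)
    db_residues = sum(len(s) for s in proteins.values())
    aligner = _aligner()
    hits: list[HomologyHit] = []
    for i, qa in enumerate(names):
        if include_self and proteins[qa]:
            hits.append(
                _summarize_alignment(qa, qa, proteins[qa], proteins[qa], db_residues, aligner)
            )
        for qb in names[i + 1 :]:
            if families is not None and families.get(qa) != families.get(qb):
                continue
            if not proteins[qa] or not proteins[qb]:
                continue
            h = _summarize_alignment(qa, qb, proteins[qa], proteins[qb], db_residues, aligner)
            hits.append(h)
            hits.append(
                HomologyHit(
                    query=h.subject,
                    subject=h.query,
                    percent_identity=h.percent_identity,
                    alignment_length=h.alignment_length,
                    mismatches=h.mismatches,
                    gap_opens=h.gap_opens,
                    evalue=h.evalue,
                    bitscore=h.bitscore,
                )
            )
    return hits
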