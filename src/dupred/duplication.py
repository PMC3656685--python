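"""Duplicate-gene calling and closest-paralog identification.

Two routes mirror common practice: a homology route (local protein alignment,
bitscore > 80 and >= 50% coverage of the shorter protein) and a family route
(any family with two or more genes from the focal species makes those genes
duplicates).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ValidationError

__all__ = [
    "GeneRecord",
    "AlignmentHit",
    "ParalogPair",
    "align_proteins",
    "call_duplicates",
    "call_duplicates_by_family",
    "closest_paralog",
]

# Karlin-Altschul constants for gapped BLOSUM62 scoring (raw -> bit score).
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041


@dataclass
class GeneRecord:
    """One gene: identifiers, species, sequences and labels."""

    gene_id: str
    species: str
    protein_seq: Optional[str] = None
    cds_seq: Optional[str] = None
    disease_label: Optional[str] = None  # MD / PD / ND for focal-species genes
    family_id: Optional[str] = None

    def validate(self) -> None:
        if self.cds_seq is not None and len(self.cds_seq) % 3 != 0:
            raise ValidationError(
                f"{self.gene_id}: CDS length {len(self.cds_seq)} not divisible by 3"
            )
        if self.disease_label is not None and self.disease_label not in (
            "MD",
            "PD",
            "ND",
        ):
            raise ValidationError(
                f"{self.gene_id}: disease label must be MD/PD/ND, got "
                f"{self.disease_label!r}"
            )


@dataclass(frozen=True)
class AlignmentHit:
    """Best local alignment between two proteins."""

    query: str
    subject: str
    bitscore: float
    aligned_len: int  # columns of the local alignment (gaps included)
    identity: float  # identical columns / aligned columns
    shorter_len: int
    coverage: float  # aligned residues of the shorter protein / its length
    raw_score: float = 0.0

    @property
    def pair(self) -> tuple[str, str]:
        return tuple(sorted((self.query, self.subject)))


@dataclass
class ParalogPair:
    """A gene and its closest paralog, stored canonically (lexicographic)."""

    gene_a: str
    gene_b: str
    identity: float = math.nan
    age: float = math.nan
    is_md_pair: bool = False
    metrics: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gene_a > self.gene_b:
            self.gene_a, self.gene_b = self.gene_b, self.gene_a

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def _check_protein(seq: str, alphabet: str, label: str) -> None:
    bad = sorted(set(seq.upper()) - set(alphabet))
    if bad:
        raise ValidationError(f"{label}: non-amino-acid characters {bad}")


def align_proteins(
    seq_a: str,
    seq_b: str,
    substitution_matrix: str = "BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    karlin_lambda: float = DEFAULT_LAMBDA,
    karlin_k: float = DEFAULT_K,
    ids: tuple[str, str] = ("a", "b"),
) -> AlignmentHit:
    """Best local alignment of two proteins with a bitscore.

    Gap costs follow the BLAST convention: a gap of length L costs
    ``gap_open + L * gap_extend``.  The raw Smith–Waterman score is converted
    to a bitscore via the Karlin–Altschul formula
    ``(lambda * S - ln K) / ln 2``.  When no positive-scoring window exists
    an empty hit (score 0, identity 0, coverage 0) is returned.
    """
    if not seq_a or not seq_b:
        raise ValidationError("empty protein sequence")
    matrix = substitution_matrices.load(substitution_matrix)
    alphabet = str(matrix.alphabet)
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    _check_protein(seq_a, alphabet, ids[0])
    _check_protein(seq_b, alphabet, ids[1])

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend

    shorter_len = min(len(seq_a), len(seq_b))
    score = aligner.score(seq_a, seq_b)
    if score <= 0:
        return AlignmentHit(
            query=ids[0],
            subject=ids[1],
            bitscore=0.0,
            aligned_len=0,
            identity=0.0,
            shorter_len=shorter_len,
            coverage=0.0,
            raw_score=0.0,
        )
    alignment = next(iter(aligner.align(seq_a, seq_b)))
    col_a, col_b = str(alignment[0]), str(alignment[1])
    aligned_len = len(col_a)
    identical = sum(1 for x, y in zip(col_a, col_b) if x == y and x != "-")

    # residues of each sequence consumed by the aligned region
    used_a = sum(1 for x in col_a if x != "-")
    used_b = sum(1 for y in col_b if y != "-")
    used_shorter = used_a if len(seq_a) <= len(seq_b) else used_b

    bitscore = (karlin_lambda * score - math.log(karlin_k)) / math.log(2)
    return AlignmentHit(
        query=ids[0],
        subject=ids[1],
        bitscore=bitscore,
        aligned_len=aligned_len,
        identity=identical / aligned_len if aligned_len else 0.0,
        shorter_len=shorter_len,
        coverage=used_shorter / shorter_len,
        raw_score=float(score),
    )


def call_duplicates(
    hits: Iterable[AlignmentHit],
    min_bitscore: float = 80.0,
    min_coverage: float = 0.5,
    genes: Optional[Iterable[str]] = None,
) -> tuple[set[tuple[str, str]], Counter]:
    """Call duplicate pairs from alignment hits.

    A pair is retained iff its best hit has bitscore strictly above
    ``min_bitscore`` AND coverage of the shorter protein of at least
    ``min_coverage``.  Returns the retained unordered pairs and per-gene
    paralog counts (genes with zero retained pairs are singletons; pass
    ``genes`` to include them with count 0).
    """
    best: dict[tuple[str, str], AlignmentHit] = {}
    for hit in hits:
        if hit.query == hit.subject:
            raise ValidationError(f"self-hit for gene {hit.query}")
        key = hit.pair
        prev = best.get(key)
        if prev is None or hit.bitscore > prev.bitscore:
            best[key] = hit

    pairs = {
        key
        for key, hit in best.items()
        if hit.bitscore > min_bitscore and hit.coverage >= min_coverage
    }
    counts: Counter = Counter()
    if genes is not None:
        for g in genes:
            counts[g] = 0
    for a, b in pairs:
        counts[a] += 1
        counts[b] += 1
    return pairs, counts


def call_duplicates_by_family(
    genes: Sequence[GeneRecord],
    focal_species: str = "human",
) -> dict[str, set[str]]:
    """Family-based duplicate calling.

    Every focal-species gene that shares a ``family_id`` with at least one
    other focal-species gene is a duplicate.  Returns a map from family id to
    its set of duplicated focal-species genes (families contributing fewer
    than two focal genes are omitted; their genes are singletons).
    """
    missing = [g.gene_id for g in genes if g.family_id is None]
    if missing:
        raise ValidationError(
            f"genes without family_id: {sorted(missing)}"
        )
    by_family: dict[str, set[str]] = {}
    for g in genes:
        if g.species == focal_species:
            by_family.setdefault(g.family_id, set()).add(g.gene_id)
    return {fam: members for fam, members in by_family.items() if len(members) >= 2}


def closest_paralog(
    gene: str,
    candidates: Sequence[tuple[str, float, float]],
) -> ParalogPair:
    """Pick the most recent duplication partner of ``gene``.

    ``candidates`` are ``(partner_id, age, identity)`` triples.  The partner
    with the smallest duplication age wins; ties break on higher protein
    identity, then on lexicographic partner id.
    """
    if not candidates:
        raise ValidationError(f"no paralog for gene {gene}")
    best = min(
        candidates,
        key=lambda c: (c[1], -(c[2] if not math.isnan(c[2]) else -1.0), c[0]),
    )
    partner, age, identity = best
    return ParalogPair(gene_a=gene, gene_b=partner, identity=identity, age=age)
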