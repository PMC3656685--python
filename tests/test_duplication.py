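"""Protein alignment, duplicate calling, closest-paralog selection."""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from dupred.duplication import (
    AlignmentHit,
    GeneRecord,
    align_proteins,
    call_duplicates,
    call_duplicates_by_family,
    closest_paralog,
)
from dupred.errors import ValidationError

from oracles import sw_local_score

AA = "ACDEFGHIKLMNPQRSTVWY"


def _hit(q, s, bitscore, coverage=0.9, identity=0.5):
    return AlignmentHit(
        query=q,
        subject=s,
        bitscore=bitscore,
        aligned_len=100,
        identity=identity,
        shorter_len=100,
        coverage=coverage,
    )


def test_identical_proteins_align_perfectly():
    hit = align_proteins("ACDEFGHIK", "ACDEFGHIK")
    assert hit.identity == 1.0
    assert hit.coverage == 1.0
    assert hit.bitscore > 0


def test_no_positive_window_reports_empty_alignment():
    hit = align_proteins("AAAAAA", "WWWWWW")
    assert hit.raw_score == 0.0
    assert hit.bitscore == 0.0
    assert hit.identity == 0.0
    assert hit.aligned_len == 0


def test_non_amino_characters_rejected():
    with pytest.raises(ValidationError):
        align_proteins("ACDE1", "ACDE")
    with pytest.raises(ValidationError):
        align_proteins("", "ACDE")


def test_five_mismatches_give_identity_090_and_oracle_score():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list(AA), 50))
    mutated = list(seq)
    for pos in rng.choice(50, size=5, replace=False):
        choices = [c for c in AA if c != mutated[pos]]
        mutated[pos] = choices[int(rng.integers(len(choices)))]
    mutated = "".join(mutated)
    hit = align_proteins(seq, mutated)
    matrix = substitution_matrices.load("BLOSUM62")
    assert hit.raw_score == sw_local_score(seq, mutated, matrix, 11, 1)
    if hit.aligned_len == 50:  # full-length local alignment
        assert hit.identity == pytest.approx(0.9)


@pytest.mark.parametrize("seed", range(8))
def test_alignment_score_matches_dp_oracle(seed):
    rng = np.random.default_rng(seed)
    a = "".join(rng.choice(list(AA), int(rng.integers(10, 40))))
    b = "".join(rng.choice(list(AA), int(rng.integers(10, 40))))
    matrix = substitution_matrices.load("BLOSUM62")
    hit = align_proteins(a, b)
    assert hit.raw_score == pytest.approx(
        sw_local_score(a, b, matrix, 11, 1), abs=1e-9
    )


def test_bitscore_threshold_is_strict():
    # bitscore exactly 80 with good coverage is NOT a duplicate
    pairs, _ = call_duplicates([_hit("A", "B", 80.0, coverage=0.9)])
    assert pairs == set()
    pairs, _ = call_duplicates([_hit("A", "B", 81.0, coverage=0.5)])
    assert pairs == {("A", "B")}


def test_coverage_threshold_is_inclusive():
    pairs, _ = call_duplicates([_hit("A", "B", 81.0, coverage=0.4999)])
    assert pairs == set()
    pairs, _ = call_duplicates([_hit("A", "B", 81.0, coverage=0.5)])
    assert pairs == {("A", "B")}


def test_paralog_counts_equal_graph_degree():
    hits = [
        _hit("A", "B", 100),
        _hit("B", "C", 100),
        _hit("A", "C", 50),  # fails bitscore
    ]
    pairs, counts = call_duplicates(hits)
    assert pairs == {("A", "B"), ("B", "C")}
    assert counts == {"A": 1, "B": 2, "C": 1}


def test_best_hit_per_pair_wins():
    hits = [_hit("A", "B", 50), _hit("B", "A", 120)]
    pairs, _ = call_duplicates(hits)
    assert pairs == {("A", "B")}


def test_raising_bitscore_never_grows_duplicate_set():
    rng = np.random.default_rng(3)
    genes = [f"G{i}" for i in range(12)]
    hits = [
        _hit(a, b, float(rng.uniform(0, 200)), coverage=float(rng.uniform(0, 1)))
        for a, b in itertools.combinations(genes, 2)
    ]
    previous = None
    for threshold in (0, 40, 80, 120, 160, 200):
        pairs, _ = call_duplicates(hits, min_bitscore=threshold)
        if previous is not None:
            assert pairs.issubset(previous)
        previous = pairs


def test_family_based_calls():
    genes = [
        GeneRecord("A", "human", family_id="f1"),
        GeneRecord("B", "human", family_id="f1"),
        GeneRecord("C", "mouse", family_id="f1"),
        GeneRecord("D", "human", family_id="f2"),
        GeneRecord("E", "mouse", family_id="f2"),
    ]
    dup = call_duplicates_by_family(genes)
    assert dup == {"f1": {"A", "B"}}


def test_family_calls_require_family_ids():
    with pytest.raises(ValidationError, match="X"):
        call_duplicates_by_family([GeneRecord("X", "human")])


def test_family_duplicate_count_matches_enumeration():
    rng = np.random.default_rng(5)
    genes, expected = [], 0
    for fam in range(10):
        k = int(rng.integers(0, 5))
        expected += k if k >= 2 else 0
        for j in range(k):
            genes.append(GeneRecord(f"f{fam}g{j}", "human", family_id=f"f{fam}"))
        genes.append(GeneRecord(f"f{fam}m", "mouse", family_id=f"f{fam}"))
    dup = call_duplicates_by_family(genes)
    assert sum(len(v) for v in dup.values()) == expected


def test_closest_paralog_prefers_smallest_age():
    pair = closest_paralog("G", [("P1", 320.0, 0.5), ("P2", 90.0, 0.4)])
    assert pair.pair == ("G", "P2")
    assert pair.age == 90.0


def test_closest_paralog_tie_breaks_on_identity_then_name():
    pair = closest_paralog("G", [("P1", 90.0, 0.6), ("P2", 90.0, 0.8)])
    assert pair.pair == ("G", "P2")
    pair = closest_paralog("G", [("P2", 90.0, 0.8), ("P1", 90.0, 0.8)])
    assert pair.pair == ("G", "P1")


def test_closest_paralog_requires_candidates():
    with pytest.raises(ValidationError):
        closest_paralog("G", [])


def test_homology_and_family_calls_agree_on_synthetic_proteins(small_cohort):
    """Primary-pair proteins with identity >= 0.35 are recovered by the
    homology route, and unrelated cross-family proteins are not."""
    proteins = {
        g.gene_id: g.protein_seq for g in small_cohort.human_genes() if g.protein_seq
    }
    primary = small_cohort.truth[small_cohort.truth.is_primary].head(12)
    fam_of = {g.gene_id: g.family_id for g in small_cohort.human_genes()}
    within, across = [], []
    for r in primary.itertuples():
        within.append((r.gene_a, r.gene_b))
    names = sorted({g for p in within for g in p})
    for a, b in itertools.combinations(names, 2):
        if fam_of[a] != fam_of[b]:
            across.append((a, b))
    hits = [
        align_proteins(proteins[a], proteins[b], ids=(a, b))
        for a, b in within + across[:20]
    ]
    pairs, _ = call_duplicates(hits)
    for a, b in within:
        pa, pb = proteins[a], proteins[b]
        identity = sum(x == y for x, y in zip(pa, pb)) / len(pa)
        if identity >= 0.35:
            assert tuple(sorted((a, b))) in pairs
    for a, b in across[:20]:
        assert tuple(sorted((a, b))) not in pairs
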