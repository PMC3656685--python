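"""Codon-level machinery shared by the selection estimator and the sequence
simulator: the standard genetic code, Nei–Gojobori site and pathway-count
tables, and a Goldman–Yang-style codon rate matrix.

Conventions (documented, configurable nowhere — they define the estimator):

* Site counting: at each codon position the three possible single-nucleotide
  changes are classified; changes producing a stop codon count as
  nonsynonymous, so synonymous + nonsynonymous site fractions always sum to 3
  per codon.
* Pathway counting for codons differing at >1 position: all orderings of the
  single changes are enumerated; orderings passing through a stop codon are
  discarded and counts are averaged over the remaining orderings.  In the
  (rare) case where every ordering passes through a stop, all orderings are
  used with the stop treated as an ordinary nonsynonymous state.
"""

from __future__ import annotations

import itertools
from typing import Dict, Tuple

import numpy as np
from Bio.Data import CodonTable
from scipy.linalg import expm

__all__ = [
    "CODONS",
    "SENSE_CODONS",
    "STOP_CODONS",
    "CODON_INDEX",
    "SYN_SITES",
    "NONSYN_SITES",
    "SD_TABLE",
    "ND_TABLE",
    "rate_matrix",
    "transition_matrix",
    "codons_to_indices",
    "indices_to_cds",
]

_BASES = "TCAG"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}

CODONS: Tuple[str, ...] = tuple(
    a + b + c for a in _BASES for b in _BASES for c in _BASES
)

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)
SENSE_CODONS: Tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)
CODON_INDEX: Dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}

# amino acid per codon, '*' for stops
_AA = {c: _STANDARD.forward_table.get(c, "*") for c in CODONS}

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}


def is_transition(x: str, y: str) -> bool:
    return (x in _PURINES and y in _PURINES) or (
        x in _PYRIMIDINES and y in _PYRIMIDINES
    )


def _single_changes(codon: str, pos: int):
    for base in "ACGT":
        if base != codon[pos]:
            yield codon[:pos] + base + codon[pos + 1 :]


def _syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        syn = sum(
            1 for alt in _single_changes(codon, pos) if _AA[alt] == _AA[codon]
        )
        total += syn / 3.0
    return total


SYN_SITES = np.array([_syn_sites(c) for c in SENSE_CODONS])
NONSYN_SITES = 3.0 - SYN_SITES


def _pathway_counts(a: str, b: str) -> Tuple[float, float]:
    """Average (nonsynonymous, synonymous) difference counts between two
    sense codons over all substitution orderings, excluding stop-passing
    orderings when possible."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    records = []  # (passes_stop, nd, sd)
    for order in itertools.permutations(diffs):
        cur = a
        nd = sd = 0
        passes_stop = False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                passes_stop = True
            if _AA[cur] == _AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        records.append((passes_stop, nd, sd))
    valid = [r for r in records if not r[0]]
    use = valid if valid else records
    nd = sum(r[1] for r in use) / len(use)
    sd = sum(r[2] for r in use) / len(use)
    return nd, sd


def _build_pair_tables() -> Tuple[np.ndarray, np.ndarray]:
    n = len(SENSE_CODONS)
    nd = np.zeros((n, n))
    sd = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j in range(i + 1, n):
            b = SENSE_CODONS[j]
            ndij, sdij = _pathway_counts(a, b)
            nd[i, j] = nd[j, i] = ndij
            sd[i, j] = sd[j, i] = sdij
    return nd, sd


ND_TABLE, SD_TABLE = _build_pair_tables()


# ---------------------------------------------------------------------------
# GY94-style codon substitution process (HKY nucleotide part, omega multiplier
# on nonsynonymous changes, stop codons excluded from the state space).
# ---------------------------------------------------------------------------

_Q_CACHE: Dict[Tuple[float, float], np.ndarray] = {}
_P_CACHE: Dict[Tuple[float, float, float], np.ndarray] = {}


def rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """61x61 rate matrix, scaled to one expected substitution per codon per
    unit time at the (uniform) stationary distribution."""
    key = (float(omega), float(kappa))
    cached = _Q_CACHE.get(key)
    if cached is not None:
        return cached
    n = len(SENSE_CODONS)
    q = np.zeros((n, n))
    for i, a in enumerate(SENSE_CODONS):
        for j, b in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if a[k] != b[k]]
            if len(diffs) != 1:
                continue
            pos = diffs[0]
            rate = kappa if is_transition(a[pos], b[pos]) else 1.0
            if _AA[a] != _AA[b]:
                rate *= omega
            q[i, j] = rate
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mean_rate = -np.diag(q).mean()
    if mean_rate > 0:
        q = q / mean_rate
    _Q_CACHE[key] = q
    return q


def transition_matrix(t: float, omega: float, kappa: float) -> np.ndarray:
    """P(t) = expm(Q t) for the scaled rate matrix; cached."""
    key = (round(float(t), 12), float(omega), float(kappa))
    cached = _P_CACHE.get(key)
    if cached is None:
        cached = expm(rate_matrix(omega, kappa) * t)
        # guard against tiny negative entries from the matrix exponential
        np.clip(cached, 0.0, None, out=cached)
        cached /= cached.sum(axis=1, keepdims=True)
        _P_CACHE[key] = cached
    return cached


_BASE_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(_BASES):
    _BASE_LUT[ord(_b)] = _i
    _BASE_LUT[ord(_b.lower())] = _i

_SENSE_OF_64 = np.full(64, -1, dtype=np.int64)
for _i, _c in enumerate(CODONS):
    if _c in CODON_INDEX:
        _SENSE_OF_64[_i] = CODON_INDEX[_c]

AA_BY_INDEX: Tuple[str, ...] = tuple(_AA[c] for c in SENSE_CODONS)


def codons_to_indices(cds: str) -> np.ndarray:
    """Map an in-frame CDS string to sense-codon indices; codons containing
    characters outside ACGT, and stop codons, map to -1."""
    arr = _BASE_LUT[np.frombuffer(cds.encode(), dtype=np.uint8)]
    n = len(arr) // 3
    arr = arr[: 3 * n].reshape(n, 3)
    bad = (arr < 0).any(axis=1)
    idx64 = arr[:, 0] * 16 + arr[:, 1] * 4 + arr[:, 2]
    idx64[bad] = 0
    out = _SENSE_OF_64[idx64]
    out[bad] = -1
    return out


def indices_to_cds(indices: np.ndarray) -> str:
    return "".join(map(SENSE_CODONS.__getitem__, indices))


def indices_to_protein(indices: np.ndarray) -> str:
    return "".join(map(AA_BY_INDEX.__getitem__, indices))


def translate_codon(codon: str) -> str:
    return _AA.get(codon.upper(), "X")
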