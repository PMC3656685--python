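"""Independent brute-force oracles used by the test suite.

Each oracle re-derives an expected value from first principles through a
different route than the package implementation: exhaustive dynamic
programming for local alignment, recursive pathway enumeration for NG86,
fixed-margin table enumeration for Fisher's exact test, rank-arrangement
enumeration for the Wilcoxon test, and log-factorial closed forms for the
hypergeometric group test.
"""

from __future__ import annotations

import functools
import itertools
from math import exp, lgamma

import numpy as np
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# exhaustive affine-gap Smith-Waterman (local) score
# ---------------------------------------------------------------------------


def sw_local_score(a: str, b: str, matrix, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score; a gap of length L costs open + L*extend."""
    neg = -1e18
    n, m = len(a), len(b)
    h = np.zeros((n + 1, m + 1))
    e = np.full((n + 1, m + 1), neg)  # gap in a (consuming b)
    f = np.full((n + 1, m + 1), neg)  # gap in b (consuming a)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e[i][j] = max(
                h[i][j - 1] - gap_open - gap_extend, e[i][j - 1] - gap_extend
            )
            f[i][j] = max(
                h[i - 1][j] - gap_open - gap_extend, f[i - 1][j] - gap_extend
            )
            s = matrix[a[i - 1], b[j - 1]]
            h[i][j] = max(0.0, h[i - 1][j - 1] + s, e[i][j], f[i][j])
            best = max(best, h[i][j])
    return best


# ---------------------------------------------------------------------------
# NG86 pathway-enumeration oracle
# ---------------------------------------------------------------------------

_STOPS = {"TAA", "TAG", "TGA"}


@functools.lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_sites_oracle(codon: str) -> float:
    """Synonymous site count of one codon; stop-creating changes count as
    nonsynonymous."""
    total = 0.0
    for pos in range(3):
        syn = 0
        for base in "ACGT":
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if alt not in _STOPS and _aa(alt) == _aa(codon):
                syn += 1
        total += syn / 3.0
    return total


def pathway_counts_oracle(a: str, b: str) -> tuple[float, float]:
    """Average (nd, sd) over substitution orderings between two sense
    codons; orderings through stops dropped when any stop-free ordering
    exists."""
    diffs = [k for k in range(3) if a[k] != b[k]]
    if not diffs:
        return 0.0, 0.0
    clean, dirty = [], []
    for order in itertools.permutations(diffs):
        cur, nd, sd, stopped = a, 0, 0, False
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                stopped = True
            if _aa(cur) == _aa(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        (dirty if stopped else clean).append((nd, sd))
    use = clean if clean else dirty
    return (
        sum(r[0] for r in use) / len(use),
        sum(r[1] for r in use) / len(use),
    )


def ng86_oracle(cds_a: str, cds_b: str) -> dict:
    """NG86 from scratch: per-codon site averages, pathway-averaged
    differences, Jukes-Cantor correction."""
    assert len(cds_a) == len(cds_b) and len(cds_a) % 3 == 0
    s_sites = n_sites = nd = sd = 0.0
    n_codons = 0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        if set(ca + cb) - set("ACGT") or ca in _STOPS or cb in _STOPS:
            continue
        n_codons += 1
        s_sites += (syn_sites_oracle(ca) + syn_sites_oracle(cb)) / 2.0
        nd_i, sd_i = pathway_counts_oracle(ca, cb)
        nd += nd_i
        sd += sd_i
    n_sites = 3.0 * n_codons - s_sites

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * np.log1p(-4 * p / 3)

    return {
        "dn": jc(nd / n_sites) if n_sites else float("nan"),
        "ds": jc(sd / s_sites) if s_sites else float("nan"),
        "n_sites": n_sites,
        "s_sites": s_sites,
        "nd": nd,
        "sd": sd,
    }


# ---------------------------------------------------------------------------
# exact-test oracles
# ---------------------------------------------------------------------------


def _log_binom(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def fisher_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by enumerating all tables with the observed
    margins (probability-mass rule, 1e-7 relative tie tolerance)."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = [
        exp(_log_binom(r1, k) + _log_binom(n - r1, c1 - k) - _log_binom(n, c1))
        for k in range(lo, hi + 1)
    ]
    p_obs = probs[a - lo]
    return min(1.0, sum(p for p in probs if p <= p_obs * (1 + 1e-7)))


def wilcoxon_exact_oracle(x, y, alternative: str = "two-sided") -> float:
    """Exact Mann-Whitney p by enumerating every assignment of pooled ranks
    (requires no ties)."""
    x, y = list(x), list(y)
    n, m = len(x), len(y)
    pooled = sorted(x + y)
    assert len(set(pooled)) == len(pooled), "oracle requires no ties"
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    u_obs = sum(ranks[v] for v in x) - n * (n + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + m + 1), n):
        us.append(sum(combo) - n * (n + 1) / 2)
    total = len(us)
    ge = sum(1 for u in us if u >= u_obs) / total
    le = sum(1 for u in us if u <= u_obs) / total
    if alternative == "greater":
        return ge
    if alternative == "less":
        return le
    return min(1.0, 2.0 * min(ge, le))


def hypergeom_term_oracle(K: int, q: int) -> float:
    """P(X = q) for X ~ Hypergeom(2K, K, K): C(K,q)*C(K,K-q)/C(2K,K)."""
    return exp(2 * _log_binom(K, q) - _log_binom(2 * K, K))
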