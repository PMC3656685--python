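"""Pairwise selection estimates: Nei–Gojobori (1986) dN/dS.

The estimator works on codon-aligned, gap-free CDS pairs.  Synonymous and
nonsynonymous site fractions are counted per codon and averaged over the two
sequences; difference counts for codons differing at more than one position
are averaged over substitution pathways (stop-passing pathways excluded); the
Jukes–Cantor correction turns proportions into distances.  See
:mod:`dupred.codon` for the exact counting conventions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import codon as _codon
from .errors import ValidationError

__all__ = ["CodonAlignmentPair", "SelectionEstimate", "ng86", "dn_group_compare"]


@dataclass(frozen=True)
class CodonAlignmentPair:
    """Two equal-length, in-frame, gap-free coding sequences."""

    cds_a: str
    cds_b: str

    def validate(self) -> None:
        a, b = self.cds_a.upper(), self.cds_b.upper()
        if len(a) != len(b):
            raise ValidationError(
                f"unequal CDS lengths ({len(a)} vs {len(b)})"
            )
        if len(a) % 3 != 0:
            raise ValidationError(f"CDS length {len(a)} is not a multiple of 3")
        n_codons = len(a) // 3
        for seq, label in ((a, "cds_a"), (b, "cds_b")):
            for i in range(n_codons):
                cod = seq[3 * i : 3 * i + 3]
                if cod in _codon.STOP_CODONS and i < n_codons - 1:
                    raise ValidationError(
                        f"internal stop codon {cod} at codon {i} in {label}"
                    )


@dataclass(frozen=True)
class SelectionEstimate:
    """NG86 output.  ``dn``/``ds`` are ``nan`` when the Jukes–Cantor
    correction is undefined (proportion >= 3/4)."""

    dn: float
    ds: float
    n_sites: float
    s_sites: float
    nd: float
    sd: float

    @property
    def omega(self) -> float:
        if self.ds and not math.isnan(self.ds) and not math.isnan(self.dn):
            return self.dn / self.ds
        return math.nan


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(pair: CodonAlignmentPair | tuple[str, str]) -> SelectionEstimate:
    """Nei–Gojobori (1986) estimate of dN and dS for one CDS pair.

    Codons containing ambiguity characters (anything outside ACGT) in either
    sequence are skipped; a terminal stop codon pair is skipped as well.
    """
    if not isinstance(pair, CodonAlignmentPair):
        pair = CodonAlignmentPair(*pair)
    pair.validate()

    ia = _codon.codons_to_indices(pair.cds_a)
    ib = _codon.codons_to_indices(pair.cds_b)
    keep = (ia >= 0) & (ib >= 0)
    ia, ib = ia[keep], ib[keep]
    n_codons = len(ia)
    if n_codons == 0:
        raise ValidationError("no countable codons in pair")

    s_sites = 0.5 * (_codon.SYN_SITES[ia].sum() + _codon.SYN_SITES[ib].sum())
    n_sites = 3.0 * n_codons - s_sites
    nd = _codon.ND_TABLE[ia, ib].sum()
    sd = _codon.SD_TABLE[ia, ib].sum()

    pn = nd / n_sites if n_sites > 0 else math.nan
    ps = sd / s_sites if s_sites > 0 else math.nan
    return SelectionEstimate(
        dn=_jukes_cantor(pn) if not math.isnan(pn) else math.nan,
        ds=_jukes_cantor(ps) if not math.isnan(ps) else math.nan,
        n_sites=float(n_sites),
        s_sites=float(s_sites),
        nd=float(nd),
        sd=float(sd),
    )


def dn_group_compare(
    dn_a: Sequence[float],
    dn_b: Sequence[float],
    alternative: str = "two-sided",
) -> dict:
    """Wilcoxon rank-sum comparison of two dN samples (missing values
    dropped), with group medians.  Group A first (e.g. MD), group B second."""
    from .stats import wilcoxon_rank_sum  # local import avoids a cycle

    a = np.asarray([v for v in dn_a if v is not None and not math.isnan(v)])
    b = np.asarray([v for v in dn_b if v is not None and not math.isnan(v)])
    if a.size == 0 or b.size == 0:
        raise ValidationError("dn_group_compare requires >=1 valid dN per group")
    stat, p = wilcoxon_rank_sum(a, b, alternative=alternative)
    return {
        "statistic": stat,
        "p": p,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
    }
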