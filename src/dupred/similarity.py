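"""Paralog functional-similarity metrics.

Four metrics are computed per gene/closest-paralog pair: tissue co-expression
(Pearson r), protein sequence identity (from the duplication module), GO
semantic similarity (Wang graph-based term similarity combined by best-match
average, restricted to leaf terms of one namespace), and the fraction of
shared protein-protein interaction partners.

The GO similarity is additionally *normalized* against the annotation-depth
bias: better-annotated genes carry more terms and systematically score lower,
so the raw score is rescaled by how close the pair's maximal term count comes
to the cohort-wide maximum.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "GoDag",
    "load_obo",
    "pearson_coexpression",
    "wang_term_similarity",
    "gene_go_similarity",
    "normalized_go_similarity",
    "shared_interaction_fraction",
    "annotation_bias_check",
]

MOLECULAR_FUNCTION = "molecular_function"


class GoDag:
    """A Gene Ontology DAG restricted to ``is_a`` edges.

    ``parents`` maps a term to its direct ``is_a`` parents; ``namespace``
    maps a term to its ontology namespace.  Leaf terms are terms without an
    ``is_a`` child *within the same namespace* of the loaded DAG (and are
    therefore DAG-version dependent).
    """

    def __init__(
        self,
        parents: Mapping[str, Iterable[str]],
        namespace: Mapping[str, str],
        names: Optional[Mapping[str, str]] = None,
    ):
        self.parents: dict[str, tuple[str, ...]] = {
            t: tuple(sorted(set(ps))) for t, ps in parents.items()
        }
        self.namespace = dict(namespace)
        self.names = dict(names or {})
        for term, ps in self.parents.items():
            for p in ps:
                if p not in self.parents:
                    raise ValidationError(
                        f"term {term} has unknown parent {p}"
                    )
        self._children: dict[str, set[str]] = {t: set() for t in self.parents}
        for term, ps in self.parents.items():
            for p in ps:
                self._children[p].add(term)
        self._svalue_cache: dict[tuple[str, float], dict[str, float]] = {}
        self._termsim_cache: dict[tuple[str, str, float], float] = {}

    def __contains__(self, term: str) -> bool:
        return term in self.parents

    def terms(self) -> list[str]:
        return sorted(self.parents)

    def is_leaf(self, term: str) -> bool:
        ns = self.namespace.get(term)
        return not any(
            self.namespace.get(c) == ns for c in self._children.get(term, ())
        )

    def leaves(self, namespace: Optional[str] = None) -> list[str]:
        return [
            t
            for t in sorted(self.parents)
            if self.is_leaf(t)
            and (namespace is None or self.namespace.get(t) == namespace)
        ]

    def filter_terms(
        self,
        terms: Iterable[str],
        namespace: Optional[str] = MOLECULAR_FUNCTION,
        leaf_only: bool = True,
    ) -> set[str]:
        out = set()
        for t in terms:
            if t not in self.parents:
                continue
            if namespace is not None and self.namespace.get(t) != namespace:
                continue
            if leaf_only and not self.is_leaf(t):
                continue
            out.add(t)
        return out

    def svalues(self, term: str, w: float = 0.8) -> dict[str, float]:
        """Wang S-values: semantic contribution of each ancestor of ``term``
        (including itself), S(term) = 1 and each ``is_a`` step multiplies by
        ``w``, taking the maximum over paths."""
        key = (term, w)
        cached = self._svalue_cache.get(key)
        if cached is not None:
            return cached
        if term not in self.parents:
            raise KeyError(f"unknown GO term {term}")
        s: dict[str, float] = {term: 1.0}
        frontier = [term]
        while frontier:
            nxt: list[str] = []
            for t in frontier:
                contrib = s[t] * w
                for p in self.parents[t]:
                    if contrib > s.get(p, 0.0):
                        s[p] = contrib
                        nxt.append(p)
            frontier = nxt
        self._svalue_cache[key] = s
        return s


def load_obo(path) -> GoDag:
    """Load an OBO file (``is_a`` edges, namespaces) into a :class:`GoDag`.

    Parsing is delegated to :mod:`obonet`; obsolete terms are dropped by the
    parser, ``alt_id``s are ignored.
    """
    import obonet

    graph = obonet.read_obo(path)
    parents: dict[str, set[str]] = {}
    namespace: dict[str, str] = {}
    names: dict[str, str] = {}
    for node, data in graph.nodes(data=True):
        parents.setdefault(node, set())
        namespace[node] = data.get("namespace", "")
        names[node] = data.get("name", "")
        for parent in data.get("is_a", []):
            parents[node].add(parent)
            parents.setdefault(parent, set())
    return GoDag(parents, namespace, names)


def pearson_coexpression(
    expr_a: Sequence[float], expr_b: Sequence[float]
) -> float:
    """Pearson correlation of two expression profiles over tissues.

    Missing tissues (``nan``) are dropped pairwise; returns ``nan`` when
    fewer than 3 complete pairs remain or a profile has zero variance.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("expression vectors differ in length")
    if a.size < 3:
        raise ValidationError("expression vectors must have length >= 3")
    keep = np.isfinite(a) & np.isfinite(b)
    a, b = a[keep], b[keep]
    if a.size < 3 or np.std(a) == 0 or np.std(b) == 0:
        return math.nan
    return float(np.corrcoef(a, b)[0, 1])


def wang_term_similarity(
    term_a: str, term_b: str, dag: GoDag, w: float = 0.8
) -> float:
    """Wang et al. graph-based similarity between two GO terms."""
    key = (term_a, term_b) if term_a <= term_b else (term_b, term_a)
    cached = dag._termsim_cache.get((*key, w))
    if cached is not None:
        return cached
    sa = dag.svalues(term_a, w)
    sb = dag.svalues(term_b, w)
    common = sa.keys() & sb.keys()
    if common:
        sim = sum(sa[t] + sb[t] for t in common) / (
            sum(sa.values()) + sum(sb.values())
        )
    else:
        sim = 0.0
    dag._termsim_cache[(*key, w)] = sim
    return sim


def gene_go_similarity(
    terms_a: Iterable[str],
    terms_b: Iterable[str],
    dag: GoDag,
    namespace: Optional[str] = MOLECULAR_FUNCTION,
    leaf_only: bool = True,
    w: float = 0.8,
) -> float:
    """Best-match-average Wang similarity between two genes' GO term sets.

    Term sets are first restricted to leaf terms of ``namespace``; if either
    gene retains no term the pair is unscorable and ``nan`` is returned
    (mirroring the exclusion of unannotated genes from the analysis).
    """
    fa = sorted(dag.filter_terms(terms_a, namespace, leaf_only))
    fb = sorted(dag.filter_terms(terms_b, namespace, leaf_only))
    if not fa or not fb:
        return math.nan
    matrix = np.array(
        [[wang_term_similarity(ta, tb, dag, w) for tb in fb] for ta in fa]
    )
    best_a = matrix.max(axis=1)
    best_b = matrix.max(axis=0)
    return float((best_a.sum() + best_b.sum()) / (len(fa) + len(fb)))


def normalized_go_similarity(
    raw: float, x: int, min_terms: int, max_terms: int
) -> float:
    """Depth-normalized GO similarity.

    ``x`` is the larger of the two genes' term counts in the pair;
    ``min_terms``/``max_terms`` are the smallest and largest per-gene term
    counts in the whole cohort.  The raw score is scaled by
    ``(x - min_terms + 1) / (max_terms - min_terms + 1)`` (the ``+1`` avoids
    zeros), which is strictly increasing in ``x`` and leaves the score
    untouched at ``x == max_terms``.
    """
    if math.isnan(raw):
        return math.nan
    if not (min_terms <= x <= max_terms):
        raise ValidationError(
            f"x={x} outside cohort term-count range [{min_terms}, {max_terms}]"
        )
    return raw * (x - min_terms + 1) / (max_terms - min_terms + 1)


def shared_interaction_fraction(
    partners_a: Iterable[str],
    partners_b: Iterable[str],
    pair: Optional[tuple[str, str]] = None,
    exclude_pair: bool = True,
    method: str = "jaccard",
) -> float:
    """Fraction of shared protein-interaction partners of a gene pair.

    Default is the Jaccard index |A∩B| / |A∪B|; ``method='min'`` uses
    |A∩B| / min(|A|, |B|).  With ``exclude_pair`` the two pair members are
    removed from each other's partner sets first.  Returns ``nan`` when the
    union (or the smaller set) is empty.
    """
    a = set(partners_a)
    b = set(partners_b)
    if exclude_pair and pair is not None:
        ga, gb = pair
        a.discard(gb)
        a.discard(ga)
        b.discard(ga)
        b.discard(gb)
    inter = len(a & b)
    if method == "jaccard":
        denom = len(a | b)
    elif method == "min":
        denom = min(len(a), len(b))
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom == 0:
        return math.nan
    return inter / denom


def annotation_bias_check(
    md_genes: Iterable[str],
    nd_genes: Iterable[str],
    go_annotations: Mapping[str, Iterable[str]],
    dag: Optional[GoDag] = None,
    namespace: Optional[str] = MOLECULAR_FUNCTION,
    leaf_only: bool = True,
) -> dict:
    """Compare per-gene GO term counts between disease and non-disease genes.

    Returns the two count distributions plus a Wilcoxon rank-sum comparison;
    genes absent from the annotation map count zero terms.
    """
    from .stats import wilcoxon_rank_sum

    def counts(genes) -> list[int]:
        out = []
        for g in genes:
            terms = go_annotations.get(g, ())
            if dag is not None:
                terms = dag.filter_terms(terms, namespace, leaf_only)
            out.append(len(set(terms)))
        return out

    md_counts = counts(md_genes)
    nd_counts = counts(nd_genes)
    if not md_counts or not nd_counts:
        raise ValidationError("annotation_bias_check requires non-empty groups")
    stat, p = wilcoxon_rank_sum(md_counts, nd_counts)
    return {
        "md_counts": md_counts,
        "nd_counts": nd_counts,
        "statistic": stat,
        "p": p,
        "md_mean": float(np.mean(md_counts)),
        "nd_mean": float(np.mean(nd_counts)),
    }
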