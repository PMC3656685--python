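"""Duplication dating by gene-tree → species-tree LCA mapping.

For a pair of paralogs, the species spanned by the clade under their
gene-tree LCA are mapped onto the species tree; the species-tree LCA of that
species set is the node where the duplication is placed, and the duplication
age is the sum of branch lengths from that node down to the focal-species
leaf.  Duplicates dated to the early-vertebrate window between the
focal–Ciona and focal–teleost splits are flagged as whole-genome-duplication
(WGD) candidates.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Optional

from .errors import ValidationError
from .trees import PhyloTree, TreeNode

__all__ = [
    "DuplicationAge",
    "species_from_leaf",
    "date_duplication",
    "classify_wgd",
    "most_recent_duplication_age",
    "filter_families",
]

_DEFAULT_SPECIES_RE = re.compile(r"_([^_]+)$")


def species_from_leaf(leaf_name: str, pattern: re.Pattern = _DEFAULT_SPECIES_RE) -> str:
    """Extract the species from a gene-tree leaf name.

    The default convention is ``GENEID_species``: the substring after the
    last underscore, lowercased.
    """
    m = pattern.search(leaf_name)
    if not m:
        raise ValidationError(
            f"cannot extract species from leaf name {leaf_name!r}"
        )
    return m.group(1).lower()


@dataclass(frozen=True)
class DuplicationAge:
    """A dated duplication event for one paralog pair."""

    pair: tuple[str, str]
    species_node: str  # label of the species-tree node (leaf name if a leaf)
    age: float  # branch-length sum from that node to the focal leaf
    is_wgd: Optional[bool] = None


class _SpeciesIndex:
    """Cached lookups on one species tree: lowercase leaf map and node ages
    relative to the focal leaf."""

    def __init__(self, tree: PhyloTree, focal_species: str):
        self.tree = tree
        self.focal_species = focal_species.lower()
        self.leaf_by_species = {
            leaf.name.lower(): leaf for leaf in tree.root.leaves()
        }
        if self.focal_species not in self.leaf_by_species:
            raise ValidationError(
                f"focal species {focal_species!r} not in species tree"
            )
        self.focal_leaf = self.leaf_by_species[self.focal_species]
        # age of every node on the root-to-focal path
        self.age_by_id: dict[int, float] = {}
        age = 0.0
        node: Optional[TreeNode] = self.focal_leaf
        while node is not None:
            self.age_by_id[id(node)] = age
            age += node.length or 0.0
            node = node.parent

    def node_age(self, node: TreeNode) -> float:
        try:
            return self.age_by_id[id(node)]
        except KeyError:
            raise ValidationError(
                f"species-tree node {node.name!r} is not an ancestor of the "
                f"focal species {self.focal_species!r}"
            ) from None

    def split_age(self, other_species: str) -> float:
        other = other_species.lower()
        if other not in self.leaf_by_species:
            raise ValidationError(
                f"species {other_species!r} not in species tree"
            )
        lca = self.tree.lca([self.focal_leaf, self.leaf_by_species[other]])
        return self.node_age(lca)


def _species_index(tree: PhyloTree, focal_species: str) -> _SpeciesIndex:
    cache = getattr(tree, "_dupred_species_index", None)
    if cache is None or cache.focal_species != focal_species.lower():
        cache = _SpeciesIndex(tree, focal_species)
        tree._dupred_species_index = cache
    return cache


def date_duplication(
    gene_tree: PhyloTree,
    gene_a: str,
    gene_b: str,
    species_tree: PhyloTree,
    focal_species: str = "human",
    species_fn: Callable[[str], str] = species_from_leaf,
) -> DuplicationAge:
    """Date the duplication event separating two gene-tree leaves.

    Both genes must be leaves of ``gene_tree``; every species spanned by
    their gene-tree LCA clade must exist in ``species_tree``, and the focal
    species must be among them.
    """
    try:
        leaf_a = gene_tree.leaf(gene_a)
        leaf_b = gene_tree.leaf(gene_b)
    except KeyError as exc:
        raise ValidationError(str(exc)) from exc

    gene_lca = gene_tree.lca([leaf_a, leaf_b])
    clade_species = {species_fn(leaf.name) for leaf in gene_lca.leaves()}

    index = _species_index(species_tree, focal_species)
    if index.focal_species not in clade_species:
        raise ValidationError(
            f"focal species {focal_species!r} not under the gene-tree LCA of "
            f"({gene_a}, {gene_b})"
        )
    missing = sorted(clade_species - index.leaf_by_species.keys())
    if missing:
        raise ValidationError(
            f"species missing from species tree: {missing}"
        )
    species_nodes = [index.leaf_by_species[s] for s in sorted(clade_species)]
    species_lca = species_tree.lca(species_nodes)
    age = index.node_age(species_lca)
    label = species_lca.name or f"node@{age:g}"
    pair = tuple(sorted((gene_a, gene_b)))
    return DuplicationAge(pair=pair, species_node=label, age=age)


def classify_wgd(
    age: float | DuplicationAge,
    species_tree: PhyloTree,
    lower_species: str = "takifugu",
    upper_species: str = "ciona",
    focal_species: str = "human",
    include_lower: bool = False,
    include_upper: bool = False,
) -> bool:
    """Is a duplication age inside the whole-genome-duplication window?

    The window runs from the focal–``lower_species`` split (teleost fishes)
    to the focal–``upper_species`` split (Ciona).  Boundary handling is
    configurable; the default is the open interval on both sides.
    """
    if isinstance(age, DuplicationAge):
        age = age.age
    index = _species_index(species_tree, focal_species)
    lower = index.split_age(lower_species)
    upper = index.split_age(upper_species)
    if lower >= upper:
        raise ValidationError(
            f"WGD window is empty: split({lower_species})={lower} >= "
            f"split({upper_species})={upper}"
        )
    above_lower = age >= lower if include_lower else age > lower
    below_upper = age <= upper if include_upper else age < upper
    return bool(above_lower and below_upper)


def most_recent_duplication_age(
    gene: str,
    dated_pairs: Iterable[DuplicationAge],
) -> float:
    """Minimum duplication age over all dated pairs containing ``gene``."""
    ages = [d.age for d in dated_pairs if gene in d.pair]
    if not ages:
        raise ValidationError(f"gene {gene} has no dated paralog pair")
    return min(ages)


def filter_families(
    families: Mapping[str, PhyloTree | Iterable[str]],
    min_species: int = 4,
    require_focal: bool = True,
    focal_species: str = "human",
    species_fn: Callable[[str], str] = species_from_leaf,
) -> list[str]:
    """Keep families with a focal-species gene and enough distinct species.

    ``families`` maps a family id either to its gene tree or to an iterable
    of leaf names.  Returns the retained family ids, in input order.
    """
    kept = []
    focal = focal_species.lower()
    for fam_id, family in families.items():
        if isinstance(family, PhyloTree):
            leaf_names = family.leaf_names()
        else:
            leaf_names = list(family)
        species = {species_fn(name) for name in leaf_names}
        if require_focal and focal not in species:
            continue
        if len(species) < min_species:
            continue
        kept.append(fam_id)
    return kept
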