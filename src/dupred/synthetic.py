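"""Synthetic cohort generator.

Builds a fully labeled cohort with the statistical structure the analysis
assumes: gene families with duplication events placed at known species-tree
nodes, disease labels, paralog pairs whose co-expression, GO-term overlap,
PPI-partner overlap and coding-sequence divergence differ between
disease-containing (MD) and non-disease (ND) pairs by configurable effect
sizes, plus protein-complex memberships and ortholog dN draws.  Every paralog
pair carries a truth record (generating node, age, effect class), so each
downstream stage can be scored against known ground truth.

The species tree fixture is a 12-leaf vertebrate tree (human, chimp,
macaque, mouse, rat, dog, opossum, chicken, frog, takifugu, zebrafish,
ciona) with ultrametric branch lengths in million-year units, covering the
whole-genome-duplication window between the human-teleost and human-Ciona
splits.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import codon as _codon
from .duplication import GeneRecord
from .errors import ConfigError
from .similarity import GoDag
from .trees import PhyloTree, TreeNode

__all__ = [
    "SPECIES_TREE_NEWICK",
    "CohortConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "evolve_cds_pair",
    "simulate_expression_pair",
    "build_go_dag",
]

# Ultrametric 12-species tree; node ages on the human path (Myr):
# human 0, human_chimp 6, primates 29, euarchontoglires 90, boreoeutheria 97,
# theria 160, amniota 320, tetrapoda 360, euteleostomi 450, chordata 600.
SPECIES_TREE_NEWICK = (
    "(((((((((human:6,chimp:6)human_chimp:23,macaque:29)primates:61,"
    "(mouse:20,rat:20)murinae:70)euarchontoglires:7,dog:97)boreoeutheria:63,"
    "opossum:160)theria:160,chicken:320)amniota:40,frog:360)tetrapoda:90,"
    "(takifugu:230,zebrafish:230)teleostei:220)euteleostomi:150,ciona:600)"
    "chordata;"
)

GO_MF_ROOT = "GO:0003674"
GO_BP_ROOT = "GO:0008150"


@dataclass
class CohortConfig:
    """All generation parameters.

    Effect-size pairs (``*_md`` vs ``*_nd``) control how disease-containing
    paralog pairs differ from non-disease pairs; setting them equal yields a
    null cohort.
    """

    n_families: int = 200
    n_singletons: int = 100
    p_disease: float = 0.2
    p_disease_singleton: float = 0.15
    p_polygenic: float = 0.05
    n_tissues: int = 36
    rho_md: float = 0.4
    rho_nd: float = 0.2
    go_terms_per_gene: Tuple[int, int] = (1, 10)
    go_overlap_md: float = 0.5
    go_overlap_nd: float = 0.3
    n_go_leaf_terms: int = 150
    ppi_degree: float = 12.0
    ppi_overlap_md: float = 0.4
    ppi_overlap_nd: float = 0.2
    dnds_md: float = 0.1
    dnds_nd: float = 0.3
    kappa: float = 2.0
    cds_length_codons: int = 300
    cds_rate_per_age: float = 5e-4  # substitutions/codon/Myr per lineage
    cds_t_floor: float = 0.02  # minimum pair divergence (age-0 duplicates)
    p_nested_duplication: float = 0.1
    complex_comember_md: float = 0.10
    complex_comember_nd: float = 0.18
    p_complex_membership: float = 0.3
    n_complexes: int = 40
    ortholog_dn_mean_md: float = 0.04
    ortholog_dn_mean_nd: float = 0.07
    ortholog_dn_singleton_factor: float = 1.4
    ortholog_dn_shape: float = 2.0
    dup_node_weights: Optional[Dict[str, float]] = None
    species_tree_newick: str = SPECIES_TREE_NEWICK
    focal_species: str = "human"
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "p_disease": self.p_disease,
            "p_disease_singleton": self.p_disease_singleton,
            "p_polygenic": self.p_polygenic,
            "go_overlap_md": self.go_overlap_md,
            "go_overlap_nd": self.go_overlap_nd,
            "ppi_overlap_md": self.ppi_overlap_md,
            "ppi_overlap_nd": self.ppi_overlap_nd,
            "p_nested_duplication": self.p_nested_duplication,
            "complex_comember_md": self.complex_comember_md,
            "complex_comember_nd": self.complex_comember_nd,
            "p_complex_membership": self.p_complex_membership,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0,1], got {p}")
        for name, rho in (("rho_md", self.rho_md), ("rho_nd", self.rho_nd)):
            if not -1.0 <= rho <= 1.0:
                raise ConfigError(f"{name} must be in [-1,1], got {rho}")
        for name, w in (("dnds_md", self.dnds_md), ("dnds_nd", self.dnds_nd)):
            if w <= 0:
                raise ConfigError(f"{name} must be > 0, got {w}")
        if self.kappa <= 0:
            raise ConfigError(f"kappa must be > 0, got {self.kappa}")
        if self.n_tissues < 3:
            raise ConfigError(f"n_tissues must be >= 3, got {self.n_tissues}")
        if self.n_families < 1:
            raise ConfigError("n_families must be >= 1")
        if self.n_singletons < 0:
            raise ConfigError("n_singletons must be >= 0")
        lo, hi = self.go_terms_per_gene
        if not (1 <= lo <= hi):
            raise ConfigError(
                f"go_terms_per_gene must be a 1<=lo<=hi range, got {lo, hi}"
            )
        if hi > self.n_go_leaf_terms:
            raise ConfigError("go_terms_per_gene upper bound exceeds term pool")
        if self.cds_length_codons < 10:
            raise ConfigError("cds_length_codons must be >= 10")
        if not self.species_tree_newick.strip():
            raise ConfigError("empty species tree")
        if self.dup_node_weights is not None:
            total = sum(self.dup_node_weights.values())
            if any(w < 0 for w in self.dup_node_weights.values()):
                raise ConfigError("dup_node_weights must be non-negative")
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(
                    f"dup_node_weights must sum to 1, got {total}"
                )

    # -- serialization ----------------------------------------------------

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["go_terms_per_gene"] = list(self.go_terms_per_gene)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown cohort config keys: {sorted(unknown)}")
        if "go_terms_per_gene" in data:
            data = dict(data)
            data["go_terms_per_gene"] = tuple(data["go_terms_per_gene"])
        config = cls(**data)
        config.validate()
        return config


@dataclass
class SyntheticCohort:
    """One generated cohort: all data layers plus the truth table."""

    config: CohortConfig
    genes: List[GeneRecord]
    gene_trees: Dict[str, PhyloTree]  # family id -> gene tree
    species_tree: PhyloTree
    expression: pd.DataFrame  # human genes x tissues
    go_annotations: Dict[str, set]
    go_dag: GoDag
    ppi: Dict[str, set]  # adjacency over gene ids
    complexes: Dict[str, set]  # complex id -> gene ids
    ortholog_dn: pd.DataFrame
    truth: pd.DataFrame

    def human_genes(self) -> List[GeneRecord]:
        focal = self.config.focal_species
        return [g for g in self.genes if g.species == focal]

    def labels(self) -> Dict[str, str]:
        return {g.gene_id: g.disease_label for g in self.human_genes()}

    # -- writers ----------------------------------------------------------

    def write(self, outdir) -> None:
        """Write every layer as plain text (FASTA/Newick/TSV/OBO/YAML)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        (out / "species_tree.nwk").write_text(self.species_tree.to_newick() + "\n")
        with open(out / "gene_trees.nwk", "w") as fh:
            for fam_id in sorted(self.gene_trees):
                fh.write(self.gene_trees[fam_id].to_newick() + "\n")

        humans = self.human_genes()
        with open(out / "proteins.fasta", "w") as fh:
            for g in humans:
                if g.protein_seq:
                    fh.write(f">{g.gene_id}\n{g.protein_seq}\n")
        with open(out / "cds.fasta", "w") as fh:
            for g in humans:
                if g.cds_seq:
                    fh.write(f">{g.gene_id}\n{g.cds_seq}\n")

        self.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.6f")

        with open(out / "labels.tsv", "w") as fh:
            for g in humans:
                fh.write(f"{g.gene_id}\t{g.disease_label}\n")

        with open(out / "go_annotations.tsv", "w") as fh:
            for gene in sorted(self.go_annotations):
                for term in sorted(self.go_annotations[gene]):
                    fh.write(f"{gene}\t{term}\n")

        _write_obo(self.go_dag, out / "go_dag.obo")

        with open(out / "ppi.tsv", "w") as fh:
            edges = set()
            for gene in sorted(self.ppi):
                for partner in sorted(self.ppi[gene]):
                    edges.add(tuple(sorted((gene, partner))))
            for a, b in sorted(edges):
                fh.write(f"{a}\t{b}\n")

        with open(out / "complexes.tsv", "w") as fh:
            for cpx in sorted(self.complexes):
                for gene in sorted(self.complexes[cpx]):
                    fh.write(f"{cpx}\t{gene}\n")

        self.ortholog_dn.to_csv(out / "ortholog_dn.tsv", sep="\t", index=False)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        self.config.to_yaml(out / "cohort_config.yaml")


# ---------------------------------------------------------------------------
# GO DAG fixture
# ---------------------------------------------------------------------------


def build_go_dag(n_leaf_terms: int = 150) -> GoDag:
    """Deterministic synthetic GO DAG (is_a edges only).

    A molecular_function namespace with a two-level hierarchy under the
    root (broad activity classes, narrower subclasses) and ``n_leaf_terms``
    leaves, some with two parents — deep and wide enough that two random
    leaf terms are usually semantically distant, as in the real molecular
    function ontology.  A tiny biological_process branch exercises namespace
    filtering.  Term ids use a reserved synthetic GO:7xxxxxx range.
    """
    parents: Dict[str, set] = {GO_MF_ROOT: set(), GO_BP_ROOT: set()}
    namespace = {GO_MF_ROOT: "molecular_function", GO_BP_ROOT: "biological_process"}
    names = {GO_MF_ROOT: "molecular_function", GO_BP_ROOT: "biological_process"}
    n_mids = max(4, n_leaf_terms // 25)
    mids, submids = [], []
    for i in range(n_mids):
        term = f"GO:{7000001 + i}"
        mids.append(term)
        parents[term] = {GO_MF_ROOT}
        namespace[term] = "molecular_function"
        names[term] = f"synthetic activity class {i + 1}"
        for j in range(2):
            sub = f"GO:{7050001 + 2 * i + j}"
            submids.append(sub)
            parents[sub] = {term}
            namespace[sub] = "molecular_function"
            names[sub] = f"synthetic activity subclass {2 * i + j + 1}"
    for i in range(n_leaf_terms):
        term = f"GO:{7100001 + i}"
        ps = {submids[i % len(submids)]}
        if i % 5 == 0:
            ps.add(submids[(i // 5) % len(submids)])
        parents[term] = ps
        namespace[term] = "molecular_function"
        names[term] = f"synthetic leaf activity {i + 1}"
    for i in range(3):
        term = f"GO:{7200001 + i}"
        parents[term] = {GO_BP_ROOT}
        namespace[term] = "biological_process"
        names[term] = f"synthetic process {i + 1}"
    return GoDag(parents, namespace, names)


def _write_obo(dag: GoDag, path) -> None:
    lines = ["format-version: 1.2", ""]
    for term in dag.terms():
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: {dag.names.get(term, term)}")
        lines.append(f"namespace: {dag.namespace.get(term, '')}")
        for parent in dag.parents[term]:
            lines.append(f"is_a: {parent} ! {dag.names.get(parent, parent)}")
        lines.append("")
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------

_CUM_CACHE: Dict[Tuple[float, float, float], np.ndarray] = {}


def _cum_transition(t: float, omega: float, kappa: float) -> np.ndarray:
    key = (round(float(t), 12), float(omega), float(kappa))
    cum = _CUM_CACHE.get(key)
    if cum is None:
        cum = np.cumsum(_codon.transition_matrix(t, omega, kappa), axis=1)
        _CUM_CACHE[key] = cum
    return cum


def _evolve_indices(
    anc: np.ndarray, t: float, omega: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Evolve sense-codon indices for time t under the GY94-style process."""
    if t == 0:
        return anc.copy()
    cum = _cum_transition(t, omega, kappa)
    u = rng.random(anc.shape)
    return (u[..., None] > cum[anc]).sum(axis=-1)


def evolve_cds_pair(
    length_codons: int,
    t: float,
    omega: float,
    kappa: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> Tuple[str, str]:
    """Evolve a pair of in-frame CDS from a common ancestor.

    ``t`` is the total expected number of substitutions per codon separating
    the pair (each lineage runs t/2).  The substitution process is a
    Goldman–Yang-style codon chain: HKY nucleotide rates with
    transition/transversion ratio ``kappa`` and an ``omega`` multiplier on
    nonsynonymous changes; stop codons are unreachable, so both sequences are
    stop-free by construction.
    """
    if length_codons < 10:
        raise ConfigError(f"length_codons must be >= 10, got {length_codons}")
    if t < 0:
        raise ConfigError(f"t must be >= 0, got {t}")
    if omega < 0:
        raise ConfigError(f"omega must be >= 0, got {omega}")
    if kappa <= 0:
        raise ConfigError(f"kappa must be > 0, got {kappa}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    anc = rng.integers(0, len(_codon.SENSE_CODONS), size=length_codons)
    a = _evolve_indices(anc, t / 2.0, omega, kappa, rng)
    b = _evolve_indices(anc, t / 2.0, omega, kappa, rng)
    return _codon.indices_to_cds(a), _codon.indices_to_cds(b)


def simulate_expression_pair(
    n_tissues: int,
    rho: float,
    seed: int | np.random.Generator = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw two tissue-expression vectors with population correlation ``rho``.

    Marginals are standard normal per tissue (Pearson r is the only statistic
    consumed downstream).
    """
    if n_tissues < 3:
        raise ConfigError(f"n_tissues must be >= 3, got {n_tissues}")
    if abs(rho) > 1:
        raise ConfigError(f"|rho| must be <= 1, got {rho}")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    z = rng.standard_normal((2, n_tissues))
    a = z[0]
    b = rho * z[0] + math.sqrt(1.0 - rho * rho) * z[1]
    return a, b


# ---------------------------------------------------------------------------
# Gene-tree construction
# ---------------------------------------------------------------------------


def _build_gene_tree(
    sp_root: TreeNode,
    fam_id: str,
    pending: Dict[str, tuple],
) -> TreeNode:
    """Copy the species tree into a gene tree, splitting lineages at the
    species nodes named in ``pending``.

    ``pending[label] = (tag_a, tag_b, pending_a)``: at the species node with
    that label the lineage duplicates into copies ``tag_a`` (which may itself
    split again per ``pending_a``) and ``tag_b``.  Leaves are named
    ``{fam_id}C{tag}_{species}``.
    """

    def subtree(node: TreeNode, tag: str, pend: Dict[str, tuple]) -> TreeNode:
        if node.is_leaf:
            return TreeNode(
                name=f"{fam_id}C{tag}_{node.name}", length=node.length or 1.0
            )
        out = TreeNode(name=None, length=node.length)
        for child in node.children:
            out.add_child(rec(child, tag, pend))
        return out

    def rec(node: TreeNode, tag: str, pend: Dict[str, tuple]) -> TreeNode:
        if node.name is not None and node.name in pend:
            tag_a, tag_b, pend_a = pend[node.name]
            dup = TreeNode(name=None, length=node.length)
            dup.add_child(subtree(node, tag_a, pend_a))
            dup.add_child(subtree(node, tag_b, {}))
            return dup
        return subtree(node, tag, pend)

    return rec(sp_root, "0", pending)


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


def _human_path(species_tree: PhyloTree, focal: str) -> List[tuple]:
    """(label, age) for every node on the focal-leaf-to-root path.

    The focal leaf itself (age 0) comes first; every node must be labeled so
    duplication placement weights can reference it.
    """
    leaf = None
    for lf in species_tree.root.leaves():
        if lf.name.lower() == focal.lower():
            leaf = lf
            break
    if leaf is None:
        raise ConfigError(f"focal species {focal!r} not in species tree")
    path = []
    age = 0.0
    node = leaf
    while node is not None:
        if node.name is None:
            raise ConfigError(
                "species tree internal nodes on the focal path must be labeled"
            )
        path.append((node.name, age))
        age += node.length or 0.0
        node = node.parent
    return path


def simulate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a complete cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    species_tree = PhyloTree.from_newick(config.species_tree_newick)
    path = _human_path(species_tree, config.focal_species)
    node_labels = [label for label, _ in path]
    node_age = dict(path)
    fish_age = None
    ciona_age = None
    # WGD window boundaries from the tree itself (if those species exist)
    leaf_names = {n.lower() for n in species_tree.leaf_names()}
    if "takifugu" in leaf_names and "ciona" in leaf_names:
        from .dating import _species_index

        idx = _species_index(species_tree, config.focal_species)
        fish_age = idx.split_age("takifugu")
        ciona_age = idx.split_age("ciona")

    if config.dup_node_weights is None:
        weights = np.full(len(node_labels), 1.0 / len(node_labels))
    else:
        unknown = set(config.dup_node_weights) - set(node_labels)
        if unknown:
            raise ConfigError(
                f"dup_node_weights refers to unknown focal-path nodes: "
                f"{sorted(unknown)} (known: {node_labels})"
            )
        weights = np.array(
            [config.dup_node_weights.get(lbl, 0.0) for lbl in node_labels]
        )

    lo_terms, hi_terms = config.go_terms_per_gene
    go_dag = build_go_dag(config.n_go_leaf_terms)
    leaf_pool = np.array(go_dag.leaves("molecular_function"))
    mf_internal = [f"GO:700000{i}" for i in range(1, 5)]
    bp_terms = [f"GO:{7200001 + i}" for i in range(3)]

    gene_trees: Dict[str, PhyloTree] = {}
    genes: List[GeneRecord] = []
    human_by_family: Dict[str, List[str]] = {}
    truth_rows: List[dict] = []
    # mutual-closest pairs: both genes generated jointly
    primary_pairs: List[dict] = []
    # third-copy pairs in nested families: gene_b generated conditional on
    # its (already generated) closest relative gene_a, with the same
    # class-dependent effect sizes
    anchored_pairs: List[dict] = []
    family_structure: Dict[str, dict] = {}

    def is_wgd_age(age: float) -> bool:
        if fish_age is None:
            return False
        return fish_age <= age < ciona_age

    # ---- family topologies ------------------------------------------------
    for i in range(config.n_families):
        fam_id = f"F{i:05d}"
        pick = int(rng.choice(len(node_labels), p=weights))
        dup_label = node_labels[pick]
        dup_age = node_age[dup_label]
        nested_label = None
        below = node_labels[:pick]  # nodes strictly more recent than the dup
        if below and rng.random() < config.p_nested_duplication:
            nested_label = below[int(rng.integers(len(below)))]
        if nested_label is None:
            pending = {dup_label: ("1", "2", {})}
        else:
            pending = {dup_label: ("1", "2", {nested_label: ("1a", "1b", {})})}
        root = _build_gene_tree(species_tree.root, fam_id, pending)
        tree = PhyloTree(root)
        gene_trees[fam_id] = tree

        focal = config.focal_species.lower()
        humans = sorted(
            lf.name
            for lf in root.leaves()
            if lf.name.rsplit("_", 1)[-1].lower() == focal
        )
        human_by_family[fam_id] = humans

        if nested_label is None:
            g1, g2 = humans
            primary_pairs.append(
                {"fam": fam_id, "a": g1, "b": g2, "node": dup_label, "age": dup_age}
            )
            truth_rows.append(
                {
                    "gene_a": g1,
                    "gene_b": g2,
                    "family_id": fam_id,
                    "node": dup_label,
                    "age": dup_age,
                    "is_primary": True,
                    "is_wgd": is_wgd_age(dup_age),
                }
            )
            family_structure[fam_id] = {"kind": "simple", "age": dup_age}
        else:
            nested_age = node_age[nested_label]
            g1a = f"{fam_id}C1a_{config.focal_species}"
            g1b = f"{fam_id}C1b_{config.focal_species}"
            g2 = f"{fam_id}C2_{config.focal_species}"
            primary_pairs.append(
                {
                    "fam": fam_id,
                    "a": g1a,
                    "b": g1b,
                    "node": nested_label,
                    "age": nested_age,
                }
            )
            for a, b, node_lbl, age, primary in (
                (g1a, g1b, nested_label, nested_age, True),
                (g1a, g2, dup_label, dup_age, False),
                (g1b, g2, dup_label, dup_age, False),
            ):
                truth_rows.append(
                    {
                        "gene_a": a,
                        "gene_b": b,
                        "family_id": fam_id,
                        "node": node_lbl,
                        "age": age,
                        "is_primary": primary,
                        "is_wgd": is_wgd_age(age),
                    }
                )
            anchored_pairs.append(
                {"fam": fam_id, "a": g1a, "b": g2, "node": dup_label, "age": dup_age}
            )
            family_structure[fam_id] = {
                "kind": "nested",
                "age": dup_age,
                "nested_age": nested_age,
            }

    # ---- singleton families ----------------------------------------------
    singleton_ids: List[str] = []
    for i in range(config.n_singletons):
        fam_id = f"S{i:05d}"
        root = _build_gene_tree(species_tree.root, fam_id, {})
        gene_trees[fam_id] = tree = PhyloTree(root)
        gid = f"{fam_id}C0_{config.focal_species}"
        human_by_family[fam_id] = [gid]
        singleton_ids.append(gid)

    # ---- disease labels ---------------------------------------------------
    labels: Dict[str, str] = {}
    for fam_id in sorted(human_by_family):
        is_singleton = fam_id.startswith("S")
        p_md = config.p_disease_singleton if is_singleton else config.p_disease
        for gid in human_by_family[fam_id]:
            u = rng.random()
            if u < p_md:
                labels[gid] = "MD"
            elif u < p_md + config.p_polygenic:
                labels[gid] = "PD"
            else:
                labels[gid] = "ND"

    # effect class per primary pair / per family: MD effects apply as soon as
    # one member (resp. one family gene) is a monogenic disease gene
    for pair in primary_pairs + anchored_pairs:
        pair["md"] = labels[pair["a"]] == "MD" or labels[pair["b"]] == "MD"
    family_md = {
        fam_id: any(labels[g] == "MD" for g in members)
        for fam_id, members in human_by_family.items()
    }
    for row in truth_rows:
        row["pair_class"] = (
            "md"
            if labels[row["gene_a"]] == "MD" or labels[row["gene_b"]] == "MD"
            else "nd"
        )

    paired_genes = {p["a"] for p in primary_pairs} | {p["b"] for p in primary_pairs}
    paired_genes |= {p["b"] for p in anchored_pairs}
    all_humans = [
        g for fam in sorted(human_by_family) for g in human_by_family[fam]
    ]
    unpaired = [g for g in all_humans if g not in paired_genes]

    # ---- expression -------------------------------------------------------
    n_pairs = len(primary_pairs)
    rho = np.array(
        [config.rho_md if p["md"] else config.rho_nd for p in primary_pairs]
    )
    z = rng.standard_normal((n_pairs, 2, config.n_tissues))
    expr_a = z[:, 0, :]
    expr_b = rho[:, None] * z[:, 0, :] + np.sqrt(1.0 - rho * rho)[:, None] * z[:, 1, :]
    expr: Dict[str, np.ndarray] = {}
    for k, pair in enumerate(primary_pairs):
        expr[pair["a"]] = expr_a[k]
        expr[pair["b"]] = expr_b[k]
    for pair in anchored_pairs:
        r = config.rho_md if pair["md"] else config.rho_nd
        expr[pair["b"]] = r * expr[pair["a"]] + math.sqrt(1.0 - r * r) * (
            rng.standard_normal(config.n_tissues)
        )
    for gid in unpaired:
        expr[gid] = rng.standard_normal(config.n_tissues)
    tissue_names = [f"tissue_{i + 1:02d}" for i in range(config.n_tissues)]
    expression = pd.DataFrame(
        np.vstack([expr[g] for g in all_humans]),
        index=pd.Index(all_humans, name="gene"),
        columns=tissue_names,
    )

    # ---- GO annotations ---------------------------------------------------
    go_annotations: Dict[str, set] = {}

    def draw_terms(n: int) -> List[str]:
        return list(rng.choice(leaf_pool, size=n, replace=False))

    def decorate(gid: str) -> None:
        # occasional non-leaf / other-namespace annotations exercise filtering
        if rng.random() < 0.2:
            go_annotations[gid].add(mf_internal[int(rng.integers(4))])
        if rng.random() < 0.3:
            go_annotations[gid].add(bp_terms[int(rng.integers(3))])

    for pair in primary_pairs:
        overlap = config.go_overlap_md if pair["md"] else config.go_overlap_nd
        n_a = int(rng.integers(lo_terms, hi_terms + 1))
        n_b = int(rng.integers(lo_terms, hi_terms + 1))
        terms_a = draw_terms(n_a)
        # each of A's terms is shared with probability `overlap`; B keeps at
        # least the shared terms and fills up with distinct terms of its own
        shared = [t for t in terms_a if rng.random() < overlap]
        n_b = max(n_b, len(shared))
        remaining = [t for t in leaf_pool if t not in terms_a]
        extra_idx = rng.choice(len(remaining), size=n_b - len(shared), replace=False)
        terms_b = shared + [remaining[j] for j in sorted(extra_idx)]
        go_annotations[pair["a"]] = set(terms_a)
        go_annotations[pair["b"]] = set(terms_b)
        decorate(pair["a"])
        decorate(pair["b"])
    leaf_set = set(leaf_pool)
    for pair in anchored_pairs:
        overlap = config.go_overlap_md if pair["md"] else config.go_overlap_nd
        anchor_terms = sorted(go_annotations[pair["a"]] & leaf_set)
        shared = [t for t in anchor_terms if rng.random() < overlap]
        n_b = max(int(rng.integers(lo_terms, hi_terms + 1)), len(shared))
        remaining = [t for t in leaf_pool if t not in anchor_terms]
        extra_idx = rng.choice(len(remaining), size=n_b - len(shared), replace=False)
        go_annotations[pair["b"]] = set(shared + [remaining[j] for j in sorted(extra_idx)])
        decorate(pair["b"])
    for gid in unpaired:
        go_annotations[gid] = set(draw_terms(int(rng.integers(lo_terms, hi_terms + 1))))
        decorate(gid)

    # ---- PPI ---------------------------------------------------------------
    ppi: Dict[str, set] = {g: set() for g in all_humans}

    def add_edges(gid: str, partners) -> None:
        for p in partners:
            if p == gid:
                continue
            ppi[gid].add(p)
            ppi[p].add(gid)

    for pair in primary_pairs:
        overlap = config.ppi_overlap_md if pair["md"] else config.ppi_overlap_nd
        d_a = max(1, int(rng.poisson(config.ppi_degree)))
        d_b = max(1, int(rng.poisson(config.ppi_degree)))
        pool = [g for g in all_humans if g not in (pair["a"], pair["b"])]
        # small cohorts: partner draws cannot exceed the gene universe
        d_a = min(d_a, max(1, len(pool) // 2))
        d_b = min(d_b, max(1, len(pool) // 2))
        n_shared = int(rng.binomial(min(d_a, d_b), overlap))
        picks = rng.choice(
            len(pool), size=n_shared + (d_a - n_shared) + (d_b - n_shared), replace=False
        )
        picked = [pool[j] for j in picks]
        shared = picked[:n_shared]
        own_a = picked[n_shared : n_shared + (d_a - n_shared)]
        own_b = picked[n_shared + (d_a - n_shared) :]
        add_edges(pair["a"], shared + own_a)
        add_edges(pair["b"], shared + own_b)
    for pair in anchored_pairs:
        overlap = config.ppi_overlap_md if pair["md"] else config.ppi_overlap_nd
        anchor_partners = sorted(ppi[pair["a"]] - {pair["b"]})
        d_b = max(1, int(rng.poisson(config.ppi_degree)))
        n_shared = int(rng.binomial(min(d_b, len(anchor_partners)), overlap))
        sh_idx = rng.choice(len(anchor_partners), size=n_shared, replace=False)
        shared = [anchor_partners[j] for j in sorted(sh_idx)]
        pool = [
            g for g in all_humans
            if g not in (pair["a"], pair["b"]) and g not in shared
        ]
        picks = rng.choice(
            len(pool), size=min(d_b - n_shared, len(pool)), replace=False
        )
        add_edges(pair["b"], shared + [pool[j] for j in picks])
    for gid in unpaired:
        d = max(1, int(rng.poisson(config.ppi_degree)))
        pool = [g for g in all_humans if g != gid]
        picks = rng.choice(len(pool), size=min(d, len(pool)), replace=False)
        add_edges(gid, [pool[j] for j in picks])

    # ---- protein complexes -------------------------------------------------
    complex_ids = [f"CPX{i + 1:04d}" for i in range(config.n_complexes)]
    complexes: Dict[str, set] = {c: set() for c in complex_ids}
    for pair in primary_pairs:
        p_co = (
            config.complex_comember_md if pair["md"] else config.complex_comember_nd
        )
        if rng.random() < p_co:
            cpx = complex_ids[int(rng.integers(len(complex_ids)))]
            complexes[cpx].update((pair["a"], pair["b"]))
        else:
            for gid in (pair["a"], pair["b"]):
                if rng.random() < config.p_complex_membership:
                    cpx = complex_ids[int(rng.integers(len(complex_ids)))]
                    complexes[cpx].add(gid)
    for pair in anchored_pairs:
        p_co = (
            config.complex_comember_md if pair["md"] else config.complex_comember_nd
        )
        if rng.random() < p_co:
            cpx = complex_ids[int(rng.integers(len(complex_ids)))]
            complexes[cpx].update((pair["a"], pair["b"]))
        elif rng.random() < config.p_complex_membership:
            cpx = complex_ids[int(rng.integers(len(complex_ids)))]
            complexes[cpx].add(pair["b"])
    for gid in unpaired + singleton_ids:
        if rng.random() < config.p_complex_membership:
            cpx = complex_ids[int(rng.integers(len(complex_ids)))]
            complexes[cpx].add(gid)
    complexes = {c: members for c, members in complexes.items() if members}

    # ---- coding sequences --------------------------------------------------
    rate = config.cds_rate_per_age
    floor_half = config.cds_t_floor / 2.0
    length = config.cds_length_codons
    cds: Dict[str, str] = {}
    proteins: Dict[str, str] = {}

    def store(gid: str, idx) -> None:
        cds[gid] = _codon.indices_to_cds(idx)
        proteins[gid] = _codon.indices_to_protein(idx)

    for fam_id in sorted(family_structure):
        struct = family_structure[fam_id]
        omega = config.dnds_md if family_md[fam_id] else config.dnds_nd
        anc = rng.integers(0, len(_codon.SENSE_CODONS), size=length)
        if struct["kind"] == "simple":
            t_lin = rate * struct["age"] + floor_half
            a = _evolve_indices(anc, t_lin, omega, config.kappa, rng)
            b = _evolve_indices(anc, t_lin, omega, config.kappa, rng)
            store(f"{fam_id}C1_{config.focal_species}", a)
            store(f"{fam_id}C2_{config.focal_species}", b)
        else:
            age, nested_age = struct["age"], struct["nested_age"]
            c2 = _evolve_indices(
                anc, rate * age + floor_half, omega, config.kappa, rng
            )
            mid = _evolve_indices(
                anc, rate * (age - nested_age), omega, config.kappa, rng
            )
            t_lin = rate * nested_age + floor_half
            c1a = _evolve_indices(mid, t_lin, omega, config.kappa, rng)
            c1b = _evolve_indices(mid, t_lin, omega, config.kappa, rng)
            store(f"{fam_id}C1a_{config.focal_species}", c1a)
            store(f"{fam_id}C1b_{config.focal_species}", c1b)
            store(f"{fam_id}C2_{config.focal_species}", c2)
    for gid in singleton_ids:
        anc = rng.integers(0, len(_codon.SENSE_CODONS), size=length)
        store(gid, anc)

    # ---- ortholog dN -------------------------------------------------------
    dn_rows = []
    shape = config.ortholog_dn_shape
    for gid in all_humans:
        base = (
            config.ortholog_dn_mean_md
            if labels[gid] == "MD"
            else config.ortholog_dn_mean_nd
        )
        if gid in singleton_ids:
            base *= config.ortholog_dn_singleton_factor
        for sp in ("mouse", "macaque"):
            dn = float(rng.gamma(shape, base / shape))
            dn_rows.append(
                {
                    "gene": gid,
                    "ortholog_species": sp,
                    "dn": dn,
                    "homology_type": "ortholog_one2one",
                }
            )
    ortholog_dn = pd.DataFrame(dn_rows)

    # ---- gene records ------------------------------------------------------
    focal = config.focal_species
    for fam_id in sorted(gene_trees):
        tree = gene_trees[fam_id]
        for leaf in tree.root.leaves():
            species = leaf.name.rsplit("_", 1)[-1]
            if species == focal:
                genes.append(
                    GeneRecord(
                        gene_id=leaf.name,
                        species=species,
                        protein_seq=proteins.get(leaf.name),
                        cds_seq=cds.get(leaf.name),
                        disease_label=labels[leaf.name],
                        family_id=fam_id,
                    )
                )
            else:
                genes.append(
                    GeneRecord(gene_id=leaf.name, species=species, family_id=fam_id)
                )

    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "gene_a",
            "gene_b",
            "family_id",
            "node",
            "age",
            "pair_class",
            "is_primary",
            "is_wgd",
        ],
    )
    return SyntheticCohort(
        config=config,
        genes=genes,
        gene_trees=gene_trees,
        species_tree=species_tree,
        expression=expression,
        go_annotations=go_annotations,
        go_dag=go_dag,
        ppi=ppi,
        complexes=complexes,
        ortholog_dn=ortholog_dn,
        truth=truth,
    )
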