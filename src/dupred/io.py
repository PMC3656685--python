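"""Readers and writers for the plain-text formats the pipeline consumes:
FASTA, Newick, TSV layers (expression, annotations, PPI edges, complexes,
labels, ortholog dN) and OBO."""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import pandas as pd
from Bio import SeqIO

from .errors import ConfigError
from .trees import PhyloTree, parse_newick


def _check(path, layer: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"missing input for layer {layer!r}: {p}")
    return p


def load_fasta(path, layer: str = "fasta") -> Dict[str, str]:
    p = _check(path, layer)
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(p), "fasta")}


def load_species_tree(path) -> PhyloTree:
    p = _check(path, "species_tree")
    return parse_newick(p.read_text())


def load_gene_trees(path) -> Dict[str, PhyloTree]:
    """One Newick per line; family ids are assigned by line order."""
    p = _check(path, "gene_trees")
    trees: Dict[str, PhyloTree] = {}
    for i, line in enumerate(p.read_text().splitlines()):
        line = line.strip()
        if not line:
            continue
        trees[f"T{i:05d}"] = parse_newick(line)
    return trees


def load_expression(path) -> pd.DataFrame:
    p = _check(path, "expression")
    return pd.read_csv(p, sep="\t", index_col=0)


def load_two_column(path, layer: str) -> Dict[str, set]:
    """gene<TAB>value file into a value-set per gene (first column key)."""
    p = _check(path, layer)
    out: Dict[str, set] = {}
    for line in p.read_text().splitlines():
        if not line.strip():
            continue
        key, value = line.split("\t")[:2]
        out.setdefault(key, set()).add(value)
    return out


def load_labels(path) -> Dict[str, str]:
    p = _check(path, "labels")
    out: Dict[str, str] = {}
    for line in p.read_text().splitlines():
        if not line.strip():
            continue
        gene, label = line.split("\t")[:2]
        out[gene] = label
    return out


def load_ppi(path) -> Dict[str, set]:
    """Undirected edge list into an adjacency map."""
    p = _check(path, "ppi")
    adj: Dict[str, set] = {}
    for line in p.read_text().splitlines():
        if not line.strip():
            continue
        a, b = line.split("\t")[:2]
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


def load_complexes(path) -> Dict[str, set]:
    """complex<TAB>gene membership file."""
    return load_two_column(path, "complexes")


def load_ortholog_dn(path) -> Optional[pd.DataFrame]:
    if path is None:
        return None
    p = _check(path, "ortholog_dn")
    df = pd.read_csv(p, sep="\t")
    required = {"gene", "ortholog_species", "dn"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigError(f"ortholog_dn table lacks columns {sorted(missing)}")
    if "homology_type" in df.columns:
        df = df[df["homology_type"].isin(
            ["ortholog_one2one", "apparent_ortholog_one2one"]
        )]
    return df
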