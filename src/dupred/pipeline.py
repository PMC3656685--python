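"""End-to-end orchestration.

``run_analysis`` drives every stage — duplicate calling, duplication dating,
the four pair-similarity metrics, selection estimates, and the statistical
battery — on either a synthetic cohort or user-supplied files, and returns a
:class:`ResultBundle` with the four result tables: duplicate enrichment,
age-stratified MD/ND comparisons per metric, dN comparisons, and the protein
complex co-membership tests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import itertools
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as _io
from . import __version__
from .dating import classify_wgd, date_duplication, filter_families
from .duplication import align_proteins, closest_paralog
from .errors import ConfigError, PipelineError
from .selection import ng86
from .similarity import (
    GoDag,
    gene_go_similarity,
    load_obo,
    normalized_go_similarity,
    pearson_coexpression,
    shared_interaction_fraction,
)
from .stats import (
    age_group_hypergeom_test,
    complex_comembership_table,
    fisher_exact_2x2,
    stratify_by_age,
    wilcoxon_rank_sum,
)
from .synthetic import CohortConfig, SyntheticCohort, simulate_cohort
from .trees import PhyloTree

logger = logging.getLogger("dupred")

__all__ = ["RunConfig", "ResultBundle", "run_analysis", "duplicate_enrichment_table"]

# metric -> direction in which disease pairs are expected to differ
METRIC_DIRECTIONS = {
    "coexpression": "md_higher",
    "identity": "md_higher",
    "go_norm": "md_higher",
    "shared_ppi": "md_higher",
    "dn": "md_lower",
}


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    mode: str = "synthetic"  # "synthetic" | "files"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    paths: Dict[str, str] = field(default_factory=dict)
    seed: int = 0
    focal_species: str = "human"
    min_family_species: int = 4
    min_bin_n: int = 3
    min_bins: int = 5
    # WGD window convention used for the WGD-vs-SSD contrast: closed at the
    # fish-split boundary so duplications mapped onto that node fall inside
    # the window (see docs/methods.md).
    wgd_include_lower: bool = True
    wgd_include_upper: bool = False
    include_pd_as_md: bool = False
    go_namespace: str = "molecular_function"
    go_leaf_only: bool = True
    wang_w: float = 0.8
    ppi_method: str = "jaccard"
    paralog_count_cap: int = 10
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"mode must be synthetic|files, got {self.mode!r}")
        if self.mode == "synthetic":
            self.cohort.validate()
        else:
            required = [
                "gene_trees",
                "species_tree",
                "labels",
                "expression",
                "go_annotations",
                "go_obo",
                "ppi",
                "complexes",
                "cds",
            ]
            missing = [k for k in required if k not in self.paths]
            if missing:
                raise ConfigError(f"files mode lacks paths for: {missing}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig.from_dict(data.pop("cohort", {}) or {})
        known = {f.name for f in dataclasses.fields(cls)} - {"cohort"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown run config keys: {sorted(unknown)}")
        config = cls(cohort=cohort, **data)
        config.validate()
        return config

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class _Layers:
    """In-memory view of all data layers, source-agnostic."""

    gene_trees: Dict[str, PhyloTree]
    species_tree: PhyloTree
    labels: Dict[str, str]
    expression: pd.DataFrame
    go_annotations: Dict[str, set]
    go_dag: GoDag
    ppi: Dict[str, set]
    complexes: Dict[str, set]
    cds: Dict[str, str]
    proteins: Dict[str, str]
    ortholog_dn: Optional[pd.DataFrame]


@dataclass
class ResultBundle:
    enrichment: dict
    pairs: pd.DataFrame
    group_tests: pd.DataFrame
    overall_tests: pd.DataFrame
    ortholog_tests: Optional[pd.DataFrame]
    complex_tests: pd.DataFrame
    age_bins: Dict[str, pd.DataFrame]
    provenance: dict

    def write(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        fmt = "%.10g"
        enrich = self.enrichment
        pd.DataFrame([{k: v for k, v in enrich.items() if k != "by_paralog_count"}]).to_csv(
            out / "enrichment.tsv", sep="\t", index=False, float_format=fmt
        )
        enrich["by_paralog_count"].to_csv(
            out / "enrichment_by_count.tsv", sep="\t", index=False, float_format=fmt
        )
        self.pairs.to_csv(out / "pairs.tsv", sep="\t", index=False, float_format=fmt)
        self.group_tests.to_csv(
            out / "group_tests.tsv", sep="\t", index=False, float_format=fmt
        )
        self.overall_tests.to_csv(
            out / "overall_tests.tsv", sep="\t", index=False, float_format=fmt
        )
        if self.ortholog_tests is not None:
            self.ortholog_tests.to_csv(
                out / "ortholog_dn_tests.tsv", sep="\t", index=False, float_format=fmt
            )
        self.complex_tests.to_csv(
            out / "complex_tests.tsv", sep="\t", index=False, float_format=fmt
        )
        for metric, df in self.age_bins.items():
            df.to_csv(
                out / f"age_bins_{metric}.tsv", sep="\t", index=False, float_format=fmt
            )
        (out / "provenance.json").write_text(
            json.dumps(self.provenance, indent=2, sort_keys=True) + "\n"
        )


def _layers_from_cohort(cohort: SyntheticCohort) -> _Layers:
    cds = {g.gene_id: g.cds_seq for g in cohort.human_genes() if g.cds_seq}
    proteins = {g.gene_id: g.protein_seq for g in cohort.human_genes() if g.protein_seq}
    return _Layers(
        gene_trees=cohort.gene_trees,
        species_tree=cohort.species_tree,
        labels=cohort.labels(),
        expression=cohort.expression,
        go_annotations=cohort.go_annotations,
        go_dag=cohort.go_dag,
        ppi=cohort.ppi,
        complexes=cohort.complexes,
        cds=cds,
        proteins=proteins,
        ortholog_dn=cohort.ortholog_dn,
    )


def _layers_from_files(paths: Dict[str, str]) -> _Layers:
    cds = _io.load_fasta(paths["cds"], "cds")
    proteins = (
        _io.load_fasta(paths["proteins"], "proteins")
        if "proteins" in paths
        else {}
    )
    return _Layers(
        gene_trees=_io.load_gene_trees(paths["gene_trees"]),
        species_tree=_io.load_species_tree(paths["species_tree"]),
        labels=_io.load_labels(paths["labels"]),
        expression=_io.load_expression(paths["expression"]),
        go_annotations=_io.load_two_column(paths["go_annotations"], "go_annotations"),
        go_dag=load_obo(paths["go_obo"]),
        ppi=_io.load_ppi(paths["ppi"]),
        complexes=_io.load_complexes(paths["complexes"]),
        cds=cds,
        proteins=proteins,
        ortholog_dn=_io.load_ortholog_dn(paths.get("ortholog_dn")),
    )


def duplicate_enrichment_table(
    labels: Dict[str, str],
    paralog_counts: Dict[str, int],
    cap: int = 10,
    include_pd_as_md: bool = False,
) -> dict:
    """Duplicate-vs-singleton enrichment of disease genes.

    Returns the MD/ND x duplicate/singleton counts and fractions, Fisher's
    exact test on that table, and the MD fraction per paralog-count stratum
    (counts above ``cap`` pooled).  PD genes are excluded unless
    ``include_pd_as_md``.
    """
    md_labels = {"MD", "PD"} if include_pd_as_md else {"MD"}
    rows = []
    for gene, label in labels.items():
        if label not in md_labels and label != "ND":
            continue
        rows.append(
            {
                "gene": gene,
                "is_md": label in md_labels,
                "count": int(paralog_counts.get(gene, 0)),
            }
        )
    df = pd.DataFrame(rows)
    df["is_dup"] = df["count"] > 0
    md_dup = int(((df.is_md) & (df.is_dup)).sum())
    md_single = int(((df.is_md) & (~df.is_dup)).sum())
    nd_dup = int(((~df.is_md) & (df.is_dup)).sum())
    nd_single = int(((~df.is_md) & (~df.is_dup)).sum())
    odds, p = fisher_exact_2x2((md_dup, md_single, nd_dup, nd_single))

    df["stratum"] = np.minimum(df["count"], cap)
    strata = (
        df.groupby("stratum")
        .agg(n_genes=("gene", "size"), n_md=("is_md", "sum"))
        .reset_index()
    )
    strata["md_fraction"] = strata["n_md"] / strata["n_genes"]

    return {
        "n_md": md_dup + md_single,
        "n_nd": nd_dup + nd_single,
        "md_dup": md_dup,
        "md_single": md_single,
        "nd_dup": nd_dup,
        "nd_single": nd_single,
        "md_dup_fraction": md_dup / max(md_dup + md_single, 1),
        "nd_dup_fraction": nd_dup / max(nd_dup + nd_single, 1),
        "dup_md_fraction": md_dup / max(md_dup + nd_dup, 1),
        "singleton_md_fraction": md_single / max(md_single + nd_single, 1),
        "fisher_odds_ratio": odds,
        "fisher_p": p,
        "by_paralog_count": strata,
    }


def _pair_identity(
    gene_a: str, gene_b: str, proteins: Dict[str, str]
) -> float:
    pa, pb = proteins.get(gene_a), proteins.get(gene_b)
    if not pa or not pb:
        return math.nan
    pa, pb = pa.rstrip("*"), pb.rstrip("*")
    if len(pa) == len(pb):
        # codon-aligned upstream: column-wise identity
        return sum(1 for x, y in zip(pa, pb) if x == y) / len(pa)
    hit = align_proteins(pa, pb, ids=(gene_a, gene_b))
    return hit.identity


def run_analysis(config: RunConfig) -> ResultBundle:
    """Run every stage and assemble the result tables.

    Deterministic given ``config.seed``; raises on missing layers or a
    cohort without any monogenic-disease gene.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)

    if config.mode == "synthetic":
        cohort_cfg = dataclasses.replace(config.cohort, seed=config.seed)
        layers = _layers_from_cohort(simulate_cohort(cohort_cfg))
    else:
        layers = _layers_from_files(config.paths)

    focal = config.focal_species
    labels = layers.labels
    if not any(v == "MD" for v in labels.values()):
        raise PipelineError("cohort contains zero MD genes")

    # ---- families and duplicate calls ------------------------------------
    kept = filter_families(
        layers.gene_trees,
        min_species=config.min_family_species,
        focal_species=focal,
    )
    humans_by_family: Dict[str, List[str]] = {}
    for fam_id in kept:
        tree = layers.gene_trees[fam_id]
        humans = sorted(
            name
            for name in tree.leaf_names()
            if name.rsplit("_", 1)[-1].lower() == focal.lower()
        )
        humans_by_family[fam_id] = humans

    paralog_counts: Dict[str, int] = {}
    for fam_id, humans in humans_by_family.items():
        for g in humans:
            paralog_counts[g] = len(humans) - 1
    unlabeled = [g for g in paralog_counts if g not in labels]
    if unlabeled:
        raise PipelineError(
            f"human genes without disease label: {sorted(unlabeled)[:5]}..."
        )

    enrichment = duplicate_enrichment_table(
        labels,
        paralog_counts,
        cap=config.paralog_count_cap,
        include_pd_as_md=config.include_pd_as_md,
    )
    logger.info(
        "enrichment: MD dup fraction %.3f vs ND %.3f (p=%.3g)",
        enrichment["md_dup_fraction"],
        enrichment["nd_dup_fraction"],
        enrichment["fisher_p"],
    )

    # ---- dating and closest paralogs --------------------------------------
    dated: Dict[tuple, dict] = {}
    candidates: Dict[str, list] = {}
    for fam_id, humans in humans_by_family.items():
        if len(humans) < 2:
            continue
        tree = layers.gene_trees[fam_id]
        for ga, gb in itertools.combinations(humans, 2):
            rec = date_duplication(
                tree, ga, gb, layers.species_tree, focal_species=focal
            )
            identity = _pair_identity(ga, gb, layers.proteins)
            dated[rec.pair] = {
                "family_id": fam_id,
                "node": rec.species_node,
                "age": rec.age,
                "identity": identity,
            }
            candidates.setdefault(ga, []).append((gb, rec.age, identity))
            candidates.setdefault(gb, []).append((ga, rec.age, identity))

    closest_pairs: Dict[tuple, dict] = {}
    for gene in sorted(candidates):
        pair = closest_paralog(gene, candidates[gene])
        info = dated[pair.pair]
        closest_pairs.setdefault(pair.pair, info)

    # ---- per-pair metrics --------------------------------------------------
    md_labels = {"MD", "PD"} if config.include_pd_as_md else {"MD"}
    dag = layers.go_dag
    term_counts: Dict[str, int] = {}

    def filtered_count(gene: str) -> int:
        if gene not in term_counts:
            term_counts[gene] = len(
                dag.filter_terms(
                    layers.go_annotations.get(gene, ()),
                    config.go_namespace,
                    config.go_leaf_only,
                )
            )
        return term_counts[gene]

    rows = []
    for (ga, gb), info in sorted(closest_pairs.items()):
        la, lb = labels.get(ga), labels.get(gb)
        has_pd = "PD" in (la, lb) and not config.include_pd_as_md
        is_md = la in md_labels or lb in md_labels

        ea = layers.expression.loc[ga].to_numpy() if ga in layers.expression.index else None
        eb = layers.expression.loc[gb].to_numpy() if gb in layers.expression.index else None
        coexpr = pearson_coexpression(ea, eb) if ea is not None and eb is not None else math.nan

        go_raw = gene_go_similarity(
            layers.go_annotations.get(ga, ()),
            layers.go_annotations.get(gb, ()),
            dag,
            namespace=config.go_namespace,
            leaf_only=config.go_leaf_only,
            w=config.wang_w,
        )
        x = max(filtered_count(ga), filtered_count(gb))

        ppi_a, ppi_b = layers.ppi.get(ga), layers.ppi.get(gb)
        shared = (
            shared_interaction_fraction(
                ppi_a, ppi_b, pair=(ga, gb), method=config.ppi_method
            )
            if ppi_a and ppi_b
            else math.nan
        )

        ca, cb = layers.cds.get(ga), layers.cds.get(gb)
        if ca and cb and len(ca) == len(cb):
            est = ng86((ca, cb))
            dn, ds = est.dn, est.ds
        else:
            dn = ds = math.nan

        rows.append(
            {
                "gene_a": ga,
                "gene_b": gb,
                "family_id": info["family_id"],
                "node": info["node"],
                "age": info["age"],
                "is_md_pair": is_md,
                "has_pd": has_pd,
                "identity": info["identity"],
                "coexpression": coexpr,
                "go_raw": go_raw,
                "go_x": x,
                "shared_ppi": shared,
                "dn": dn,
                "ds": ds,
            }
        )
    pairs = pd.DataFrame(rows)
    if pairs.empty:
        raise PipelineError("no paralog pairs to analyze")

    scored = pairs[~pairs["go_raw"].isna()]
    if not scored.empty:
        genes_in_pairs = sorted(set(scored.gene_a) | set(scored.gene_b))
        counts = [filtered_count(g) for g in genes_in_pairs if filtered_count(g) > 0]
        min_terms, max_terms = min(counts), max(counts)
        pairs["go_norm"] = [
            normalized_go_similarity(raw, int(x), min_terms, max_terms)
            if not math.isnan(raw)
            else math.nan
            for raw, x in zip(pairs["go_raw"], pairs["go_x"])
        ]
    else:
        pairs["go_norm"] = math.nan

    pairs["is_wgd"] = [
        classify_wgd(
            age,
            layers.species_tree,
            focal_species=focal,
            include_lower=config.wgd_include_lower,
            include_upper=config.wgd_include_upper,
        )
        for age in pairs["age"]
    ]

    # PD-containing pairs are held out of the MD-vs-ND comparisons
    test_pairs = pairs[~pairs["has_pd"]]

    # ---- age-stratified group tests ---------------------------------------
    group_rows, overall_rows = [], []
    age_bin_tables: Dict[str, pd.DataFrame] = {}
    for metric, direction in METRIC_DIRECTIONS.items():
        values = test_pairs[metric].to_numpy(dtype=float)
        md_mask = test_pairs["is_md_pair"].to_numpy(dtype=bool)
        ages = test_pairs["age"].to_numpy(dtype=float)
        try:
            bins = stratify_by_age(ages, md_mask, values, min_n=config.min_bin_n)
            q, K, p = age_group_hypergeom_test(
                bins,
                direction=direction,
                min_bins=config.min_bins,
                min_n=config.min_bin_n,
            )
            group_rows.append(
                {"metric": metric, "direction": direction, "q": q, "K": K, "p": p}
            )
            age_bin_tables[metric] = pd.DataFrame(
                [
                    {
                        "age": b.age,
                        "n_md": len(b.md_values),
                        "n_nd": len(b.nd_values),
                        "md_mean": b.md_mean,
                        "nd_mean": b.nd_mean,
                        "valid": b.is_valid(config.min_bin_n),
                    }
                    for b in bins
                ]
            )
        except Exception as exc:
            logger.warning("group test for %s skipped: %s", metric, exc)
            group_rows.append(
                {
                    "metric": metric,
                    "direction": direction,
                    "q": math.nan,
                    "K": math.nan,
                    "p": math.nan,
                }
            )

        md_vals = [v for v in values[md_mask] if not math.isnan(v)]
        nd_vals = [v for v in values[~md_mask] if not math.isnan(v)]
        if md_vals and nd_vals:
            stat, wp = wilcoxon_rank_sum(md_vals, nd_vals)
            overall_rows.append(
                {
                    "metric": metric,
                    "U": stat,
                    "p": wp,
                    "n_md": len(md_vals),
                    "n_nd": len(nd_vals),
                    "md_median": float(np.median(md_vals)),
                    "nd_median": float(np.median(nd_vals)),
                }
            )
    group_tests = pd.DataFrame(group_rows)
    overall_tests = pd.DataFrame(overall_rows)

    # ---- ortholog dN comparisons ------------------------------------------
    ortholog_tests = None
    if layers.ortholog_dn is not None and not layers.ortholog_dn.empty:
        dn = layers.ortholog_dn.copy()
        dn["label"] = dn["gene"].map(labels)
        dn["is_dup"] = dn["gene"].map(lambda g: paralog_counts.get(g, 0) > 0)
        orows = []
        for sp, sub in dn.groupby("ortholog_species"):
            md = sub[sub.label == "MD"]["dn"].tolist()
            nd = sub[sub.label == "ND"]["dn"].tolist()
            if md and nd:
                stat, p = wilcoxon_rank_sum(md, nd)
                orows.append(
                    {
                        "comparison": f"MD_vs_ND_{sp}",
                        "U": stat,
                        "p": p,
                        "n_a": len(md),
                        "n_b": len(nd),
                        "median_a": float(np.median(md)),
                        "median_b": float(np.median(nd)),
                    }
                )
            md_dup = sub[(sub.label == "MD") & (sub.is_dup)]["dn"].tolist()
            md_single = sub[(sub.label == "MD") & (~sub.is_dup)]["dn"].tolist()
            if md_dup and md_single:
                stat, p = wilcoxon_rank_sum(md_dup, md_single)
                orows.append(
                    {
                        "comparison": f"MDdup_vs_MDsingleton_{sp}",
                        "U": stat,
                        "p": p,
                        "n_a": len(md_dup),
                        "n_b": len(md_single),
                        "median_a": float(np.median(md_dup)),
                        "median_b": float(np.median(md_single)),
                    }
                )
        ortholog_tests = pd.DataFrame(orows)

    # ---- protein-complex co-membership ------------------------------------
    crows = []
    md_pairs = [tuple(r) for r in test_pairs[test_pairs.is_md_pair][["gene_a", "gene_b"]].to_numpy()]
    nd_pairs = [tuple(r) for r in test_pairs[~test_pairs.is_md_pair][["gene_a", "gene_b"]].to_numpy()]
    if md_pairs and nd_pairs and layers.complexes:
        table = complex_comembership_table(
            md_pairs, nd_pairs, layers.complexes, labels=("MD_pairs", "ND_pairs")
        )
        odds, p = fisher_exact_2x2(table)
        crows.append(
            {
                "comparison": "MD_vs_ND_pairs",
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    wgd_pairs = [tuple(r) for r in pairs[pairs.is_wgd][["gene_a", "gene_b"]].to_numpy()]
    ssd_pairs = [tuple(r) for r in pairs[~pairs.is_wgd][["gene_a", "gene_b"]].to_numpy()]
    if wgd_pairs and ssd_pairs and layers.complexes:
        table = complex_comembership_table(
            wgd_pairs, ssd_pairs, layers.complexes, labels=("WGD_pairs", "SSD_pairs")
        )
        odds, p = fisher_exact_2x2(table)
        crows.append(
            {
                "comparison": "WGD_vs_SSD_pairs",
                "a": table.a,
                "b": table.b,
                "c": table.c,
                "d": table.d,
                "odds_ratio": odds,
                "p": p,
            }
        )
    complex_tests = pd.DataFrame(
        crows, columns=["comparison", "a", "b", "c", "d", "odds_ratio", "p"]
    )

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "mode": config.mode,
        "version": __version__,
        "n_families": len(kept),
        "n_pairs": int(len(pairs)),
        "n_human_genes": len(paralog_counts),
    }
    return ResultBundle(
        enrichment=enrichment,
        pairs=pairs,
        group_tests=group_tests,
        overall_tests=overall_tests,
        ortholog_tests=ortholog_tests,
        complex_tests=complex_tests,
        age_bins=age_bin_tables,
        provenance=provenance,
    )
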