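"""Synthetic-cohort generator: determinism, label rates, expression and
codon-evolution behavior, truth-table completeness, effect direction."""

import itertools
import math

import numpy as np
import pytest

from dupred.errors import ConfigError
from dupred.selection import ng86
from dupred.similarity import gene_go_similarity
from dupred.synthetic import (
    CohortConfig,
    evolve_cds_pair,
    simulate_cohort,
    simulate_expression_pair,
)

from conftest import null_config


def _cohort_signature(cohort):
    return (
        {f: t.to_newick() for f, t in cohort.gene_trees.items()},
        cohort.expression.round(12).to_csv(),
        {g.gene_id: (g.cds_seq, g.disease_label) for g in cohort.genes},
        {g: tuple(sorted(t)) for g, t in cohort.go_annotations.items()},
        {g: tuple(sorted(p)) for g, p in cohort.ppi.items()},
        {c: tuple(sorted(m)) for c, m in cohort.complexes.items()},
        cohort.ortholog_dn.to_csv(),
        cohort.truth.to_csv(),
    )


def test_same_seed_reproduces_identical_cohort():
    cfg = CohortConfig(n_families=25, n_singletons=10, seed=11)
    a = simulate_cohort(cfg)
    b = simulate_cohort(CohortConfig(n_families=25, n_singletons=10, seed=11))
    assert _cohort_signature(a) == _cohort_signature(b)


def test_write_is_byte_identical(tmp_path):
    cfg = CohortConfig(n_families=10, n_singletons=5, seed=3)
    for d in ("one", "two"):
        simulate_cohort(cfg).write(tmp_path / d)
    for f in sorted((tmp_path / "one").iterdir()):
        assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes(), f.name


def test_zero_disease_probability_gives_zero_md_genes():
    cfg = CohortConfig(
        n_families=30, n_singletons=10, p_disease=0.0, p_disease_singleton=0.0, seed=2
    )
    cohort = simulate_cohort(cfg)
    assert all(g.disease_label != "MD" for g in cohort.human_genes())


def test_md_fraction_within_binomial_band():
    """n_families=200, p_disease=0.2: the realized MD fraction among family
    genes stays inside the 0.2 +/- 0.06 band (>= 95% binomial coverage)."""
    cfg = CohortConfig(n_families=200, n_singletons=0, p_disease=0.2, seed=1)
    cohort = simulate_cohort(cfg)
    labels = [g.disease_label for g in cohort.human_genes()]
    frac = sum(1 for l in labels if l == "MD") / len(labels)
    assert 0.14 <= frac <= 0.26


def test_invalid_configs_rejected():
    with pytest.raises(ConfigError):
        CohortConfig(p_disease=1.5).validate()
    with pytest.raises(ConfigError):
        CohortConfig(dnds_md=0.0).validate()
    with pytest.raises(ConfigError):
        CohortConfig(n_tissues=2).validate()
    with pytest.raises(ConfigError):
        CohortConfig(species_tree_newick="  ").validate()
    with pytest.raises(ConfigError):
        CohortConfig(dup_node_weights={"human": 0.5}).validate()


def test_config_yaml_round_trip(tmp_path):
    cfg = CohortConfig(n_families=17, rho_md=0.55, seed=9)
    cfg.to_yaml(tmp_path / "c.yaml")
    again = CohortConfig.from_yaml(tmp_path / "c.yaml")
    assert again == cfg


# ---- expression -----------------------------------------------------------


def test_expression_perfect_correlation():
    a, b = simulate_expression_pair(36, 1.0, seed=5)
    assert abs(np.corrcoef(a, b)[0, 1] - 1.0) < 1e-12


def test_expression_null_correlation_mean():
    rs = []
    rng = np.random.default_rng(0)
    for _ in range(10_000):
        a, b = simulate_expression_pair(36, 0.0, seed=rng)
        rs.append(np.corrcoef(a, b)[0, 1])
    assert abs(float(np.mean(rs))) < 0.02


def test_expression_target_correlation_recovered():
    rs = []
    rng = np.random.default_rng(1)
    for _ in range(1000):
        a, b = simulate_expression_pair(36, 0.8, seed=rng)
        rs.append(np.corrcoef(a, b)[0, 1])
    assert 0.75 <= float(np.mean(rs)) <= 0.85


def test_expression_pair_validation():
    with pytest.raises(ConfigError):
        simulate_expression_pair(2, 0.5)
    with pytest.raises(ConfigError):
        simulate_expression_pair(10, 1.5)


# ---- codon evolution ------------------------------------------------------


def test_zero_divergence_gives_identical_cds():
    a, b = evolve_cds_pair(50, 0.0, 0.2, 2.0, seed=4)
    assert a == b
    assert len(a) == 150


def test_omega_zero_forces_dn_zero():
    rng = np.random.default_rng(6)
    for _ in range(5):
        a, b = evolve_cds_pair(100, 0.5, 0.0, 2.0, seed=rng)
        assert ng86((a, b)).dn == 0.0


def test_evolved_pairs_have_no_internal_stops():
    stops = {"TAA", "TAG", "TGA"}
    a, b = evolve_cds_pair(200, 1.0, 0.5, 2.0, seed=8)
    for seq in (a, b):
        assert not any(
            seq[i : i + 3] in stops for i in range(0, len(seq), 3)
        )


def test_evolve_cds_pair_validation():
    with pytest.raises(ConfigError):
        evolve_cds_pair(5, 0.1, 0.2)
    with pytest.raises(ConfigError):
        evolve_cds_pair(20, -0.1, 0.2)


# ---- structure and truth --------------------------------------------------


def test_truth_table_covers_every_paralog_pair(small_cohort):
    focal = small_cohort.config.focal_species
    expected = set()
    for fam_id, tree in small_cohort.gene_trees.items():
        humans = sorted(
            n for n in tree.leaf_names() if n.endswith(f"_{focal}")
        )
        for a, b in itertools.combinations(humans, 2):
            expected.add((a, b))
    observed = {
        tuple(sorted((r.gene_a, r.gene_b)))
        for r in small_cohort.truth.itertuples()
    }
    assert observed == expected


def test_every_human_gene_in_exactly_one_tree(small_cohort):
    seen = {}
    for fam_id, tree in small_cohort.gene_trees.items():
        for name in tree.leaf_names():
            assert name not in seen
            seen[name] = fam_id
    for g in small_cohort.human_genes():
        assert g.family_id == seen[g.gene_id]


def test_truth_ages_match_species_tree_nodes(small_cohort, species_tree):
    from dupred.dating import _species_index

    idx = _species_index(species_tree, "human")
    node_ages = set(idx.age_by_id.values())
    assert set(small_cohort.truth["age"]).issubset(node_ages)


def test_effect_direction_go_similarity_md_above_nd():
    """With go_overlap_md > go_overlap_nd the mean simulated GO similarity
    of MD pairs exceeds ND pairs in nearly every cohort."""
    wins = 0
    n_cohorts = 30
    for seed in range(n_cohorts):
        cohort = simulate_cohort(
            CohortConfig(n_families=150, n_singletons=0, seed=seed)
        )
        primary = cohort.truth[cohort.truth.is_primary]
        sims = {"md": [], "nd": []}
        for r in primary.itertuples():
            s = gene_go_similarity(
                cohort.go_annotations[r.gene_a],
                cohort.go_annotations[r.gene_b],
                cohort.go_dag,
            )
            if not math.isnan(s):
                sims[r.pair_class].append(s)
        if np.mean(sims["md"]) > np.mean(sims["nd"]):
            wins += 1
    assert wins >= math.ceil(0.95 * n_cohorts)


def test_null_config_helper_has_no_effects():
    cfg = null_config()
    assert cfg.rho_md == cfg.rho_nd
    assert cfg.go_overlap_md == cfg.go_overlap_nd
    assert cfg.dnds_md == cfg.dnds_nd
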