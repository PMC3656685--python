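# dupred

Age-stratified analysis of functional redundancy between duplicated disease
genes and their closest paralogs.

## The scientific problem

Genes whose mutations cause Mendelian (monogenic) disorders are — counter to
the classical expectation — *enriched* among duplicated genes.  One proposed
explanation is functional compensation: a closest paralog that still covers
the gene's function masks deleterious mutations, letting them drift in the
population while still surfacing as disease in individuals where the backup
copy is weakly expressed.  Testing this requires comparing disease-gene
paralog pairs (MD-pairs) with non-disease pairs (ND-pairs) *of similar
duplication age*, because redundancy decays as duplicates diverge.

`dupred` implements that analysis as a reusable pipeline:

1. **Duplicate calling** — from all-vs-all local protein alignments
   (bitscore > 80 and alignment covering ≥ 50% of the shorter protein) or
   from gene-family membership (≥ 2 genes of the focal species in a family).
2. **Duplication dating** — for a paralog pair, take the clade under their
   gene-tree LCA, map the clade's species onto a species tree, and date the
   duplication at the species-tree LCA of that set; the age is the branch
   length summed from that node to the focal-species leaf.  Duplications
   dated between the human–teleost and human–Ciona splits are flagged as
   whole-genome-duplication (WGD) candidates.
3. **Similarity metrics per gene/closest-paralog pair** — tissue
   co-expression (Pearson r), protein identity, GO semantic similarity
   (Wang's graph-based measure combined by best-match average over leaf
   molecular-function terms, then depth-normalized by
   `raw × (x − min + 1)/(max − min + 1)` where `x` is the pair's maximal
   term count), and the Jaccard fraction of shared protein-interaction
   partners.
4. **Selection** — Nei–Gojobori (1986) dN/dS with pathway counting and the
   Jukes–Cantor correction, implemented natively and checked against an
   independent pathway-enumeration oracle.
5. **Statistics** — Fisher's exact test (duplicate enrichment, protein
   complex co-membership), Wilcoxon rank-sum (age-omitted comparisons), and
   the age-binned hypergeometric group test: with `K` valid age bins and
   `q` bins in which the MD mean beats the ND mean, p = P(X ≥ q) for
   X ~ Hypergeom(2K, K, K).
6. **Synthetic cohorts** — a generator that emulates every input layer
   (gene trees with duplications at known species-tree nodes, disease
   labels, correlated expression, GO/PPI overlap, a GY94-style codon
   process with configurable dN/dS) plus a per-pair truth table, so the
   entire pipeline is testable without any external download.

## Worked example

```python
from dupred import RunConfig, run_analysis

bundle = run_analysis(RunConfig(seed=2))
e = bundle.enrichment
print(f"MD duplicate fraction: {e['md_dup_fraction']:.3f}")
print(f"ND duplicate fraction: {e['nd_dup_fraction']:.3f}")
print(bundle.group_tests)
```

prints (seed 2, default synthetic cohort of 200 families + 100 singletons):

```
MD duplicate fraction: 0.898
ND duplicate fraction: 0.788
         metric  direction   q   K         p
0  coexpression  md_higher  10  10  0.000005
1      identity  md_higher  10  10  0.000005
2       go_norm  md_higher   8  10  0.011507
3    shared_ppi  md_higher  10  10  0.000005
4            dn   md_lower  10  10  0.000005
```

Reading: in all 10 age bins the disease-containing pairs have higher mean
co-expression, protein identity and shared-PPI fraction and lower dN than
non-disease pairs of the same duplication age (q = 10 of K = 10;
p = 1/C(20,10) ≈ 5.4×10⁻⁶ under the hypergeometric group test); the
normalized GO similarity points the same way in 8 of 10 bins (p ≈ 0.012).  `bundle.pairs` holds the per-pair table,
`bundle.complex_tests` the protein-complex co-membership Fisher tests.

The same analysis runs from the shell:

```bash
dupred simulate --seed 1 --out cohort/            # write all data layers
dupred run-all  --seed 1 --out results/           # full synthetic analysis
dupred date-duplications --gene-trees cohort/gene_trees.nwk \
    --species-tree cohort/species_tree.nwk --out ages.tsv
```

File-driven mode consumes generic formats (Newick, FASTA, TSV, OBO); see
`RunConfig(mode="files", paths={...})`.

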