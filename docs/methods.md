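# Methods

This note documents the models, conventions and design choices behind
`dupred`, in the order the pipeline applies them.

## Duplicate calling

The homology route scores all-vs-all local protein alignments
(`Bio.Align.PairwiseAligner`, BLOSUM62; BLAST-style gap costs: a gap of
length L costs `gap_open + L·gap_extend`, defaults 11/1).  Raw
Smith–Waterman scores are converted to bitscores with the Karlin–Altschul
formula `(λS − ln K)/ln 2` using the standard gapped BLOSUM62 constants
λ = 0.267, K = 0.041 (configurable — the original search engine's defaults
are not documented).  A pair is a duplicate iff bitscore **> 80** (strict)
and the aligned region covers **≥ 50%** of the shorter protein, counting
only columns that consume the shorter sequence.  Where several hits exist
for a pair, the highest bitscore wins.  The family route declares every
focal-species gene sharing a family with another focal-species gene a
duplicate.  Families are analyzed only if they contain a focal-species gene
and at least 4 distinct species.

## Duplication dating

For a paralog pair, the species set of the clade under the pair's gene-tree
LCA is mapped onto the species tree; the duplication is placed at the
species-tree LCA of that set and its age is the branch-length sum from that
node to the focal leaf.  No gene-loss inference or probabilistic
reconciliation is attempted: the procedure is deliberately the bare LCA
mapping, so ages can only take the finite set of values
{path length(node → focal leaf)} for nodes on the root-to-focal path —
these values define the age bins used by the statistics.  Species are
parsed from leaf names as the substring after the last underscore,
lowercased (`GENEID_species`); multifurcations are used as-is.  A gene's
most recent duplication (MRD) is its minimum pair age; its closest paralog
is the minimum-age partner, ties broken by higher protein identity, then
lexicographic id.

### WGD window

Duplicates dated after the focal–Ciona split and before the focal–teleost
split are classified as whole-genome-duplication (WGD) candidates.
`classify_wgd` defaults to the open interval on both boundaries with
`include_lower` / `include_upper` flags.  Because the dating procedure maps
a duplication that occurred *between* the two splits exactly onto the
fish-split node (its clade spans the teleosts but not Ciona), the open
convention can never label a mapped node age as WGD; the pipeline therefore
runs with `include_lower=True` (window closed at the fish split), which is
the convention under which node-age dating can populate the window at all.
Both conventions remain available.

## Similarity metrics

* **Co-expression**: Pearson r over tissues, missing tissues dropped
  pairwise, undefined (missing) below 3 complete pairs or at zero variance.
  Expression values are used as provided (no log transform by default; the
  generator emits normal marginals, for which r is exact).
* **Identity**: fraction of identical columns.  For codon-aligned
  synthetic proteins of equal length this is computed column-wise; unequal
  lengths fall back to the local aligner.
* **GO similarity**: Wang's graph-based term similarity on `is_a` edges
  with edge weight w = 0.8, combined by best-match average (BMA); term sets
  are first restricted to *leaf* terms of the molecular_function namespace
  (leaf = no same-namespace `is_a` child in the loaded DAG, hence
  DAG-version dependent).  Pairs where either gene retains no term are
  excluded (missing), matching the exclusion of unannotated genes.
  The combination strategy and namespace are configurable; the
  information-content measures (Resnik/Lin) are out of scope.
* **Normalization**: better-annotated genes score systematically lower raw
  BMA similarity, so the pipeline reports
  `normalized = raw × (x − min + 1)/(max − min + 1)`, with `x` the larger
  term count in the pair and min/max the cohort-wide per-gene extremes
  (the `+1` avoids zeros).  This is the simplest form that is strictly
  increasing in `x`, leaves `raw` untouched at `x = max`, and the module
  keeps it pluggable — it should not be read as a literally published
  formula.
* **Shared PPI partners**: Jaccard index of the two partner sets with the
  pair members removed from each other's sets;
  `|A∩B| / min(|A|,|B|)` is available behind `method="min"`.

## Selection (NG86)

dN and dS follow Nei–Gojobori (1986) on codon-aligned, gap-free CDS pairs:
per-codon synonymous/nonsynonymous site fractions averaged over the two
sequences (changes creating a stop count as nonsynonymous, so
S + N = 3 × codons); difference counts for multi-substitution codons are
averaged over all substitution orderings, discarding orderings that pass
through a stop codon (if every ordering does, all are used with the stop
treated as an ordinary nonsynonymous state); the Jukes–Cantor correction
`d = −¾ ln(1 − 4p/3)` is applied to both proportions and is undefined
(missing) at p ≥ 3/4.  Codons containing ambiguity characters are skipped.
The implementation is table-driven; the test suite holds an independent
pathway-enumeration oracle and asserts exact agreement (1e−9) on all
61×61 single-codon pairs and on random sequences.  Note that NG86 with a
transition bias (κ > 1) underestimates ω: at true ω = 0.2, κ = 2 the
mean-dN/mean-dS recovery sits near 0.17, within the ±25% band used by the
calibration check.  Maximum-likelihood codon models are out of scope;
precomputed ortholog dN tables can be supplied instead.

## Statistics

* **Fisher's exact test**: conditional two-sided p by the probability-mass
  rule — the sum over all fixed-margin tables whose hypergeometric
  probability is ≤ the observed one (relative tie tolerance 1e−7); odds
  ratio is the sample OR `ad/bc` with ∞/NaN edge cases reported as such.
* **Wilcoxon rank-sum**: exact null distribution when min(n, m) ≤ 8 with no
  ties, otherwise the normal approximation with tie and continuity
  corrections.
* **Age-binned hypergeometric group test**: one bin per distinct age value;
  a bin is *valid* when both groups have ≥ 3 samples (configurable).  With
  K valid bins and q bins whose MD mean beats the ND mean in the expected
  direction (ties never count toward q), p = P(X ≥ q) for
  X ~ Hypergeom(2K, K, K), i.e. m = n = k = K.  The printed lower-tail
  form P(X ≤ q) is available behind `tail="lower"`; the upper tail is the
  default because it is the tail that measures enrichment in the direction
  of every claim.  The test refuses to run below 5 valid bins.
* **Complex co-membership**: a pair is a co-member if its genes share at
  least one protein complex; pairs with neither member in any complex count
  as non-co-members.  The resulting 2×2 tables (MD-pairs vs ND-pairs;
  WGD-pairs vs SSD-pairs) feed Fisher's test.

PD-labeled (polygenic) genes are held out of both the MD and ND groups by
default (`include_pd_as_md` reassigns them to MD).  No multiple-testing
correction is applied.

## Synthetic cohorts

The generator's defaults define the study conditions used by the test
suite.

* **Species tree**: a fixed 12-leaf vertebrate tree (human, chimp, macaque,
  mouse, rat, dog, opossum, chicken, frog, takifugu, zebrafish, ciona),
  ultrametric with approximate divergence times in Myr; the 10 nodes on the
  human path (ages 0, 6, 29, 90, 97, 160, 320, 360, 450, 600) are the
  possible duplication placements and hence the age bins.
* **Families**: each family duplicates at a node drawn uniformly from the
  human path (configurable weights); with probability 0.1 a second, more
  recent duplication nests inside the first copy, yielding 3 focal genes.
  Singleton families (one focal gene, all 12 species) provide the
  non-duplicate background.  Gene trees are loss-free copies of the species
  tree, so dating is exact by construction — passing the dating checks
  says nothing about robustness to gene loss or topological error.
* **Labels**: MD with probability 0.2 (0.15 for singletons, reproducing the
  duplicate-enrichment direction), PD with probability 0.05.  A pair (or
  family, for the codon process) counts as MD as soon as one member is MD.
* **Effect layers**: per closest pair — bivariate-normal expression with
  Pearson ρ 0.4 (MD) vs 0.2 (ND) over 36 tissues; GO term sets of 1–10
  leaf terms where the partner shares each term with probability 0.5 vs
  0.3 (the partner keeps at least the shared terms, and extras are drawn
  outside the first gene's set so the knob is the realized sharing
  probability); PPI partner sets of Poisson(12) degree sharing partners
  with probability 0.4 vs 0.2; complex co-membership 0.10 vs 0.18 (disease
  pairs less often in the same complex); ortholog dN drawn from Gamma
  distributions with mean 0.04 vs 0.07 (×1.4 for singletons).  In 3-gene
  families the third copy is generated *anchored* on its closest twin with
  the same class-dependent effects, so the truth table's per-pair effect
  class is generative for every pair.
* **Codon evolution**: a Goldman–Yang-style 61-state codon chain (HKY
  nucleotide rates, κ = 2, uniform codon frequencies, ω multiplier on
  nonsynonymous changes, ω 0.1 vs 0.3 by family class) run via the matrix
  exponential of the scaled rate matrix; stop codons are outside the state
  space, so no stop-rejection step is needed.  Pair divergence is
  t = 2 × 5·10⁻⁴ × age + 0.02 substitutions/codon (a floor so that age-0
  duplicates are not identical); CDS length 300 codons.
* **GO DAG**: a deterministic synthetic molecular_function hierarchy
  (root → 6 classes → 12 subclasses → 150 leaves, some leaves with two
  parents) plus a small biological_process branch so namespace and
  leaf-only filtering are exercised.  The hierarchy is deep and wide enough
  that two random leaves are usually semantically distant, as in the real
  ontology; a flatter DAG would let chance best-matches dominate the BMA
  score.  Term ids use a reserved synthetic GO:7xxxxxx range.

What the generator does **not** emulate: gene loss and incomplete lineage
sorting in gene trees, indels and codon-frequency bias in CDS evolution,
microarray noise models, annotation-depth bias between disease and
non-disease genes (term counts are class-independent, so the GO
normalization acts as pure multiplicative rescaling here), and incomplete
annotation coverage.  Passing the suite therefore demonstrates correctness
of the computations and calibration of the statistics under clean
conditions, not robustness to these real-data complications.

## Problem sizes and calibration of the checks

The test suite simulates at sizes chosen to characterize the estimators
well while keeping the default run practical: the type-I experiment uses
1,000 null cohorts of 200 families (each group test must fire at α = 0.05
in ≤ 7% of runs — the binomial 95% band around the nominal 5%, which the
discrete hypergeometric test undershoots); the power experiment uses 100
cohorts of 500 families at the default effect sizes (Δρ = 0.2,
ΔGO-overlap = 0.2, ω 0.1 vs 0.3) and requires the paper-direction
significant result in ≥ 90% of runs, scoring each metric by either of the
two comparisons the pipeline reports (age-binned group test, age-omitted
rank-sum).  A pilot showed the normalized GO score is the binding metric:
its age-binned group test alone sits near 85% power because the
depth-normalization multiplier is pure noise under this generator, while
the raw GO group test and all other metrics fire in ~100% of runs.
The ω-recovery experiment uses 500 pairs of 300 codons at t = 0.3; the
dating check uses 1,000 loss-free families and demands exact node and age
recovery.

## Known limitations

* NG86's ω bias under transition-biased evolution is inherited by design;
  absolute dN values are method-dependent.
* The dating module assumes loss-free gene trees; gene loss can make the
  LCA mapping overestimate ages.
* The Wang-similarity background level depends on DAG depth; comparisons
  across DAG versions are not meaningful.
* The hypergeometric group test treats age bins as exchangeable and
  ignores bin sizes beyond the validity threshold.
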