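# Methods

This note records the models implemented, the choices made where the
design was genuinely open, and what the synthetic data do and do not
establish about real data.

## Distance models

**Nucleotide.** The p-distance counts mismatches over sites where both
sequences have an unambiguous base (pairwise deletion; `-` and `.` are
both gaps, IUPAC ambiguity codes are treated as missing).  The
Jukes–Cantor correction d = −¾ ln(1 − 4p/3) is applied per pair.  Pairs
with p ≥ 0.75 have no finite JC distance; they are set to a configurable
cap `d_max` (default 10 substitutions/site) and flagged saturated rather
than left infinite, because the downstream double-centering step requires
finite entries.  Pairwise rather than complete deletion was chosen to
match the long-standing default behavior of distance programs on ragged
alignments and to avoid discarding whole columns for one gappy row.

**Protein.** Pairwise distances are maximum-likelihood estimates under
the JTT empirical model.  The bundled data file
(`data/jtt.txt`) carries the published symmetric exchangeabilities S and
stationary frequencies π; the rate matrix Q_ij = S_ij π_j is scaled so
−Σ π_i Q_ii = 1 (one expected substitution per unit branch length).
Because Q is reversible, D^{1/2} Q D^{−1/2} (D = diag π) is symmetric and
is eigendecomposed once with `eigh`; P(d) = exp(Qd) then costs one 20×20
congruence per evaluation.  The pairwise log-likelihood
l(d) = Σ_sites log(π_x P(d)_{xy}) is unimodal in practice and is
maximized by bounded Brent search on (0, d_max] to absolute tolerance
1e-6, which makes matrices bit-reproducible.  Identical sequences return
0; an optimum within tolerance of d_max is capped and flagged saturated.
No among-site rate variation or invariant-sites component is modeled at
the distance stage.

## Neighbor joining and bootstrap

NJ follows the standard Q-criterion agglomeration and is exact on
additive matrices (verified to 1e-9 in path length).  Two conventions are
fixed for determinism and downstream consumers: ties in the Q-criterion
resolve to the lowest index pair in current label order, and a negative
branch length produced by the join formulas is clamped to zero with the
deficit moved to its sister branch, preserving the joined pair's total
length.  The returned tree is unrooted (trifurcating seed node for
n ≥ 3).

Bootstrap support resamples alignment columns with replacement,
recomputes the distance matrix and NJ tree per replicate, and reports for
each internal edge of the *original* tree the percentage of replicates
whose tree contains the same leaf bipartition.  Supports are attached to
the original topology rather than a consensus tree, matching how
phylograms are usually annotated.  Replicate r draws from an independent
stream seeded by (seed, r), so results do not depend on execution order;
replicates in which some pair loses all comparable sites are skipped with
a warning, and more than 10% skipped aborts the run.

## Distance-covariance congruence test

The dependence statistic between two strain-indexed dissimilarity
matrices is the sample distance covariance computed directly on the
matrices: both are double-centered and dCov² = (1/n²) Σ Â∘B̂ (clamped at
zero before the square root).  The reported R is the distance correlation
dCor = dCov/√(dVar_A dVar_B), which lies in [0, 1]; dCor was chosen as
the normalized companion of the distance covariance, and a Mantel r is
available as a clearly labeled secondary output only.  If either dVar is
exactly zero the matrix carries no distance information and R is defined
as 0.  (Note that a matrix with all off-diagonal entries equal has small
but *nonzero* dVar under this V-statistic definition, because the zero
diagonal participates in the centering.)

The null distribution permutes the strain labels of one matrix, rows and
columns jointly — the exchangeability convention of distance-matrix
tests.  The Monte-Carlo p uses the add-one formula
p = (1 + #{T_perm ≥ T_obs})/(1 + n_perm), which is a valid p-value and
never returns 0; ties count toward rejection (conservative).  For n ≤ 8
an exhaustive mode enumerates all n! permutations and returns the exact
tail probability.  A minimum of n = 4 shared strains is enforced, below
which the permutation null is vacuous.  Because the double-centering
operator commutes with joint row/column permutation, permuted statistics
are computed from the pre-centered matrices; the test suite checks this
fast path against a naive double-loop oracle to 1e-10.

No multiple-testing correction is applied anywhere in the pipeline, and
the report should be read accordingly: across many gene-pair comparisons,
p-values in (0.001, 0.05] are suggestive rather than confirmatory.

## Homolog curation

Erm selection keeps hits at ≥ 35% identity (the boundary is inclusive)
and then excludes hits recognizable as the rRNA dimethyltransferase KsgA
— a universally conserved close relative — by genomic context: the ksgA
neighborhood is conserved across actinobacteria, flanked by IspE
(4-diphosphocytidyl-2-C-methyl-D-erythritol kinase), a TatD-family
deoxyribonuclease, and methionyl-tRNA synthetase.  A hit is called ksgA
when at least two of the three marker products occur within ±3 gene
positions, matched case-insensitively against a small synonym list.  The
2-of-3/±3 rule is this package's explicit formalization of a procedure
usually done by eye; both the window and the marker list are parameters.
Hits absent from the neighborhood table are retained but flagged
`context_known = False` and logged, so curation decisions are auditable.

ABC ATPase selection keeps hits at ≥ 40% positives and reduces to one
hit per genome — the "closest homolog" operationalized as maximal
bitscore, with ties broken by higher percent identity and then
lexicographic subject id.  Both filters are monotone: raising a threshold
never enlarges the selected set.

## Multi-locus concatenation

Five housekeeping protein alignments (rpoB, recA, atpD, dnaA, ftsZ) are
concatenated per strain at the alignment level (no re-alignment); strains
missing any required gene are dropped with a logged census.  The retained
set is the intersection across genes and is independent of gene order;
row order follows the first gene's alignment.  A strain with a fragment
row still counts as present — no length-fraction filter is applied, as
none is defined for the source procedure.

## Exact association tests

Fisher's exact test is computed from the hypergeometric law in exact
rational arithmetic (`fractions.Fraction` over `math.comb`), so p-values
carry no enumeration round-off; the two-sided p sums all tables with the
same margins whose point probability does not exceed the observed one
(the standard "by probability" rule).  A zero margin yields the
degenerate p = 1.  The gene co-occurrence test builds the 2×2 table of
joint presence and is one-sided toward co-occurrence by default — the
directional reading of "more often together than separately" — with the
two-sided version available by flag.

## Synthetic data generator

The generator produces every input the pipeline consumes, with the
dependence structure the analysis is meant to detect:

* **Species tree** — Yule pure-birth with waiting times Exp(k·λ); the
  expected root height is Σ_{k=2..n} 1/(kλ), which the tests check
  against simulation.  Taxon labels are assigned to leaves in *random*
  order: strain identity must carry no information about tree position,
  otherwise two independently simulated histories would be spuriously
  correlated through the labeling and permutation nulls would break (the
  type-I calibration test guards exactly this).
* **Horizontal transfer** — gene trees arise from the species tree by
  random SPR moves: a uniformly chosen subtree is pruned and regrafted
  onto a uniformly chosen valid recipient edge at a uniform feasible
  height, keeping the gene tree ultrametric.  Transfer is modeled at the
  topology level, not by sequence splicing, because the analysis consumes
  distances and topology-level transfer is the minimal sufficient
  mechanism.
* **Sequences** — root states from stationary frequencies, then site-wise
  Markov transitions P(rate·branch) along each branch.  Per-locus clock
  rates (`marker_rate` default 0.02, `protein_rate` 0.15 substitutions
  per site per unit tree time) reflect that a 16S marker diverges far
  more slowly than resistance proteins; with a unit clock, Yule trees of
  height 2–4 would saturate both JC69 and JTT distances and every
  statistic would degenerate.  The defaults put 16S distances in the
  ~0–0.15 range and protein distances in ~0–1.2, both comfortably within
  estimator range at the default lengths (750 nt, 250 aa).
* **Presence/absence** — per-strain joint Bernoulli for the two genes
  with specified marginals and log odds ratio, solved from the Plackett
  quadratic; the realized 2×2 table is recorded in the ledger.  Defaults
  mirror an isolate survey scale: marginal frequencies 7/90 and 18/90,
  log-OR 2.0 (clear positive co-occurrence).
* **Environment** — two covariates evolve by Brownian motion along the
  species tree plus independent Gaussian noise, then map onto soil-like
  scales (pH ≈ 6.2 ± BM, organic matter ≈ 12% ± 5·BM), spanning roughly
  the pH 4–8 and 3–21% ranges seen across contrasting soil sites.
* **Hit/neighborhood tables** — every gene-positive genome receives a
  qualifying hit (plus weaker qualifying and sub-threshold ABC decoys so
  best-per-genome selection is exercised); configurable decoy genomes
  receive sub-threshold methyltransferase hits or above-threshold hits
  embedded in a ksgA marker neighborhood.  The ledger records exactly
  which subjects curation must select, so the curation tests assert
  against generated truth rather than re-derived expectations.

All randomness flows from a single config seed through derived streams;
identical configs give byte-identical files on disk.

**What the simulations do not show.** The generator omits rate
heterogeneity across sites, indels and alignment error, gene duplication,
within-genome paralogy beyond simple decoys, non-ultrametric rate
variation across lineages, and any real biosynthetic-cluster structure.
Passing tests therefore demonstrate that the estimators and tests behave
correctly when their model assumptions hold, and that the pipeline
distinguishes vertical from horizontal regimes under those assumptions —
not that any particular historical dataset would reproduce specific
published correlation values, which depend on unrecoverable alignments
and database snapshots.

## Problem sizes and numerics

Simulation-backed checks use deliberately modest sizes chosen to give
stable Monte-Carlo estimates: 8×8 matrices for oracle agreement (50
pairs), n = 6 for exhaustive-permutation comparisons, 100–200 replicates
of n = 12–15 communities for calibration and regime recovery, 100
replicates for bootstrap support, and alignment lengths 500–3000 nt /
250–1000 aa.  Scalar ML optimization uses absolute tolerance 1e-6;
distance matrices print at 6 decimals (beyond JC/JTT estimation noise);
permutation ties use relative tolerance 1e-12.  Known limitation: the NJ
implementation is O(n³) in pure Python and is comfortable at the few
hundred taxa of these analyses but not intended for thousands.
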