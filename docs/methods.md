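# Methods

## Biosynthetic cost

Codon cost is additive over the three nucleotides. The default metric
counts nitrogen atoms per base — A=5, C=3, G=5, U=2 (ring and exocyclic
nitrogens; the ribose-phosphate backbone contributes none) — giving codon
costs between 6 (UUU) and 15 (AAA/AAG/AGA/GAA/...). Costs are defined on
the RNA alphabet; DNA input is transparently mapped (T→U). Relative cost
divides by the most expensive synonymous codon, so every family's maximum
is exactly 1. No authoritative per-nucleotide high-energy-phosphate table
ships with the package: energetic analyses must supply one as a TSV
(`read_cost_table`), and a clearly labeled placeholder (affine in the
nitrogen table) exists only to exercise energy-metric code paths. Codon
cost is independent of the cost of the encoded amino acid, which is out of
scope by construction.

## tAI and wobble pairing

The decoding weight of codon *c* is `W(c) = Σ_j (1 − s_j)·tGCN_j`, summed
over anticodons of the codon's box (identical first two codon positions)
whose position-34 base pairs the codon's third base. Pairing rules
(anticodon-34 : codon-3, penalty s):

| pair | s | note |
|------|-----|------|
| A:U, C:G, G:C, U:A | 0 | Watson–Crick |
| G:U | 0.41 | wobble |
| A:C | 0.28 | inosine-like |
| A:A | 0.9999 | inosine-like |
| U:G | 0.68 | wobble |
| U:U | 0.70 | superwobble |
| U:C | 0.95 | superwobble |

U:U = 0.70 and U:C = 0.95 are fixed constants of the analysis; the other
four default to the classical eukaryote-derived values and are
override-able (`default_rules(...)`), since optimized bacterial constants
vary between studies. The superwobble rules apply in all codon boxes; this
is the assumption that makes strategy-3 species (single U34 anticodon per
four-codon box) translatable. The lysidine-modified tRNA-Ile(CAU), which
reads AUA, is booked separately from the CAU pool (whose unmodified
members decode AUG) and is added automatically by `ile_cat_correction`
when more than one Met(CAU) gene is present — compensating for tRNA gene
finders that cannot distinguish the two isotypes. Pseudogene-flagged rows
and undetermined ("NNN") anticodons in tRNAscan-SE output contribute no
decoding capacity and are skipped with a warning.

Any sense codon with W = 0 is a hard error: a real genome must translate
all codons, and a zero weight would silently poison the geometric mean of
gene tAI. Normalized weights come in two flavors: global `w = W/max(W)`
(the classical tAI weight; used as the model's efficiency feature) and
within-family `rel` (relative translational efficiency; used for trade-off
plots and optimality coordinates). Both are invariant under uniform
scaling of copy numbers. Gene tAI is the geometric mean of `w` over
codons, excluding the terminal stop; internal stops are errors.

### Hypothetical inventories

`full` carries one copy of each of the 61 Watson–Crick anticodons.
`strategy1` removes all A34 anticodons (NNU codons read by G34 via G:U).
`strategy2` additionally removes C34 anticodons (NNG read by U34 via U:G)
— except where the corresponding NNA codon is a stop, so no U34 partner
exists: tRNA-Trp(CCA) is retained, as in real strategy-2 bacteria,
keeping UGG translatable. `strategy3` additionally drops G34 anticodons in
four-codon boxes, leaving a single U34 anticodon per box.

## The selection model

Within each synonymous family F,

    P(c | F) = exp(GC_b·n_GC(c) + S_c·cost(c) + S_t·eff(c)) / Σ_{c'∈F} exp(…)

with features: `n_GC` = number of G/C nucleotides over all three codon
positions, `cost` = absolute codon cost (atoms), `eff` = global tAI weight
`w`. Each feature convention is switchable (`build_features`: third-position
GC only; within-family relative cost/efficiency) so alternative published
parameterizations can be matched. Probabilities are softmax-normalized
within families, hence invariant to adding a constant to any feature —
absolute and centered features give identical likelihoods.

Fitting maximizes the multinomial log-likelihood of pooled codon counts
(genome-wide fits therefore weight genes by length). The optimizer is a
derivative-free Nelder–Mead simplex with 5 seeded multi-starts (origin
plus random points in [−2, 2]^k) and tolerance 1e−8 on the log-likelihood;
the likelihood is that of a conditional-logit model and is concave, so
multi-starts guard only against simplex stagnation. Model selection fits
all 7 non-empty subsets of {GC_b, S_c, S_t} (excluded parameters held at
0) and returns the AIC minimum, ties broken towards fewer parameters.
`fit_r2` is the squared Pearson correlation between observed within-family
frequencies and fitted probabilities across sense codons of families of
size ≥ 2, unweighted. Per-gene fits hold GC_b at the genome-wide estimate
and free S_c/S_t; genes with no multi-codon family observed are flagged
not-estimable rather than failing, and are excluded (with a logged count)
from downstream regressions.

## Pareto optimality geometry

Coordinates are per-codon means of (relative cost, relative efficiency),
so scores are length-comparable across genes and depend only on amino-acid
composition, not residue order. Because positions choose codons
independently, the achievable region is (1/L of) a Minkowski sum of
per-position option sets. The Pareto frontier (cheapest for given
efficiency) is built exactly by merging the edges of per-position convex
chains in slope order — the closed-form limit of a scalarization sweep in
which weight λ picks, per position, the option minimizing
λ·cost − (1−λ)·eff; the anti-frontier is the mirrored construction.
Non-convex pockets of the achievable set are unreachable by scalarization;
the score uses the convex frontier (a known limitation — a gene in a
pocket measures against the convex boundary).

d1 (to the Pareto frontier) and d4 (to the anti-frontier) are measured
along the fixed trade-off direction (−1, +1)/√2 — simultaneously cheaper
and more efficient — as intersections of that line with each polyline;
d1 + d4 is then the local frontier-to-frontier width and the score
`100·d4/(d1+d4)` a true relative position. A ray that misses a polyline
clamps to the nearest polyline endpoint. Degenerate cases: d1 = 0 (on the
frontier) and coinciding frontiers (e.g. poly-Met) both score 100.
Frontier-vertex and score equivalence against brute-force enumeration of
every encoding is asserted in the test suite for peptides up to length 6.

## Mutagenesis

`enumerate_snvs` produces all 3L single-nucleotide variants; classes are
determined purely by codon translation before/after (first codon: any
mutation leaving the permitted-start set is a start loss; a stop codon
mutating to another stop is synonymous with zero score change). Nonsense,
start-loss and stop-loss variants are excluded from both deleterious-
fraction denominators — their harm is not a cost-efficiency statement —
and carry no score delta. For scorable variants the delta is
optimality(mutant) − optimality(original), each sequence under its own
amino-acid constraint (non-synonymous changes rebuild the frontier for the
mutated composition, an O(families) update of the compositional chains).
Mutations are applied one at a time; exhaustive scanning is the default,
with seeded uniform sampling without replacement for long genomes.

## Statistical analyses

All regressions are OLS (statsmodels); quoted p-values are the regression
F-test p. Trade-off gradients regress within-family relative efficiency on
relative nitrogen cost across sense codons of multi-codon families
(singleton families are identically (1,1) and carry no information); both
axes switchable to absolute/global variants. Per-family classification is
"none" when all costs are equal or the slope is not significant at 0.05
(two-codon families classify by slope sign, as no significance test is
possible with two points). Expression association reports both linear- and
log-abundance fits, as expression spans orders of magnitude and either
scale is defensible. Rate association excludes species pairs with mean
Ks > 1 (saturation) or fewer than 1000 genes (configurable for small
synthetic cohorts); the filters commute. When separate cost-optimality and
efficiency-optimality covariates are available, the joint model is
compared to each single-factor model by ANOVA F-test.

## Synthetic data

The genome generator inverts the selection model: per gene, an amino-acid
sequence is drawn (uniform over the 20 amino acids by default; an
organism-like composition vector can be supplied — this shifts the
family-size mix, not correctness), then codons are sampled from the
within-family softmax at the gene's true parameters, with a start codon
prepended and a stop appended. Per-gene S_c/S_t can be coupled to a
log-normal latent abundance to emulate expression-dependent selection. All
generators are seeded and byte-reproducible.

Default study conditions: 500 genes × 300 codons at
(GC_b, S_c, S_t) = (0.4, −0.08, 0.10), echoing typical genome-wide
bacterial estimates. Parameter-recovery studies use the **strategy-2**
inventory: this is an identifiability decision made at design time — under
a full complement the tAI weight is ~0.8 correlated with codon cost within
families, giving an asymptotic SE for S_t of ≈0.036 at this problem size
(the design cannot resolve S_t to ±0.02), whereas strategy 2 decouples the
features (SE ≈ 0.012). It is also the more realistic condition: no
sequenced bacterium carries a full tRNA complement. For
mutagenesis-direction studies, genomes spanning low-to-high optimality are
produced by ramping the selection strength from 0 (neutral codon choice)
to strong joint cost/efficiency selection — the same mechanism that grades
optimality in real genomes. A construction that instead places top genes
exactly on the frontier is avoided: such genes saturate at score 100 where
most non-synonymous variants land exactly on the mutated composition's
frontier (delta 0), an artifact real genes do not exhibit.

What the generator does not emulate: site-level functional constraints
(RNA structure, splice/fold constraints), amino-acid composition bias
linked to expression, phylogenetic correlation between species, and real
mutation processes. Passing recovery tests therefore demonstrates
correctness of the estimator under the model's own assumptions, not
robustness to model violation in real genomes.

## Numerical choices and limitations

- Collinear frontier edges are merged by slope (tolerance 1e−12); ray-
  segment intersection uses an algebraic solve with ±1e−9 end tolerances.
- Scores are clipped to [0, 100]; fractions with empty denominators are
  reported as NaN rather than 0.
- QC criteria are checked in a documented order (length > 30 strictly,
  divisibility by 3, start codon ∈ {ATG, GTG, TTG}, terminal stop, no
  internal stop, unambiguous bases); each failing record carries exactly
  the first failing reason. The 500-gene minimum is a warning (and a
  refusal only for genome-wide fits), mirroring its role as a
  species-inclusion criterion.
- The wobble-penalty defaults are a documented stand-in where
  bacteria-optimized constants are not settled; the trade-off sign pattern
  (negative / positive / none across the three hypothetical inventories)
  is robust to ±0.1 perturbations of every configurable penalty, but the
  R² magnitudes of those regressions shift with the constants.
- Bayesian uncertainty on parameters, phylogenetic correction,
  orthology/alignment/Ka–Ks computation and tRNA gene prediction are out
  of scope; rate and abundance tables are consumed as precomputed inputs.
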