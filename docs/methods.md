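# Methods

This note records the models implemented in `caryogeo`, the estimators
and conventions chosen where several were defensible, and what the
synthetic data generator does and does not emulate.

## Data model and missing data

Alignments are fixed-length haploid sequences over `A C G T N -`; IUPAC
ambiguity codes are accepted on input and mapped to `N`. Two deletion
conventions coexist deliberately:

- **Pairwise deletion** for nucleotide diversity π: each pair of
  sequences is compared over its own gap-free, unambiguous sites and
  contributes `diff/valid`; π is the mean of these per-pair proportions.
  This matches the convention of per-locality diversity tables and keeps
  π comparable across localities with different amounts of missing data.
- **Complete deletion** for S, k̄, D, F_S, haplotype counts entering
  F_S, and mismatch distributions: sites with any missing value are
  dropped globally. Rationale: the coalescent nulls used for p-values
  are gap-free, and the observed statistic must be computed on the same
  footing as its null.

Haplotype identity is exact string match after normalization. Sequences
containing `N` are never merged with compatible unambiguous haplotypes:
merging rules under ambiguity are not identifiable from data, and the
conservative choice is deterministic. A species absent from a locality
is recorded as absent, not as a zero count; single-specimen localities
carry not-calculable markers (NaN / "n/a") rather than zeros.

## Diversity

Haplotype diversity uses the unbiased estimator
`H = n/(n-1) (1 - Σ p_i²)`. One printed-table quirk is worth noting: a
published row with n = 8 and two haplotypes reports H = 0.1250, which no
integer composition reproduces under either the biased or unbiased
estimator; the value is treated as a source-data quirk and not matched.

## Neutrality statistics

**Tajima's D** follows the standard constants a₁, a₂, b₁, b₂, c₁, c₂,
e₁, e₂; S = 0 is not calculable.

**Fu's F_S** sets θ̂ = k̄ and evaluates S′ = Pr(K ≥ k_obs) under the
Ewens sampling formula. The unsigned Stirling numbers of the first kind
are computed exactly with big integers (coefficients of the rising
factorial) and converted to logs once per n; the pmf is assembled in log
space and renormalized, keeping it usable to n in the hundreds.

**Simulation p-values** come from an internal Kingman coalescent
(time in units where a sample pair coalesces at rate 1). By default the
null is conditioned on the observed S — mutations are placed
multinomially on branches proportionally to length — because the
observed statistic then varies only through tree shape, mirroring the
usual practice of S-conditioned neutrality tests; conditioning on
θ̂ = k̄ (Poisson placement) is available by flag. The reported p is the
lower tail Pr(sim ≤ obs), the direction relevant for expansion, with
significance flags at 0.05 (D) and 0.02 (F_S); a two-sided p is also
returned. p-values use the (count+1)/(reps+1) estimator. The type-I
error of the D flag is checked against the 95% binomial envelope around
0.05 in the test suite (500 null replicates).

**Mismatch distributions.** Observed classes are complete-deletion
pairwise difference counts. The constant-size expectation is geometric,
`F_i = θ^i/(θ+1)^{i+1}`. The sudden-expansion expectation treats the
post-expansion size as effectively infinite: the class-j probability is
the pre-expansion geometric smeared by a Poisson(τ) number of mutations
accumulated since the expansion,
`F_j = e^{-τ} Σ_i (τ^{j-i}/(j-i)!) F̂_i(θ₀)`; a finite θ₁ variant is
provided and reduces exactly to the constant model at τ = 0. Parameters
(τ, θ₀) are fitted by least squares (coarse grid seeding a Nelder-Mead
refinement); no estimator is canonical here and least squares keeps the
fit free of distributional assumptions about class counts.

**Raggedness.** `r = Σ_{i=1}^{d+1} (x_i − x_{i−1})²` with the class
beyond the last observed one set to zero, so a single-class
distribution scores 1. The p-value is a parametric bootstrap: genealogies
are simulated under the fitted expansion (no coalescence during the
recent epoch, i.e. θ₁ → ∞), mutations placed at rate θ₀/2 per unit
branch length, and p = Pr(r_sim ≥ r_obs). A near-zero fitted θ₀ is
floored at 0.05 to keep the bootstrap defined for perfectly star-like
samples.

**McDonald-Kreitman counts.** Codons with missing data skip only the
affected sequences. Within-species polymorphic changes are the minimal
changes connecting the observed codons (minimum spanning tree over
Hamming distances), each edge classified synonymous/non-synonymous by
averaging over all minimal single-step pathways, excluding orderings
that pass through stop codons whenever a stop-free ordering exists. A
site is a **fixed difference** when the two species share no nucleotide
at it — the standard operational rule, which also handles codons that
are simultaneously polymorphic within one species; the fixed change is
classified between the majority codons of the two species, restricted
to the fixed sites. The reading frame defaults to the one minimizing
internal stops; pervasive stops (> 50% of codons) trigger a warning.
The default genetic code is invertebrate mitochondrial (NCBI table 5).
Counts can be fractional when pathway averaging splits a change between
classes. Positive selection is never indicated when Mn = 0.

## Parsimony networks and MOTUs

**Connection limit.** The probability that j observed differences over
L sites arose without superimposed change is modelled with per-site
Poisson change counts: a site differs iff its count is odd; parsimony
means every differing site changed exactly once and every identical
site not at all; the divergence parameter is moment-matched from j/L.
The limit is the largest j keeping this probability above the
confidence level (default 0.95; 7 steps at L = 590), and a single step
is always connectable. This is the package's own transcription of the
statistical-parsimony idea; an explicit user-supplied limit overrides
it.

**Construction.** Distance classes are processed in ascending order;
within a class, every pair whose endpoints lay in different components
at the start of the class is connected. This deliberately admits cycles
among equally parsimonious alternatives. Multi-step edges are expanded
with inferred zero-frequency intermediates so every edge spans one
mutation.

**Loop resolution** removes one edge per cycle, longest connections
first (an unequal-length alternative is never the parsimonious one;
this also makes the resolved network a minimum spanning network, which
the tests verify against exhaustive spanning-tree search). Among
equal-length alternatives the cascade is: retain links to
higher-frequency haplotypes, then to interior (degree > 2) nodes, then
geographically closer locality pairs (minimum great-circle distance,
when coordinates are supplied), then remove the lexicographically
smallest edge. The cited loop-breaking criteria carry no total order,
so the order is fixed here as above and every removal is logged,
including whether the lexicographic tie-break decided it.

**Nesting** works on the intermediate-expanded graph, grouping nodes
one mutational step inward from the tips, stripping assigned groups and
repeating until the level is exhausted; isolated leftovers form
singleton clades at their level and merge at the next (a worked
five-node chain nests as {A,B} {C} {D,E} at level 1 and one clade at
level 2). MOTUs are the clades of a user-chosen level restricted to
observed haplotypes, numbered by decreasing total frequency. The level
is a parameter, not automated: the right resolution is a judgment about
the spatial question being asked.

## Refugium localization reconstruction

Tips carry locality characters; haplotypes observed at several
localities get multi-state sets, which set-valued Fitch handles
natively. The bottom-up pass takes intersections where non-empty, else
unions; multifurcations keep the states attaining the maximal child-set
count (a safeguard — simulated and BEAST-style trees are binary). The
root set R of each genealogy contributes weight 1/|R| to each member
state; the relative probability score of a character is 100 × (summed
weights / number of trees), so scores always sum to 100. The ×100
percent convention matches how such scores are conventionally reported.
Tree samples are read from Newick/NEXUS, burn-in removed as a leading
fraction, and subsampled uniformly with a caller-supplied seed;
unrooted trees are rejected.

Equivalence between Fitch root sets and exhaustive minimal-labeling
enumeration is verified in the tests for every rooted binary topology
with up to 6 tips and up to 4 states. One subtlety the enumeration
makes explicit: a cherry-plus-outgroup tree with tip states {X},{X},{Y}
has MPR root set {X, Y} — the single change can sit on either root
edge — and the implementation reports exactly that tie.

**Bayes factors** are decimal-log (the Jeffreys grading —
substantial (½–1], strong (1–2], decisive > 2 — is a base-10 scale),
computed from harmonic-mean log marginal likelihoods evaluated stably
as −(logsumexp(−ℓ) − log N). The harmonic-mean estimator is known to be
high-variance; it is provided because it is the comparison the workflow
calls for, not because it is the best marginal-likelihood estimator.

## Synthetic scenarios

Genealogies come from msprime's structured coalescent with `ploidy=1`
(haploid-copy timescale: a pair in a deme of size N coalesces after N
generations on average — the mtDNA-relevant scaling, verified against
E[T₂] = N in the tests). Mutations are infinite-sites by default (each
mutation a fresh column; Watterson's E[S] = θ a₁ is verified), with a
finite-sites Jukes-Cantor option. Defaults mirror a short COI fragment:
L = 590 sites.

Preset parameters (chosen once, as the study conditions the generator
emulates):

- `refugial-expansion` — source deme Ne 500 (strong) / 2000 (weak);
  four colonies Ne 100 / 500 founded 300 / 1500 generations ago by mass
  emigration from the source; μ = 6×10⁻⁶ per site per generation;
  samples 15 (source) + 4×10. Colonies are young and internally
  coherent, deep coalescence happens inside the source, so the Fitch
  root state concentrates on the source and D/F_S trend negative.
- `sudden-growth` — one deme, present Ne 50 000 (strong) grown from 50
  at 300 generations ago (weak: 5 000 from 500 at 1 000);
  μ = 8.5×10⁻⁶; n = 50. This is the star-genealogy demography of the
  mismatch expansion model: strongly negative D and F_S, smooth
  unimodal mismatch.
- `island-constant` — four demes of Ne 1 000 with symmetric migration
  (10⁻³ / 10⁻⁴ per generation); structured but stationary.
- `single-panmictic` — one deme, Ne 1 000, n = 50; the null used for
  type-I calibration.

Two signals pull in opposite directions and are deliberately modelled
by different presets: a genealogy star-like enough to give ~100%
power for negative D carries almost no parsimony root-state
information (tip states are interchangeable on a star), while colony
monophyly that powers the source reconstruction adds structure that
damps D. `refugial-expansion` favors source recovery with a mild
negative-D trend; `sudden-growth` is the expansion-statistics
workhorse.

"Posterior-like" tree samples are independent draws from the scenario,
not MCMC output: they exercise the tree-sample contract (many rooted
genealogies with shared tips) without phylogenetic inference, and carry
no autocorrelation or estimation noise a real posterior would have.
The generator also omits recombination (appropriate for mtDNA),
selection, sequencing error, and rate heterogeneity among sites;
passing tests therefore validate the statistical machinery, not
robustness to those real-data features.

## Problem sizes and determinism

Every stochastic routine takes an explicit seed, and fixture export,
pipeline runs and subsampling are byte-reproducible under it. The test
suite uses the scales the methods are designed for: hundreds of null
replicates for calibration envelopes, 250-tree samples for RLR, 20
replicate scenarios for recovery rates, and exhaustive enumeration
oracles up to 6 tips / 6 haplotypes where exhaustion is feasible.

## Known limitations

- The connection-limit estimator is a fresh transcription of the
  parsimony-probability idea; its numeric limits can differ by a step
  or two from legacy implementations of the same idea (it is
  deliberately conservative, and overridable).
- Mismatch model fitting assumes the θ₁ → ∞ simplification that
  dominates practice; finite-θ₁ fitting is not exposed.
- McDonald-Kreitman pathway averaging can yield fractional counts for
  multi-hit codons; integer-only reporting would require an arbitrary
  rounding rule.
- Per-MOTU neutrality tests inherit the MOTU delimitation; different
  nesting levels give different per-unit statistics.
- No nested-clade hypothesis testing, median-joining construction,
  tree inference, or distribution modelling: inputs beyond alignments,
  tables and tree files are out of scope.
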