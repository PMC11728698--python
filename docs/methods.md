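# Methods

## Problem setting

A taxonomic profiler estimates, per metagenomic sample, a vector of
species relative abundances against its own catalogue ("native feature
space"). To compare profilers that use different catalogues, every output
is translated into one shared catalogue ("common feature space") through a
*feature mapping* — a weighted many-to-many correspondence produced
upstream (e.g. by classifying each native feature's marker genes against
the common catalogue). `profspace` takes the mapping as an input; building
one is out of scope.

## Projection

Given table X (features × samples, relative abundances) and mapping
entries (native n, common c, weight w) with Σ_c w(n, c) = 1 per native
feature, the projected table is Y[c] = Σ_n w(n, c)·X[n] over mapped
natives. Operations apply in the fixed order **split → sum → drop →
renormalize**; only drop-before-renormalize is semantically forced (the
converted columns must be re-closed to 1 after omissions), the rest is a
documented convention — the three first steps commute, so the order does
not change the result. Per sample, the pre-normalization projected mass
plus the dropped mass equals the input mass to within 1e−9
(property-tested and re-measured by the acceptance script).

Accounting: *lost abundance* is the summed abundance of dropped native
features per sample; *lost features* counts only dropped features with
nonzero abundance in that sample, so counts differ across samples. A
sample that loses all its mass is left all-zero and flagged rather than
renormalized (renormalizing 0/0 has no meaningful answer). An optional
species-rank filter treats every mapping entry whose common target is not
labelled `species` as unmapped; rank labels are passed explicitly (or
taken from the native table), and features without a label pass through.

## Metric suite

"Present" means abundance strictly greater than 0 — no detection
threshold; projection and simulation emit exact zeros, so support sets are
well defined.

- **Sensitivity/precision** are functions of the TP/FP/FN support counts
  only; a zero denominator yields an *undefined* value (NaN), which
  propagates and is excluded from medians with the exclusion count
  reported — never an exception, never a silent 0.
- **FPRA/FNRA** weight the same error sets by abundance mass; both require
  normalized columns (within 1e−6).
- **Shannon entropy** is in natural log. Richness/Shannon are reported as
  estimate − reference differences.
- **Bray–Curtis**: Σ|u−v| / Σ(u+v); undefined when both vectors are
  all-zero.
- **Weighted UniFrac** (normalized form): per branch, the abundance below
  it is the sum over descendant leaves; d = Σ b|u−v| / Σ b(u+v) ∈ [0, 1].
  Implementation precomputes a branch × feature incidence table per tree
  (cached), so repeated calls cost one matrix product. Features absent
  from the tree are dropped and the vectors re-closed, with a warning
  (strict mode raises instead). On a star tree with equal branch lengths
  the metric provably collapses to Bray–Curtis — used as a test oracle.
- **Aitchison**: zeros replaced multiplicatively (each zero → δ, nonzero
  entries scaled by 1 − zδ, preserving closure; error if zδ ≥ 1), then
  Euclidean distance of clr-transformed vectors. Default δ = 1/D², D the
  number of features in the shared space — the conventional default of
  compositional-data software; exposed as a parameter since no single
  value is canonical.
- **Medians** over an even number of samples use the midpoint of the two
  central order statistics (numpy's default).

All three distances are verified against independent brute-force
implementations (naive loops; UniFrac by explicit per-edge descendant-set
enumeration) to 1e−9 on random instances, and cross-checked against
scipy/scikit-bio.

## Community structure

Distance matrices over all sample pairs are computed with vectorized
routines that are algebraically identical to the single-pair metrics
(equality asserted in tests); weighted UniFrac reduces to Bray–Curtis on
branch-length-weighted branch-mass vectors, which is how the pairwise
path computes it.

Distance matrices are not probability distributions; to form the inputs of
the Jensen–Shannon divergence each matrix's upper triangle is normalized
to unit sum (the repository's convention — the diagonal is identically
zero and the lower triangle duplicates the upper). JSD uses the mixture
m = (p+q)/2 in the denominator of both KL terms, natural log, 0·log 0 = 0;
the result lies in [0, ln 2]. A literal symmetrized KL form D(p‖q) (which
is unbounded and infinite on disjoint supports, and not the
Jensen–Shannon construction) is available behind `literal_kl=True` for
comparison only. Divergence, not its square root, is reported. Tool
rankings are ascending in JSD with ties sharing a rank.

## Confusion mining

For a candidate pair (fn, fp), a sample is *eligible* only when
ref[fn] > 0, est[fn] = 0, ref[fp] = 0 and est[fp] > 0 — the pair is
simultaneously a false negative and a false positive there; in any other
sample at least one member is not actually an error, so the sample carries
no evidence. Candidates are enumerated from per-sample FN × FP incidence
(pairs with zero eligible samples can never qualify, so the full
|features|² scan is avoided) and eligible-sample counts for all pairs are
obtained with one boolean matrix product. Defaults: ≥ 25 eligible samples
and Pearson r strictly greater than 0.5 (both exposed). Pairs with fewer
than 3 distinct values in either abundance series are skipped (degenerate
correlation) with a logged note. Both directions of a symmetric pair are
reported as distinct records, since they qualify on different sample
subsets. The implementation is verified against an all-pairs brute-force
oracle with a textbook two-pass Pearson.

## Synthetic data generator

The generator emulates *profile-level* structure of a realistic
gut-microbiome benchmark; it deliberately does not simulate reads,
sequencing error, or genome selection — so passing tests demonstrate the
correctness of the evaluation machinery, not the read-level behaviour of
any real profiler.

Ground truth: per sample, richness ~ round(Normal(R, R/10)) clipped to
[1, n_features], features chosen uniformly, abundances i.i.d.
LogNormal(μ, σ) closed to sum 1. Defaults: 343 samples, a universe of
1000 species, R = 200, σ = 1 — a long-tailed community whose median
richness ≈ 200 and Shannon diversity ≈ ln(200) − σ²/2 ≈ 4.8 nats, the
order of magnitude of real gut profiles. (Per-sample entropy can never
exceed ln(richness), which bounds what any closed composition of ~200
species can reach.)

Profiler error model, applied in the fixed order **confusion → dropout →
FP injection → noise**, then re-closure:

1. *confusion* — each configured (source, sink, fraction) moves that
   fraction of the source's abundance to the sink (the sink may be absent
   from the truth universe); emulates catalogue sibling mismatches;
2. *dropout* — a present feature is dropped with probability decreasing
   linearly in log-abundance from `dropout_rate_at_min` at the sample
   minimum to 0 at the maximum (rare species are harder to detect); when
   all nonzero abundances are equal the probability is 0 (the linear rule
   is undefined there);
3. *FP injection* — Poisson(rate) absent features appear, abundances drawn
   log-uniformly between the sample's minimum and median nonzero truth
   abundance (false positives live in the low tail);
4. *noise* — multiplicative exp(Normal(0, σ)) on surviving entries.

With every rate at zero the output is bit-for-bit the truth. Mapping
generation: round(unmapped_fraction·n) features unmapped, then
round(split_fraction·rest) split 0.5/0.5 over two targets drawn from the
one-to-one pool (which also creates many-to-one targets), remainder
one-to-one; both fractions zero gives a pure renaming bijection. Trees:
successive random joins into a rooted binary topology, branch lengths
i.i.d. Exponential(mean 0.1). Every generator is a pure function of
(config, seed); independent seed streams are derived per generator.

## Reporting

Similarity transforms map each metric onto [0, 1] with higher = better:
1 − |u−v|/(u+v) for richness and Shannon (applied to the scenario's median
truth u and median estimate v), 1 − d for Bray–Curtis/UniFrac, TPRA =
1 − FPRA, and identity for sensitivity/precision. The Aitchison distance
and FNRA are summarized as medians but not given similarity axes (no
bounded transform is standard for an unbounded distance; FNRA is the
mirror of information already on the sensitivity axis). No composite
single score is computed — rankings are per metric.

## Problem sizes and numerical choices

The packaged property checks use: 100 random (table, mapping) instances up
to 200 features × 30 samples for mass conservation; 200 random trees with
≤ 12 leaves for metric-oracle agreement (1e−9); the full 343-sample,
1000-feature scenario for perfect-profiler recovery; 20 replicates of
80 samples × 120 features with 5 injected confusion pairs (fraction 1.0,
σ = 0.1) for confusion recovery; 20 seeds × 3 levels of each error rate at
40 samples × 400 features for monotone degradation; and 60 samples ×
600 features for the archetype comparison. These sizes exercise every code
path at the study's structure while keeping a full run in seconds.

Perfect-profiler distances are asserted ≤ 1e−12 rather than exactly 0:
the identity projection re-closes each column once in floating point,
which perturbs values at the last bit. Support-based quantities
(sensitivity, precision, richness difference, FPRA/FNRA) are exact and
asserted exactly.

## Known limitations

- The simulator draws features independently and identically across
  samples; real cohorts have correlated prevalence structure, sample
  covariates and compositional interactions the generator does not model.
- Error modes are independent of phylogeny (except explicit confusion
  pairs); real profiler errors cluster on related taxa.
- Mappings are inputs; the framework cannot assess how good a mapping
  itself is beyond the lost-mass accounting.
- Evaluation is species-level only; no genus/family aggregation and no
  unweighted UniFrac.
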