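# Methods

## Model and procedure

`qcoexp` screens a gene × condition expression matrix for partners of a
set of bait genes in four steps.

1. **Qualitative discretization.** Each gene's profile is ranked across
   conditions; the lowest r·⌈qn⌉ conditions receive negative levels, the
   highest r·⌈qn⌉ positive levels (r rank chunks of ⌈qn⌉ per side, the
   most extreme chunk at ±r), and the remainder 0. Only ranks matter, so
   the representation is invariant under monotone transforms of the
   normalized data and insensitive to per-gene scale. Ties at the
   quantile cut are resolved conservatively: a condition is non-zero only
   if its value lies strictly beyond the first interior order statistic.
   A constant gene therefore discretizes to all zeros, and tied runs never
   inflate the extreme set; within the extremes, chunks are filled in
   stable (value, condition-order) order so output is deterministic.
   Missing values are excluded from ranking and set to level 0; genes
   missing more than `max_missing` (default 20%) of conditions are
   rejected.

2. **BF scoring.** The pairwise score is the number of conditions with
   identical non-zero levels (same-sign mode; an allow-opposite mode also
   counts exactly opposite levels and reports the majority sign). The
   matched condition set is retained as the edge's *support*; per bait,
   partners are grouped into modules by greedy support intersection at a
   consistency level c: seed with the highest-BF edge, admit a partner if
   its support covers ≥ c of the group's current condition set, shrink to
   the intersection.

3. **Permutation significance.** The partner vector is permuted across
   conditions B times (margins fixed); the closed-form null mean is
   Σ_k n_k(a)·n_k(b)/n over non-zero levels. Two tail estimators are
   offered. The *conservative* estimator is the add-one-smoothed
   (1 + #{BF\* ≥ bf})/(1 + B). Because BF is a small discrete count
   (null mean ≈ 0.67 at q = 0.06, n = 93), its achievable tail
   probabilities are far apart (≈ 0.14, 0.03, …) and the conservative
   estimator realizes a false-positive rate well below nominal (measured
   ≈ 0.016 at α = 0.05; a mid-p variant still only reaches ≈ 0.034). The
   *randomized* estimator — the classical randomized p-value for discrete
   statistics, p = P̂(BF\* > bf) + U·P̂(BF\* = bf) with U uniform — is
   exactly uniform under the null (measured FPR 0.046–0.048 at α = 0.05
   over 2000 pairs) and is the screening default. U is drawn from the
   pair's own RNG stream, so results remain deterministic.

4. **Downstream analysis.** Called edges are assembled into an annotated
   undirected graph (optionally restricted to TF partners; bait–bait
   edges flagged), extended by screening further bait sets (idempotent
   and order-independent for a fixed seed), summarized as TF-family
   counts and per-TF candidate rankings, intersected with DE lists,
   overlaid across species through BLAST best hits (Jaccard of
   bait-neighborhoods under a bait correspondence), and tested for
   functional-bin over-representation with one-sided Fisher exact tests
   and Benjamini–Hochberg step-up control (significance at FDR ≤ 0.1).

## Parameters

| parameter | default | meaning |
|---|---|---|
| q | 0.06 | fraction of conditions called responsive per extreme per rank; the biclustering literature's default for microarray compendia. Raise toward the expected prevalence of condition-specific responses (e.g. 0.25 when modules span a quarter of conditions) |
| r | 1 | non-zero ranks per sign; r = 1 records only direction, r ≥ 2 grades response strength |
| sign_mode | same-sign-only | opposite-regulation detection is opt-in |
| min_bf | 0 | absolute floor on the matched-condition count; the main precision control in dense screens |
| alpha | 0.01 | level for the permutation p |
| n_permutations | 1000 | permutations per pair; p-value granularity 1/(B+1) |
| tie_break | randomized | tail estimator (see above) |
| consistency c | 0.95 | support-overlap fraction for module grouping |
| BLAST max_evalue / min_identity / mode | 1e-10 / 0 / best-hit | homolog-map thresholds; reciprocal-best available |
| FDR threshold | 0.1 | Benjamini–Hochberg significance cut for enrichment |

Edge calling uses `bf >= min_bf` **and** `p <= alpha`. The defaults are a
permissive starting point, not a validated operating rule; for planted-
truth benchmarks the package calibrates `min_bf` from the permutation
null of representative margins (`calibrate_min_bf`) at a chosen per-pair
false-positive budget.

## The synthetic generator

`SyntheticSpec` draws per-gene baseline means from N(8, 2²) (log2-scale
microarray intensities) with iid N(0, noise_sd²) noise across conditions,
then adds a constant shift of `effect_size · coherent_sign` to each
module's bait and partners on exactly the module's condition subset.
Defaults describe the screening study conditions this package targets:
500 genes × 93 conditions, 14 bait-anchored modules of 5 partners on
random quarter-size subsets, effect 2 × noise_sd. Shifts are additive
because discretization is rank-based and only ordering matters. The
boundary noise_sd = 0 is allowed: baselines are then exactly tied, ties
discretize to zero, and a planted pair's BF equals its subset size — the
construction oracle used in tests.

**What the generator does not emulate, and what that implies.** Real
compendium profiles carry gene-specific structure outside any shared
module — each gene responds to its own private condition sets — and
array-level artifacts (probe effects, batches). The generator's
background is pure iid noise. Two measured consequences, reproduced by
`scripts/acceptance.py` and asserted (and honestly failed) by two
acceptance tests:

- *Recovery at the default settings is noise-limited.* A 2σ shift on 23
  of 93 conditions puts a shifted condition into a gene's top-⌈qn⌉ rank
  set with probability ≈ 0.76 at the matched q = 0.25, and rank-set
  membership is independent between genes elsewhere, so a true pair's BF
  (≈ 21.9 ± 2.8) overlaps the permutation null (≈ 12.4 ± 2.8).
  Measured over 10 seeds with the BF floor calibrated to a 5% false-edge
  budget: sensitivity ≈ 42–44% at ≈ 3–4% false edges; no q in 0.12–0.40
  and no threshold achieves ≥ 90% sensitivity at ≤ 5% false edges. The
  scenario's information content is not the limit (a subset-aware t-test
  would separate at ≈ 8σ); the qualitative reduction pays for its
  robustness and subset-discovery ability with rank noise.
- *A constant planted shift is a global-covariance signal.* Its expected
  Pearson correlation is e²f(1−f)/(e²f(1−f)+1) ≈ 0.43 at e = 2,
  f = 0.25 — about 4 null SDs at n = 93 — so Pearson ranks planted
  partners essentially as highly as BF does (median percentile ≈ 99.6 vs
  ≈ 99.5). Demonstrating the condition-subset advantage of qualitative
  matching requires mean-zero within-subset co-variation plus
  gene-specific variation elsewhere, which this generator deliberately
  does not model. Passing and failing tests on this generator accordingly
  speak to calibration, determinism and construction correctness, not to
  superiority over global correlation on real compendia.

## Numerical and design choices

- **Per-pair RNG streams.** The permutation stream for a pair is seeded
  by (user seed, blake2b(bait), blake2b(partner)), so screens are
  reproducible, order-independent, and stable under gene subsetting.
- **Skip rule.** Pairs below `min_bf` are never permuted (pure
  optimization: they cannot be called); with the conservative estimator a
  BF of 0 short-circuits to p = 1 exactly.
- **Tie-breaks.** Edges sort by (bait order, descending BF, partner ID);
  module grouping admits candidates in that order; best-hit homolog
  selection breaks e-value ties by higher bitscore then lexicographic
  subject ID; probe→gene collapse keeps the max-BF (then min-p) probe.
- **Degenerate inputs.** Constant genes discretize to zero everywhere and
  are excluded from Pearson comparison with an explicit error (NaN in
  bulk tables); empty networks refuse to export; empty bait lists,
  stray gene-set members and out-of-range p-values raise validation
  errors naming the offender.
- **Library use.** Fisher tail probabilities come from scipy's
  hypergeometric distribution, BH adjustment from statsmodels, Pearson
  from scipy, graph handling from networkx; the test-suite cross-checks
  each against independent enumeration or hand computation.
- **Problem sizes.** Test and acceptance runs use the defaults above
  (10-seed recovery, 10⁴ null pairs for the mean, 2000 pairs for FPR,
  500 null-enrichment replicates, full Fisher enumeration to N = 12);
  the whole suite completes in well under a minute on one CPU.

## Known limitations

- The BF definition counts non-zero level agreement only. Published
  screens of this style report BF values up to the full sample count,
  which a sparse-extreme discretization cannot produce; those values are
  only reachable if zero-level agreement also counts or the responsive
  fraction q is large. The non-zero-only definition is retained because
  its permutation null has the clean closed-form mean used for
  calibration.
- Only bait-anchored screening is implemented — no full all-pairs
  biclustering (seed-and-expand), no mutual-rank/Spearman/partial
  correlation networks, no GO-DAG-aware enrichment propagation, and no
  upstream normalization or DE calling; the tool consumes normalized
  matrices and finished DE lists.
- The randomized p-value trades a small amount of per-pair repeatability
  (the U draw) for exact calibration; with the conservative estimator,
  calls are reproducible in the strictest sense but realized error rates
  are well below nominal, costing power at fixed α.
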