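# Methods

## Problem setting

Given a binary target vector *T* over *n* observations and *m* binary
features *X₁…X_m*, the package labels each feature's statistical relation
to *T* through conditional-independence (CI) tests at level α, and reports
the causal neighbourhood (direct ∪ joint) and Markov blanket (plus
conditional ∪ conditional_joint). The intended data regime is the one that
motivates the method: features correlated up to ~0.75 among themselves,
a sparse target (~10% positive), and weak target–feature coupling
(correlations ~0.2), at sample sizes of a few hundred.

## Conditional-independence testing

Tests are stratified 2×2 tests of Xᵢ vs *T* within each realized
assignment of the conditioning set. Two statistics are available, summed
over strata: the Pearson chi-square without continuity correction and the
G statistic 2·Σ n·ln(n·N/(n_r·n_c)); strata with a zero marginal
contribute 0. Significance comes from a Monte-Carlo permutation null that
permutes Xᵢ *within each conditioning stratum* while *T* stays fixed,
which preserves the conditional null exactly. Because both statistics
depend on a stratum's table only through its (1,1) cell once margins are
fixed, the within-stratum permutation distribution of that cell is
hypergeometric; the implementation samples it directly (vectorized over
all B resamples) rather than materializing permutations — an identical
null, orders of magnitude faster. The p-value uses the add-one estimator
(1 + #{stat_b ≥ stat_obs}) / (B + 1), so p ∈ [1/(B+1), 1] and is never 0.
B defaults to 5000. Ties are counted with a 1e-12 tolerance. Discreteness
makes the test mildly conservative at small n (empirical type-I ≈ 0.04 at
nominal 0.05 for n = 250); the suite checks the rate stays within 99%
binomial bounds of the nominal level.

Degenerate inputs: if Xᵢ or *T* has zero variance within every stratum
the statistic is 0 and p = 1 (verdict independent), so constant columns
fall out of candidate sets silently rather than erroring.

### Power control

Two rules limit low-powered tests, both driven by `min_stratum_count`
(l, default 10):

* **gate** — a test is performed only when every realized conditioning
  stratum holds ≥ l observations (default reading); a gated-out test is
  recorded with `performed = False` and the conservative verdict
  *dependent*. A `gate_mode="total"` switch offers the alternative reading
  n ≥ l·2^|S|.
* **conditioning-set cap** — k = ⌊log₂(T_min / l)⌋ floored at 0, where
  T_min is the minority count of *T*. For the 310-observation regime with
  ~10% positives this gives k = 1, i.e. only marginal and single-variable
  conditioning tests.

## The searches

All three searches share one engine over a pluggable CI test (the
Monte-Carlo test bound to data, or a d-separation oracle bound to a known
network for asymptotic analyses).

1. **Marginal screen.** C = {i : Xᵢ ⊥̸ T at α}, all m tests recorded.
2. **Spouse capture** (blanket search only). Every feature outside C is
   tested given each single member of C; those turning dependent join the
   candidate set, remembering their *activators* (the conditioning
   variables that made them dependent).
3. **Elimination.** For n = 1, 2, … all size-n subsets of the current
   candidate set are enumerated (per tested variable, excluding itself);
   a variable found independent given any subset is removed, with all its
   separating sets recorded. Within a round, tests are evaluated against
   the candidate set as it stood at the round start and all subsets are
   tested (no short-circuit), so results are independent of enumeration
   order; removals apply at round end. The loop stops when
   n > min(|C|−1, k). Captured candidates are removable only by sets
   containing at least one of their activators — their dependence is
   conditional by construction, so only supersets of an activating context
   are informative — and their activators stay available to their
   conditioning pool even after elimination.
4. **Blanket consistency pass** (blanket search only). Eliminated
   variables are re-tested against the full retained set (grow to a
   fixpoint); every retained variable is then re-checked in the full
   retained context, captures additionally conditioned on their activators
   (shrink to a fixpoint). Rescued variables are labelled conditional;
   demoted ones indirect/none. Both phases require a performable test: the
   gate and the k cap apply, so at desk-scale sample sizes the pass is
   inert and the result is plain elimination plus the pattern rescue below.
   Asymptotically (oracle test) the pass is what makes the blanket search
   exact: re-opening colliders catches spouses eliminated early, and
   conditioning on the full blanket removes false survivors whose
   separator had been eliminated. The suite verifies exact labels on
   every DAG with ≤ 5 nodes (29,849 networks).
5. **Pattern rescue.** Among variables still eliminated: a pair of
   marginally dependent variables whose recorded separating sets each
   contain the other is relabelled **joint**; the analogous pair among
   captured (marginally independent) candidates is **conditional_joint**.
   The stricter "every separating set contains the partner" reading is
   used. A variable joins at most one pair; ties are resolved toward the
   pair with the largest minimum marginal dependence strength (smallest
   worse marginal p), then lexicographically. Pattern detection operates
   on the recorded trace only, never on fresh searches.

The basic search (`ncpc`) is steps 1, 3, 5 (joint only); the baseline
(`pc_local_baseline`) is steps 1 and 3. The basic search is not
asymptotically correct when conditional structure exists — it can retain a
variable that only a spouse explains away — and equals the blanket search
exactly when the target has no spouses (verified exhaustively on 4-node
networks). At finite samples the blanket search's larger candidate pool
also gives the elimination more potential separators, so its blanket is
not guaranteed to be a superset of the basic search's neighbourhood
replicate by replicate; containment is an asymptotic property.

Multiple-testing correction (off by default, matching the benchmark
protocol of running all algorithms uncorrected): with
`correction="bh"|"by"`, verdicts within each test batch (the marginal
screen; each elimination round) are taken from step-up-adjusted p-values;
raw p-values stay in the trace.

## Display graph

The direct-dependence graph is display-only. Attachment edges (target to
blanket member) carry the variable's weakest supporting p-value (the
maximum p over performed tests that kept it dependent); removal edges
(separator ⊸ removed variable, dot-headed) carry the p of the first
removing test. Conditional variables attach to their activators, giving
the undirected path target–child–spouse; pattern pairs and their
attachments are grey (inconsistent). Feature–feature edges are classified
by an auxiliary test of Xᵢ vs Xⱼ given *T* — dashed when conditionally
independent, solid otherwise; auxiliary tests reuse the same Monte-Carlo
machinery (or the oracle) and never feed back into labels. A conditional
pair with no blanket activator would be drawn as dotted, disconnected
nodes (the non-faithful signature); a rescued conditional without capture
evidence falls back to a direct target attachment to keep the blanket
reachable by undirected edges.

## Synthetic benchmark

The generator emulates the motivating data panel:

* **Network** — 15 nodes in a random topological order; parent counts
  Binomial(2, 0.75) (mean 1.5, max 2) truncated to available
  predecessors; parents uniform over predecessors; CPT entries i.i.d.
  Beta(2, 2). The Beta parameters were calibrated once against the
  printed operating characteristics below and frozen. Note the first two
  nodes of any topological order are structurally capped, so the realized
  overall parent-count mean is ≈ 1.36 while unconstrained nodes average
  exactly 1.5; networks carry their generation order so this is
  measurable.
* **Target** — noisy AND of the two designated neighbours: each input is
  read out stochastically (P(R=1|x=1) = 0.5, P(R=1|x=0) = 0.1, modelling
  interference by unmodelled factors), the AND output is flipped with
  false-positive rate 0.01 and false-negative rate 0.2 (reporter noise).
* **Time scenario** — a chosen triple (in topological order) is rewired
  into a chain X1→X2→X3; X1 keeps its original parents, X2/X3 keep their
  original children. Chain CPTs are solved analytically: for parent
  marginal p and requested correlation r, P(1|1) = p + r(1−p),
  P(1|0) = p(1−r), which preserves the marginal along the chain and
  makes the end-to-end correlation r12·r23 (the adjacent correlations are
  set equal; the original coupling of r13 to the requested levels is not
  specified, so the symmetric chain is used).
* **Hidden scenario** — the triple instead receives a common Bernoulli(½)
  hidden cause H with CPTs pᵢ ± √r·sᵢ, preserving each marginal and
  giving all three pairs correlation r. This is only achievable for
  marginals in [r/(1+r), 1/(1+r)]; the rewiring errors outside that range,
  and the benchmark driver passes marginals clipped into it (at r = 0.75
  the three variables are effectively centred near ½).

Operating characteristics at the defaults, measured by the acceptance
script over 200 replicates of n = 1000 at the real-data-like correlation
setting 0.5: ~10% active targets, target–input correlation ≈ 0.23 (within
the intended 0.17–0.25 band), and sample correlation 0.75 at the
strongest setting. What the generator does *not* emulate: real binding
data's spatial/temporal autocorrelation structure beyond the three-node
scenario, anti-correlated profile pairs, annotation errors, and
class-imbalanced multi-class targets — so passing benchmarks demonstrate
robustness to the modelled confounding only.

`run_benchmark` scores each algorithm's predicted neighbourhood
(direct ∪ joint) against the ground truth {X1, X2}: a replicate is
correct iff there are no false positives and no false negatives;
precision TP/(TP+FP) (replicates with no predicted positives excluded as
undefined rather than coerced); recall TP/(TP+FN). Confidence intervals
on the correct rate are normal approximations. The suite checks the
qualitative ordering at the hard corner (correlation 0.75, n = 300,
100 replicates): joint detection ≥ plain elimination ≥ PC-style baseline,
with a strict improvement over the baseline.

## Enrichment

For ≤ 6 chosen features, every realized presence/absence pattern is
compared between the class (T = 1) and the rest by a two-sided Fisher's
exact test on (pattern-in-class, pattern-in-rest, other-in-class,
other-in-rest), Benjamini–Hochberg adjusted across the patterns tested,
retained below an FDR threshold (default 0.15), with direction from the
sign of the frequency difference. Sidedness is a flag; two-sided is the
default since both enrichment and depletion are of interest.

## Numerical and design notes

* All randomness flows from numpy Generators seeded by the configuration;
  identical (data, config, seed) give byte-identical results including
  trace order. Benchmark replicates use spawned `SeedSequence` children.
* The engine memoizes CI tests within a run, so repeated queries (e.g. in
  the consistency pass) are answered consistently and recorded once.
* Exact network quantities (marginals for CPT calibration, the CI oracle
  used in tests) come from joint enumeration over ancestral closures,
  guarded to ≤ 20 nodes; d-separation uses the standard reachability
  algorithm and is cross-checked against both networkx and brute-force
  CI enumeration.
* Desk-scale defaults keep the full test suite within a couple of minutes:
  the exhaustive oracle check enumerates all DAGs with 3–5 nodes, the
  benchmark ordering check uses 100 replicates at n = 300, and the
  calibration checks use 200 replicates at n = 1000.

## Known limitations

* Only complete binary data; missing values and continuous features are
  rejected (the k-cap rule would extend to continuous features, but the
  tests here are contingency-table based).
* The blanket consistency pass needs sample sizes large enough to pass
  the power gate when conditioning on the whole retained set; below that
  the blanket search relies on the pattern heuristics and inherits their
  finite-sample behaviour.
* Joint/conditional-joint patterns are heuristic rescues of a
  mathematically inconsistent signature; they deliberately trade a small
  precision loss for a large recall gain in the correlated regime.
* No hidden confounders or cycles are assumed within the target's Markov
  blanket; the hidden-cause scenario exists precisely to measure behaviour
  when that assumption fails.
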