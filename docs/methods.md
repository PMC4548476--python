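# Methods

## Model and data representation

The package works under the standard neutral coalescent for a single,
well-mixed population of constant size, with infinite-sites mutation:
at most one mutation ever hits a site, so each segregating site is a
binary column (0 = ancestral, 1 = derived) and a sample collapses to a
matrix of distinct haplotype rows `X` with multiplicities `ν`.  The
ancestral (root) state is assumed known and all-zero; data whose root is
unknown can be recoded so the weighted-majority character of each column
becomes 0 (the consensus-root expedient), a choice that is recorded in
output metadata because it changes the likelihood.

Backwards in time a configuration `[X, ν]` is reduced by three
operations: coalescence of a duplicated haplotype (`νᵢ ≥ 2`, decrement),
type-I removal of a singleton row's private mutation (column deleted, row
stays unique) and type-II removal (column and row deleted, multiplicity
added to the merge row).  Removing a mutation deletes its column, so the
MRCA is the empty matrix with count vector `[1]`.  A row with several
private removable mutations contributes a *single* type-I event, removing
the smallest-index column: mutations on one terminal branch are
exchangeable, and fixing their removal order keeps the recursion from
counting the same genealogy class more than once.  A row can have at most
one type-II-eligible column under infinite sites; the code asserts this
rather than guessing a tie-break.

Every configuration reachable from valid data is a rooted perfect
phylogeny, so column supports form a laminar family over rows.  The
canonical key used for memoisation is the canonical code of the
corresponding mutation tree (per-node column multiplicity, attached
haplotype multiplicity, sorted child codes): configurations equal up to
simultaneous row and column permutation map to the same key, which both
deduplicates the exact recursion and makes it permutation-invariant by
construction.  Non-laminar matrices (only possible as direct user input)
fall back to brute-force minimisation over row permutations, limited to
9 rows.

## Exact recursion

`p[X, ν]` satisfies

    n(n−1+θ) p[X,ν] = Σ νᵢ(νᵢ−1) p[coalesced] + θ Σ_A p[δᵢ] + θ Σ_B (ν_b+1) p[Δᵢ]

with `p(MRCA) = 1`.  Evaluation is a memoised, *iterative* depth-first
pass over canonical keys (no call-stack recursion: chain lengths reach
`#sites + n − 1`), entirely in log space — exact likelihoods for
realistic samples sit around 1e−20 and below.  Each memo instance is
bound to one θ; a grid sweep uses one memo per point, which is simpler
than parameterised caching and matches how grids are actually swept.
A configurable key ceiling (default 5e7) aborts with a resource error
advising importance sampling instead.  The same reachability graph
yields the number of distinct ancestral configurations and, by a
paths-to-MRCA dynamic program in exact integer arithmetic, the number of
distinct genealogies.

## Sequential importance sampling

A genealogy is sampled step by step: at each configuration the proposal
weights the applicable events, one is drawn with probability
proportional to its weight, and `log q(G)` accumulates.  The importance
weight is `w(G) = p(G; θ)/q(G)`; the likelihood estimate is the mean
weight (the estimator is the empirical mean of `R` draws — a displayed
sum without the `R⁻¹` factor would not estimate an expectation), its
standard error is the sample standard deviation over `√R`, and the
effective sample size is the scale-invariant plug-in `(Σw)²/Σw²`, the
standard sample analogue of `R/(1 + var_q(w̄))`, clamped to `[1, R]`.
All three are computed by log-sum-exp; per-realization step summaries
(event kind, `n` before the step, the acting multiplicities) are
sufficient statistics to re-evaluate `log p(G; θ)` at any θ, so one
sampling pass prices a whole likelihood curve.  Budgets are either a
fixed number of realizations (bit-reproducible from the seed) or a
wall-clock allowance measured around whole realizations (never aborting
mid-chain); timed results always carry realization counts because wall
time is hardware-dependent.  Each run owns an independent RNG stream and
its own per-configuration cache, so concurrent runs cannot perturb one
another.

Per-configuration event tables and proposal weights are memoised within
a run, keyed by the raw byte representation of `(X, ν)`; successor
configurations are materialised lazily on first traversal.  Repeated
visits — the normal case when drawing thousands of chains from one
dataset — then cost a dictionary lookup and a categorical draw.

## Proposals

* **EGT** — the scheme the recursion itself suggests: weights
  proportional to the recursion's terms, `νᵢ(νᵢ−1)/n` for coalescence,
  `θ/n` for type I, `θ(ν_b+1)/n` for type II.  (Renderings of this
  scheme sometimes show the coalescence weight as `νᵢ−1`; that form is
  inconsistent with the recursion term `νᵢ(νᵢ−1)` the mutation weights
  are taken from, and in our benchmarks it also destroys the well-known
  efficiency deficit of EGT against SD on simulated grids, so the
  recursion-faithful weights are used.)
* **SD** — weight `νᵢ` for every eligible row; θ-free, so its curves
  re-use realizations exactly.
* **HUW** — for eligible row `i`, `Σ_m u_{i,m}(θ₀)` over current
  columns, where `u_{i,m} = p_θ₀(d_m)·νᵢ/d_m` if row `i` carries
  mutation `m` and `[1−p_θ₀(d_m)]·νᵢ/(n−d_m)` otherwise
  (`d_m` = multiplicity-weighted carrier count; the 0-branch is skipped
  at `d_m = n`, where `p = 1`).  `p_θ(d)`, the probability that the next
  backward event involves a carrier, is computed as

      p_θ(d) = Σ_k [(d−1)/(n−k)]·a_k / Σ_k a_k,
      a_k = C(n−d−1, k−2) / [C(n−1, k−1)(k−1+θ)],   k = 2…n−d+1,

  i.e. an average over the level at which a size-`d` mutation arose,
  weighted by the classical level-size distribution
  `C(n−d−1,k−2)/C(n−1,k−1)` and the waiting factor `1/(k−1+θ)`.  This
  form is self-consistent (each numerator term ≤ its denominator term,
  so `p ∈ [0,1]`), reduces to the `d = 1` closed form (whose numerator
  is the `k = n` term of the same sum) and gives `p = 1` at `n = 2`.
  Values are cached per `(d, n)` and clamped against floating-point
  drift.  When no columns remain the sum is empty; remaining events are
  pure coalescences and the scheme falls back to SD weights, keeping
  support full (all proposals coincide there up to normalisation).
  `θ₀` defaults to the run's target θ.
* **Exact singleton** — on configurations whose rows are all singletons,
  steps are drawn from the target's own one-step conditional
  (probability ∝ recursion coefficient × exact successor probability);
  elsewhere a delegate proposal (default SD) is used.  The exact memo
  fills on demand under a key budget (default 2e5); a configuration
  whose successors cannot all be priced inside the budget falls back to
  the delegate, and the failure is remembered so the budget is probed at
  most once per configuration.  This realises the mixed red/green
  sampling scheme with an explicit, testable coverage rule.
* **Exact** (validation tool) — the target conditional at *every*
  configuration; every weight is then exactly `p(D; θ)` and ESS = R.
  Affordable only where the exact memo is; used to validate the sampler.

All proposals give positive weight to every event with positive target
coefficient (for θ > 0), so absolute continuity of the target with
respect to the trial distribution holds by construction; a configuration
where every weight vanishes raises a dedicated error naming it.

## Inference

Likelihood curves evaluate the reusable per-realization statistics on a
strictly increasing θ grid, with estimate, SE and ESS per point; the MLE
is the grid argmax, smallest θ on ties, flagged when it sits on a grid
boundary.  For θ-dependent proposals the driving value defaults to the
grid midpoint (recorded in the output); ESS degrades away from it, and
the CLI warns when ESS at the argmax falls below 10.

## Simulator

Topologies are built by uniform pairwise merging with exponential
inter-coalescence times at rate `k(k−1)/2` (time in units of 2N
generations); mutations fall on branches as Poisson(θ/2 × length), each
a fresh column carried by the branch's descendant leaves — so `θ = 4Nμ`
and `E[S] = θ Σ_{k<n} 1/k` (Watterson), the convention of the familiar
command-line simulators.  Columns are ordered oldest-first for
determinism; column order is immaterial downstream.  Benchmark grids
derive per-dataset seeds by `SeedSequence` spawning in fixed cell order,
so a collection is byte-reproducible from one seed.  Simulated data are
ideal in ways real data are not: no sequencing error, no missing data,
no recombination, ascertainment or population structure, and the root
state is known exactly — tests passing on simulated data validate the
algorithms under the model, not the model against nature.

## Gene trees

Compatibility uses the rooted three-gamete test by default (the root is
known to be all-zero; a column pair fails on gametes {01, 10, 11});
the classical unrooted four-gamete variant is available behind a flag.
Construction is the radix-sort algorithm: columns sorted by decreasing
weighted carrier count (ties by original index, for reproducibility),
each row's sorted mutation list inserted as a root-to-leaf trie path,
unary chains collapsed into multi-label edges.  Exports (DOT, Newick
with counts/mutations as comments, indented text) are deterministic.

## Problem sizes and numerical choices

The test suite and the acceptance script run the exact recursion on
datasets up to a few tens of configurations, importance sampling at
R up to 2×10⁵ on the bundled five-sequence dataset, and the proposal
comparison on a simulated grid of θ ∈ {1, 3, 5} × n ∈ {20, 30, 40} with
three replicate datasets per cell at R = 5000 — sizes chosen so the
whole battery completes in minutes on one CPU while leaving the
qualitative comparisons (EGT below SD in fixed-R ESS) clearly resolved.
The parameter-recovery check uses 12 replicate datasets at n = 30,
θ = 3 with R = 4000 over a θ grid of [0.5, 8] step 0.25, asserting only
a broad corridor (median MLE in [1.5, 5]) because coalescent MLEs from
single loci are intrinsically noisy.  Statistical assertions use 3σ (or
4 SE) bounds computed from the replicate counts actually run.

Known limitations: no recombination, migration or growth; unknown-root
handling is the consensus expedient only (no enumeration over candidate
roots); exact computation is memory-bound well below the sample sizes
importance sampling handles; fixed-time benchmarking is wall-clock based
and therefore hardware-dependent by design.
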