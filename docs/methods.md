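# Methods

## Scope

`ctd` scores the connectedness of a node subset *S* inside a weighted
graph *G* by data compression and converts the achieved compression into a
p-value upper bound. Around that core it implements the two companion
workflows such a score needs in practice: learning the disease-specific
partial-correlation networks that serve as *G*, and the oracle machinery
(exhaustive enumeration, permutation sampling, power analysis) used to
validate the bound.

## The compression score

**Null code.** All size-*k* subsets of an *N*-node graph are equally
likely under the null, so one subset costs `I0 = log2 C(N,k)` bits. `I0`
is computed from the exact integer binomial up to N = 10,000 and via
log-gamma beyond; code lengths are kept real-valued throughout (log2 N is
not rounded up), which makes bit scores continuous and still satisfies the
Kraft inequality as sub-probabilities.

**Alternative code.** One member of *S* (the seed) is spelled out in
log2 N bits. The diffusion walker then emits one membership bit per
visited node (the bitstring *B*, with *F* ones); members never reached are
spelled out in log2 N bits each:

    IA = (|S| − F) · log2 N + |B|.

`|B|` counts every post-seed step. A walk that ends because the miss run
reached `num_misses` keeps its terminal zero-run inside `|B|` — the
decoder detects the block boundary by counting that same shared run
length. A walk that ends because all of *S* was found ends at its final
'1'.

**Significance.** `d = I0 − IA` bits of compression has null probability
below `2^−d`; `p_bound = min(1, 2^−d)`. The bound is meaningful only for
k ≪ N (a warning fires at k > N/5). Benjamini–Hochberg adjustment across
cases is provided for multi-patient scoring, and `bits_threshold(alpha) =
−log2(alpha)` converts a significance level to the bits scale (4.32 bits
at α = 0.05).

**Unique decodability.** Bounds of this form are valid only if encodings
are uniquely decodable. Rather than ship a decoder, the suite checks the
operational consequence: on exhaustively enumerable graphs the sum of
`2^−IA` over all subsets of a size class stays ≤ 1 (Kraft–McMillan). This
also implies the bound dominates the enumerated ground-truth p-value,
which is asserted subset-by-subset at N = 20, k = 3.

## The walker

`diffuse_probability` follows the recursive scheme: unvisited neighbors of
the current node inherit shares of `p1` proportional to edge weight; when
a share's half exceeds `threshold_diff` (default 0.01), half is retained
and half recursively diffused onward, the neighbor being marked visited
*for that diffusion call only*. A node with no unvisited neighbors spreads
its mass uniformly over all unvisited nodes, so disconnected graphs still
diffuse; if no unvisited node exists anywhere, the residual is dropped and
tracked in `DiffusionState.discarded` (outside that case one call deposits
exactly `p1`, and the tests assert the balance to 1e-9).

`rank_nodes` runs the walk: diffuse from the current node, step to the
unvisited node of maximal accumulated probability, zero that node's score,
and stop once all of *S* is visited or `num_misses` consecutive non-members
were stepped on. Design choices that the pseudocode-level description
leaves open:

* **Call-local visitation.** Marks made inside a diffusion call are
  discarded on return; only actual steps extend the walk's visited list.
  Otherwise diffusion-touched nodes could never be stepped to.
* **Probability accumulation.** Scores persist and accumulate across walk
  steps, so the walk is guided by diffusion from *all* previously
  encountered nodes; a visited node's score is zeroed and excluded from
  the argmax. The alternative reading — a fresh diffusion per step — is
  available via `RankingEngine(reset_probs_each_step=True)`; in our
  N = 20 power experiments the accumulating variant tracked the expected
  connectedness trend at least as well.
* **Tie-breaking.** Argmax ties resolve to the first node in `node_names`
  order. This is deterministic but not innocuous: in highly symmetric
  graphs (complete unit-weight graphs, uniform fallbacks from isolated
  seeds) it channels walks toward early-named nodes, which is why test
  fixtures avoid planting structure on alphabetically extreme names.
* **`num_misses` default = ceil(log2 N).** After that many consecutive
  misses the bitstring has spent as many bits as one fixed-length node
  code, so continuing the walk cannot compress further.
* **Signed edges.** The GMRF learner emits signed partial correlations;
  diffusion shares are ill-defined for negative weights, so the walker
  always runs on |w| (`to_diffusion_weights`), keeping sign for reporting.

**Precomputation.** The walker's step sequence depends only on the graph
and the seed — *S* enters through the stopping rule alone. `RankingEngine`
therefore computes the full length-*N* visit ordering per seed once and
derives any subset's walk by truncation. This is what makes scoring all
C(20,3) = 1,140 subsets of a 20-node graph take well under a second and
the C(50,5) ≈ 2.1 M enumeration feasible when needed.

## Validation oracles

* **Ground truth** (`brute_force_pvalue`): every size-*k* subset is scored
  (best seed); p(S) is the tie-aware rank fraction
  #{IA ≤ IA(S)} / C(N,k). Enumeration refuses above a configurable cap
  (default 5×10⁶).
* **Permutation** (`permutation_pvalue`): uniform random size-*k* subsets
  with an add-one pseudo-count, `(1 + hits)/(n_perms + 1)`. Uniform subset
  draws — not graph rewiring — because that is the sampling analogue of
  the uniform null the bound addresses; the label-permutation control
  lives separately in `permute_node_labels`.
* **Power** (`power_analysis`): power(t) = #{ctd_p ≤ t ∧ bf_p ≤ t} /
  #{bf_p ≤ t}, reported as missing when the denominator is empty.
* **Tightness.** The bound's looseness is measured on the bits scale,
  `gap_bits = (IA − I0) − log2(bf_p)`, i.e. log2 of the unclamped bound
  over the ground-truth p. On the probability scale the clamped gap
  `ctd_p − bf_p` is ∧-shaped (it vanishes both for the best subsets and
  for the disconnected bulk, where both probabilities saturate at 1) and
  carries no monotone signal; on the bits scale the gap shrinks with
  subset internal degree (Spearman ≈ −0.4 at N = 20), matching the claim
  that the bound is tighter for highly connected sets. The acceptance
  script reports both correlations.
* **Matched vs permuted** (`matched_vs_permuted`): paired d-scores of the
  same subsets on a learned disease network and a label-permuted control
  network — the specificity control for network learning.

## Network learning

Profiles are z-scored per feature against a reference population (ddof 1;
features with no usable reference are dropped). Surrogate profiles — real
samples plus elementwise standard-normal noise, cycling sources in column
order — fill the design matrix to `target_rank` columns. Discriminative
designs allocate ceil(rank/2) columns to the disease side and
floor(rank/2) to the control side; non-discriminative designs draw all
columns from the disease side. Default `target_rank` is the feature count
(square design) but never below the real sample count.

The GMRF is estimated by graphical lasso on the standardized empirical
covariance over a 20-point log-spaced penalty grid anchored at the
smallest fully-sparsifying penalty (grid floor at 5% of it), selected by
extended BIC with γ = 0.5 — deterministic and sample-size aware. The
precision matrix is converted to partial correlations
ρᵢⱼ = −Θᵢⱼ/√(ΘᵢᵢΘⱼⱼ). Edge-support *ranking* quality is evaluated from the
regularization path (`glasso_edge_path_scores`: penalty level at which an
edge first enters), which is independent of the selection criterion —
EBIC at γ = 0.5 is deliberately conservative and can return an empty
model on weak-edge problems where the path still ranks true edges first
(AUC ≈ 0.9 at p = 30, n = 200, |ρ| ≈ 0.18).

Pruning is set subtraction: a disease-control edge is zeroed whenever the
control-only network carries that edge above a magnitude floor (default
0); a `subtract_weights` variant subtracts the control weight instead.
Pruning is idempotent.

Perturbation sets are |z| > 2.0 by default (or top-k |z|), intersected
with the scoring graph's nodes; feature selection keeps features present
in ≥ 50% of patients' optimal subsets.

## Synthetic fixtures

* **Random networks**: exactly `round_half_up(connectedness · N(N−1)/2)`
  distinct edges sampled uniformly, weights uniform on (0.01, 1]. Graphs
  may be disconnected; the walker's uniform fallback handles that. The
  weight distribution is a package choice (configurable), as is half-up
  rounding of the edge count.
* **Case/control profiles**: controls are i.i.d. standard normal; disease
  samples add a latent factor ℓ ~ N(0,1) with loading +effect on substrate
  features and −effect on product features. Substrate–substrate
  correlation tends to e²/(1+e²) (0.8 at the default effect 2.0, chosen so
  module detection succeeds at n = 100/class), substrate–product to its
  negative. This is a minimal single-factor emulation of an enzyme
  deficiency: it reproduces the co-perturbation signature but none of the
  heavy tails, missingness, batch structure, or multi-pathway coupling of
  real metabolomics data — passing tests show the pipeline recovers the
  planted structure, not that it handles clinical data.
* **Sparse precision matrices** (`random_sparse_precision`): uniform
  random support, fixed-magnitude random-sign entries, diagonal lifted to
  strict dominance — ground truth for support-recovery simulations.

## Study sizes

The shipped validation studies run on one CPU in about a minute total:
conservativeness/tightness and power at N = 20, k = 3 (1,140 subsets per
network, three connectedness levels 10%/30%/60%); power additionally
averaged over 10 replicate network triplets in the acceptance script, the
single-triplet statistic being noisy; Kraft at N = 10, k = 3; diffusion
conservation over 100 dead-end-free seeded instances; module recovery
over 20 seeds at p = 30 features, n = 100/class; support recovery at
p = 30, n = 200. The full-scale N = 50, k = 5 enumeration with scoring is
supported through the same API (the count check runs it without scoring).

## Known limitations

* The p-value bound is conservative by construction; its power is
  meaningful only relative to the enumerated ground truth, and only for
  small k/N.
* Deterministic tie-breaking biases walks in near-symmetric graphs (see
  above); results on graphs with many exactly equal weights should be
  read with that in mind.
* The permutation oracle's null (uniform subsets) is one of several
  defensible choices; rewiring nulls answer a different question.
* Walks assume nonnegative weights; sign information influences scoring
  only through magnitude.
* `find_best_subset` searches the (seed, found-prefix) candidate family;
  it can absorb a member found shortly after the core module if the null
  cost of naming one more member exceeds the extra bitstring cost, and
  the null length for a candidate uses the candidate's own size, not
  |S|. Alternative candidate families can be scored with the same
  encodings.
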