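# Methods

## The model

### Regulatory states on the phylogeny

The unit of analysis is an orthologous gene group: one gene per species,
related by descent. For group *m* and species *i* the binary regulatory
state Z<sub>mi</sub> says whether the gene is a transcriptional target of
the focal TF. Z evolves independently per group along the rooted
phylogeny as a two-state CTMC with gain rate λ and loss rate μ per unit
branch length; branch lengths are divergence times taken as-is from the
Newick input (no rescaling), so rates are in inverse time units of that
file. The transition matrix uses the closed form

    P(0→1, t) = λ/(λ+μ) · (1 − e^{−(λ+μ)t}),   P(1→0, t) = μ/(λ+μ) · (1 − e^{−(λ+μ)t}),

which is numerically stable and fast; the generic matrix exponential is
kept in the test suite as an independent oracle.

The probability of an observed leaf configuration sums over all ancestral
state assignments (Felsenstein pruning, implemented batched over all 2^N
configurations at once). On a star tree this reduces to the root-prior-
weighted product of per-branch transition probabilities. An exhaustive-
enumeration implementation (all node-state assignments, ≤ 12 nodes) pins
the semantics in tests.

The root prior π = P(Z<sub>root</sub>=1) is a free parameter. It can
optionally be tied to the chain's stationary distribution λ/(λ+μ)
(`tie_root_to_stationary`), which removes one parameter at the cost of
coupling the root to the rates.

### Sequence channel

P(S | Z) treats the promoter window as emitted from a hidden
background/motif layer. For Z=0 every base is background
(P = ∏ p<sub>b</sub>). For Z=1 a position is in the motif state with
marginal probability q. The HMM is approximated by a motif scan: every
offset on both strands is scored as Σ<sub>k</sub> log(PSSM<sub>k</sub>(b)/p<sub>b</sub>),
segments above a threshold are called greedily by descending score with
overlap forbidden on base intervals (so N<sub>b</sub> + N<sub>m</sub>·width
partitions the window exactly), and the window's sufficient statistics are
(N<sub>b</sub>, N<sub>m</sub>, log R). The log-likelihood difference is
then N<sub>b</sub> log(1−q) + N<sub>m</sub> log q + log R. Natural
logarithms are used throughout, and all probabilities are carried in log
space; exponentiation happens only at reporting boundaries.

Numerical and policy choices:

- **Call threshold**: 60% of the PSSM's maximum achievable score by
  default. A relative threshold is scale-free across motifs; it is
  configurable, and an absolute threshold can be requested.
- **Strands**: both are scanned; a hit's strand is recorded but not
  modeled (TF binding is strand-agnostic). Scan statistics are invariant
  under reverse-complementing the window.
- **Ambiguous bases**: N scores 0 in segments and contributes 0 to the
  background log-probability, i.e. it is treated as uninformative.
- **Ties** in greedy selection break by leftmost start, then strand.
- **Long regions**: every 500 bp window (step 250 bp, end-anchored flush
  window included) is scanned and the window maximizing the z=1 vs z=0
  difference represents the region; ties go to the first window by
  coordinate. The maximized difference doubles as the region's binding
  affinity; interspecies affinity difference is the mean absolute pairwise
  difference across species.
- **Multiple TFs**: scans of the same window by several PSSMs may be
  pooled (N<sub>m</sub> and log R add; N<sub>b</sub> is recomputed from
  the pooled footprint).

The scan-approximated P(S | Z=1) is not exactly normalized over sequence
space — the approximation inherited from the scan construction; P(S | Z=0)
is a proper distribution (verified exhaustively at tiny scale in tests).

### Expression channel

Expression enters softly: only each gene's cluster index is modeled.
Clusters are computed per species (cluster numbers K may differ across
species, so θ vectors are per-species). A target's index follows
multinomial θ1, a non-target's θ0. Preprocessing utilities mirror the
intended workflow: a coefficient-of-variation filter (default threshold
1.26; a group is kept if any member's CV across conditions exceeds it;
zero-mean genes count as CV 0 with a warning), seeded k-means on per-gene
z-scored profiles (shape, not level, drives membership), and removal of
singleton clusters from fitting. Externally produced label tables are
accepted as a first-class input, since clustering methodology is
orthogonal to the evolutionary model.

### Joint likelihood, weight and EM

The group likelihood multiplies the CTMC prior over leaf configurations by
per-species emissions P(S|z)·P(E|z)^w. The weight w ≥ 0 is a fixed,
pre-computed tuning exponent (never estimated): w=0 ignores expression;
large w overwhelms the sequence term (checked at w=50 in tests, where
predictions coincide with an expression-only model). Default w=1; a sweep
facility (cross-validation over a grid) supports choosing it.

EM treats (leaf configuration, root state) as the hidden variable:

- **E-step**: posterior over all 2^N configurations per group (exact,
  enumerated; practical for the small species counts this model targets),
  plus the root-state posterior per configuration.
- **M-step**: closed forms for π (expected root-state frequency), q
  (expected motif fraction: Σ E[Z=1]·N_m / Σ E[Z=1]·(N_m+N_b)) and θ0/θ1
  (smoothed weighted label counts, pseudocount 0.5 per cluster to keep
  held-out labels finite); (λ, μ) by Nelder–Mead on the expected
  complete-data log-likelihood in log-rate space (bounds 10⁻⁶..10³),
  accepted only if the objective improves — a generalized EM step that
  preserves monotonicity.

Because the θ update maximizes a *smoothed* objective, the quantity that
is guaranteed non-decreasing is the EM objective: data log-likelihood plus
the Dirichlet smoothing term w·s·Σ log θ. That objective is what the
trace records (with smoothing 0 it is the log-likelihood itself); the
final data log-likelihood is reported separately. Convergence: objective
gain < 10⁻⁶ (default) or 500 iterations. Optional random restarts perturb
the initial parameters with seeded noise and keep the best final
likelihood; the library default is a single start (the CLI `fit` uses 5).

Inference is the MAP leaf configuration per group (ties broken toward the
lexicographically smallest configuration in the canonical species-sorted,
binary-counting order) plus per-species marginals P(Z=1).

### Rewiring statistics

Configurations are classified as conserved-in-all, conserved-partial
(missing one species), species-specific, non-target, or mixed. The
re-wiring rate is 1 − conserved/denominator with an explicit denominator
convention: `all_groups` (default; all analyzed groups) or
`groups_with_any_link` (groups that are a target somewhere). The verbal
definition "non-conserved links among all links" is ambiguous between the
two; both are implemented and the report states which was used.

The permuted-PSSM control shuffles the motif's positions (rows) and base
identities (columns) independently, once each per replicate, rescans every
window, refits the model from the same initialization and recomputes the
rate; the null's mode uses a 0.05-wide histogram binning. The identity
permutation reproduces the unpermuted analysis exactly.

## The simulator

`SimScenario` realizes the model's own generative process on a default
three-species tree `((speciesA:0.9,speciesB:0.9):0.1,speciesC:1.0)` —
branch lengths in units of 100 My, in the spirit of human/mouse/cattle
divergence — with gain/loss rates λ=0.3, μ=0.7 and root prior 0.3 (the
stationary target fraction), i.e. roughly a third of analyzed genes are
targets in any one species and states mix appreciably but not fully over
a branch.

Six canonical scenarios cross two sequence-signal levels with three
expression-signal levels:

| knob | weak | medium | strong |
|---|---|---|---|
| q_true (motif planting rate /bp) | 0.004 | — | 0.01 |
| PSSM consensus-base probability | 0.65 | — | 0.90 |
| total variation θ1 vs θ0 (K=4, θ0 uniform) | 0.1 | 0.3 | 0.6 |

Windows are 500 bp; when Z=1 each position starts a PSSM-drawn motif with
probability q_true, otherwise emits an i.i.d. background base; labels are
drawn from θ1/θ0 per species. All randomness flows through one seeded
`SeedSequence` hierarchy, so regeneration is bit-identical. A convenience
generator of Gaussian cluster profiles exercises the k-means path.

What the simulator does *not* emulate about real data: promoter alignment
and indels, binding-site clustering/spacing biases, non-uniform genomic
background, correlated expression noise across species, and errors in the
assumed tree. Passing tests therefore demonstrate internal consistency of
the method (the estimator recovers the generative truth), not performance
on real genomes.

## Problem sizes used in the checks

Parameter recovery uses 2000 groups (strong/strong); EM-monotonicity runs
all six scenarios at 500 groups; cross-validation uses 500 groups, 5
folds, weights {0, 1, 5}; the permutation null uses 150 groups with 50
permutations; the acceptance script uses 1000/300/120 groups for the
recovery, cross-validation and null sections. These sizes make the checks
statistically meaningful for the quantities asserted (e.g. recovery
tolerances of ±0.05 on q and the stationary fraction, total variation 0.1
on θ1) while keeping each run to minutes.

## Known limitations

- Exact enumeration of 2^N leaf configurations limits the method to small
  species counts (the intended regime is 3–6).
- (λ, μ) and π are only weakly identified from three leaves; estimates of
  the stationary fraction are much more stable than the individual rates.
- The scan approximation undercounts overlapping or weak motif instances,
  biasing q̂ slightly downward (visible but within tolerance in recovery
  experiments).
- The expression weight is not estimable from the likelihood (larger w
  always reweights channels, it is not a fit parameter); it must be chosen
  by cross-validation or assigned.
- One TF at a time; combinatorial states for TF sets are out of scope
  (scan pooling for multiple motifs of one factor complex is provided).
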