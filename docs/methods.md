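# Methods

This note documents the models implemented in `tipchron`, the numerical
and design choices behind them, and what the synthetic-data validation
does and does not demonstrate.

## Character data and recoding

A character matrix is read from NEXUS with per-character ordered flags
(ASSUMPTIONS `TYPESET`, a sidecar `key = value` file, or an explicit index
list; state symbols 0–9A–Z).  Recoding builds each character's working
state space:

- **Ordered characters** get a morphocline covering every integer state
  from the smallest to the largest observed.  An observed polymorphism
  between two *adjacent* fixed states is inserted as its own intermediate
  state at that position, so a chain `0 < (01) < 1 < 2` has four states.
  A polymorphism spanning non-adjacent states is treated as an ambiguity
  set over the spanned recoded positions, not a new state (intermediates
  are only defined between otherwise-adjacent fixed states).
- **Unordered characters** map observed states onto 0..k−1; polymorphisms
  stay ambiguity sets.  Missing (`?`) and gap (`-`) cells are full
  ambiguity.

By default k per character is the observed recoded state count; a
`fixed_k` override forces a common state space (used by the exact
pattern-enumeration tests, and available when a maximum state count is
known a priori).

Step matrices follow the morphocline: under the **equal** scheme every
adjacent move costs 1 (fixed→next-fixed costs 2 through an intermediate);
under the **half-step** scheme moves into or out of a polymorphic
intermediate cost 0.5, so fixed→next-fixed totals 1.  Parsimony
informativeness is computed on recoded states: a character is informative
iff at least two states each occur in at least two taxa, with
non-determinate cells ignored.  Other programs' conventions can differ for
characters whose variation sits in ambiguity sets.

## Parsimony

Scoring is generalized (Sankoff) dynamic programming with the
per-character step matrix, so both weighting schemes and ambiguity sets
are handled uniformly; with symmetric costs the score is independent of
root placement.  Search is heuristic — random stepwise addition followed
by hill climbing over NNI and SPR neighborhoods — with every distinct
optimal topology retained (deduplicated by unrooted bipartition set).
An exhaustive enumerator (≤ 12 taxa) provides the ground truth used in
validation.  Ensemble indices use per-character minimum steps m (Steiner
cost of the observed states), observed steps s on the tree, and maximum
conceivable steps g (star-tree score): CI excluding uninformative
characters = Σm/Σs over informative characters, RI = (Σg−Σs)/(Σg−Σm) over
all characters (the standard convention), RCI = RI × Σm/Σs over all
characters.  Bootstrap pseudoreplicates resample characters with
replacement and use a reduced-effort search (10 additions, NNI only);
support values are stochastic by nature.

## Mk likelihood with variable coding

Rate matrices are symmetric with uniform stationary distribution,
normalized to one expected change per unit branch length: unordered —
all off-diagonal rates equal; ordered — nonzero rates only between
adjacent recoded positions.  Transition matrices come from a cached
spectral decomposition (the matrices are symmetric, so the
eigendecomposition is exact and stable).  Among-character rate variation
uses the discrete-gamma approximation with equal-probability categories
and category means (4 categories by default).  Pruning is vectorized over
characters grouped by (state count, ordered), with per-character
log-scaling at every internal node so deep or saturated trees do not
underflow.

The "variable" correction conditions each character on being
non-constant: corrected lnL = lnL − ln(1 − Σ_j L_const(j)), where the
constant-pattern likelihoods are computed in the same pruning pass as k
appended pseudo-characters.  On a degenerate tree (all effective lengths
0) the constant-pattern mass reaches 1 and the correction is undefined;
this is reported as an explicit numerical error.  Polymorphic
intermediate states participate in the Mk state space of ordered
characters, matching their treatment in the matrix used by all analyses.

## Tree and clock priors

The time-tree prior is the fossilized birth–death process with every
fossil a terminal sample, in the (d, r, s, ρ) parameterization
(d = λ−μ > 0, r = μ/λ ∈ [0,1), s = ψ/(μ+ψ) ∈ [0,1), ρ fixed), conditioned
on the root age with both root lineages required to leave at least one
sample.  Two variants are provided and limit-checked:

- **no-removal** (default): a sampled fossil's lineage continues
  unobserved and is conditioned on producing no further samples — the
  fossil factor is ψ·p0(y)/q(y).  This is the published fossil-tip form.
- **removal** (`FBDParams.removal`, `ChainConfig.fossil_removal`): the
  sampling event terminates the lineage — the fossil factor is ψ/q(y).
  The extinction probability p0 and branch propagator q are identical in
  the two variants (a ψ event is a sample either way), so they differ
  only in the p0(y) factor.

The synthetic generator realises the removal variant (fossil sampling
truncates the simulated lineage), so recovery experiments run the sampler
with `fossil_removal=True`; with ψ = 0 the two variants coincide and both
reduce to the classic birth–death and Yule densities, which the tests
check against independently written closed forms.

The IGR relaxed clock draws each branch's effective length independently:
v_b ~ Gamma with mean c·t_b and variance σ²·c·t_b (shape c·t_b/σ², rate
1/σ²).  The variance convention (linear in expected length) is a choice;
reference implementations differ across versions, so the test suite
verifies self-consistency and parameter recovery rather than agreement
with any one program.  Hyperpriors (defaults, exponentials parameterized
by rate): d ~ Exp(50), c ~ Normal(0.25, 0.05) truncated at 0,
σ² ~ Exp(3), r, s ~ Beta(1, 1), ρ fixed at 0.005, root age uniform on
(47.8, 55) Ma, tip ages uniform in their calibration windows, gamma shape
α ~ Exp(1) (stated here because the source analyses leave it implicit),
and Exp(10) on branch lengths in non-clock mode.

## MCMC

One generation is a full sweep: every movable tip age, internal node age,
branch effective length, and scalar parameter receives one
Metropolis–Hastings proposal; coupled chains (heat β_i = 1/(1+T·i))
attempt one state swap per generation with acceptance
(β_i−β_j)(lnP_j−lnP_i).  Moves: normal slides for tip ages (rejected
outside the window via the prior, never clipped), uniform draws within
the current valid interval for node ages, multipliers (Hastings +ln m)
for v_b, d, c, σ², α, slides for r and s, and joint "ridge" moves that
slide an age while rescaling the adjacent effective lengths to preserve
their rates (deterministic rescaling, Jacobian Σ ln(t′/t) in the
acceptance ratio).  The ridge moves are what make desk-scale run lengths
mix: age and length are strongly correlated along terminal branches.

The posterior pieces are maintained incrementally — a length move touches
one IGR term and a partial pruning update along the path to the root
(with accept/reject rollback); an age move touches the FBD density and
the adjacent IGR terms; only the gamma-shape move pays for a full
likelihood evaluation.  Constant prior terms (window widths) are dropped.
Topology is fixed by default; time-tree NNI moves (age-preserving child/
sibling swaps, rejected when ages conflict) are available behind
`topology_moves`.  Every recorded sample is asserted to satisfy
parent-older-than-child and all calibration windows.  Switching off the
likelihood and tree prior turns the sampler into a prior sampler; the
tests require the resulting marginals to match the analytic hyperpriors
(KS tests on thinned draws), with chain swaps enabled — the standard
detailed-balance validation.

Summaries: majority-rule-plus-compatible-groups consensus over the
sampled rooted clades, per-clade posterior probability and median age
(over the samples containing that clade; parents nudged to respect
monotonicity when medians from different samples disagree), per-branch
median relative rate v_b/(c·t_b), per-tip posterior mean and shortest-
interval 95% HPD.  ESS and PSRF come from arviz; ASDSF is the mean over
splits (frequency ≥ 0.1 in either run) of the split-frequency standard
deviation across runs.

Default run lengths are deliberately scaled down (2000 sweeps ≈ 1.2×10⁵
elementary proposals; the tip-age validation uses 450-sweep runs on
20-taxon × 200-character datasets, and the trait-model validation uses
25–40-tip trees — study-sized, and large enough that Pagel's λ is
identifiable and the α₀ intervals honestly calibrated).  The classic
multi-million-generation settings are accepted through the same
configuration fields.

## Biochronology workflow

TD1 runs tip dating with uniform windows and reports per-tip means and
HPDs.  Locality averaging takes the arithmetic mean of member-tip
posterior means; full precision feeds TD2 (rounding to 0.1 Ma is display
only), and a tip mapped to no locality is an error (multi-locality tips
are not representable).  TD2 reruns the same machinery with every tip
fixed, which disables the tip-age moves.  Rate painting multiplies each
branch's median relative rate by the posterior median base clock rate to
give absolute rates in changes per character per Ma.

Time-scaled topologies assign ages bottom-up: tips at their estimated
ages, each parent at the oldest child age plus a fixed spacing (1 Ma in
the classic usage; 0 gives pure ghost-lineage stretching).  Because the
source material is ambiguous about whether terminal branches also receive
a 1-Ma floor, both conventions are implemented
(`terminal_rule ∈ {none, floor_1ma}`, default `none`).  The total branch
sum at spacing 0 equals the stretching forced by age heterogeneity among
descendants, an identity the tests verify by independent recursion.

## Continuous-trait reconstruction

Tip values of ln M1 area evolve by Brownian motion on the time tree:
random walk (mean α₀) or directional (mean α₀ + β·root-to-tip time; the
non-ultrametric fossil tips make β identifiable).  Covariances are
elapsed time to the most recent common ancestor, transformed by Pagel's
λ (internal-node depths scaled, equivalently off-diagonal covariances),
δ (node depths raised to a power) or κ (branch durations raised to a
power); one transform per run.  Inference is MH-MCMC over (α₀, ln σ², β,
transform parameter) under wide uniform priors (a documented caveat — the
source analyses state none), with ancestral states drawn at each sampled
generation from their exact conditional multivariate normal given tips
and parameters.  Proposals with non-positive-definite covariance are
rejected.  Marginal likelihoods use the harmonic-mean estimator over
post-burn-in sampled likelihoods — retained deliberately for fidelity to
the workflow it mirrors, despite its known instability — and model
comparison reports 2·Δln(marginal likelihood) with the conventional
weak/positive/strong bands.  Reported mm² values are exp of the ln-scale
posterior means.

## Synthetic data: what it emulates, what it does not

The generator draws FBD trees forward in time (fossil sampling truncates
the lineage; unsampled lineages pruned; small trees rejected and
re-simulated, which biases fixtures toward larger trees), evolves
characters under the Mk process with IGR branch lengths and continuous
gamma rate multipliers, discards constant characters (emulating variable
coding), injects adjacent-state polymorphisms at a set rate, builds
uniform calibration windows guaranteed to contain the true ages, groups
tips of similar age into localities, and draws BM traits from the exact
implied multivariate normal.  The default regime mirrors the study's
shape: ~40 taxa, 118 characters, ~65% ordered, 2–4 states, one extant
tip, clock rate 0.25 changes per character per Ma (the centre of the
clock-rate hyperprior).

Passing the validation battery shows the implementation is internally
correct and calibrated **under its own model**: priors are recovered
exactly, 95% HPDs on fossil tip ages cover the truth at ≥ 85% over
replicates, search matches enumeration, and the exact likelihood/density
identities hold to 1e-8.  It does not show that real morphological data
satisfy the model: the generator has no character correlation, no
taphonomic or geographic sampling structure, calibration windows that
always contain the truth, and per-category discrete-vs-continuous gamma
mismatch as the only observation noise besides polymorphism injection.
Conclusions about real faunas inherit the usual caveats of the model
itself.

## Known limitations

- No sampled-ancestor trees, diversified sampling, or skyline FBD.
- Tip-dating topology search is NNI-only and off by default; posterior
  probabilities for clades are meaningful only relative to the supplied
  starting topology unless NNI moves are enabled.
- The harmonic-mean marginal likelihood is high-variance; Bayes factors
  near the "weak" band should not be over-read.
- Exhaustive parsimony is capped at 12 taxa; branch-and-bound is not
  implemented.
- The NEXUS dialect accepted is the dialect emitted (plus simple TYPESET
  blocks); interleaved matrices and exotic symbol sets are out of scope.
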