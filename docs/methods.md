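# Methods

## The problem

When a gene appears to be missing from a species' transcriptome or genome,
two very different explanations compete: the gene is genuinely absent, or
its sequence has diverged far enough that similarity search no longer finds
it (*homology detection failure*). decayscreen implements a screen that
separates these possibilities for orthogroups (OGs) scored against a focal
species, and then asks whether a binary/ternary species trait — here the
sperm-bristle state of *Macrostomum* flatworms, a proxy for mating strategy
— predicts sequence presence/absence beyond what detection failure alone
explains.

## Bit-score decay model

For an orthogroup with focal self bit-score `L` (bits) and decay rate `R`
(per unit genetic distance), the expected bit-score of a homolog at
distance `t` from the focal species is

    S(t) = L * exp(-R * t)

with variance

    sigma^2(t) = L * (1 - exp(-R*t)) * exp(-R*t),

a binomial-style law: zero at t = 0 (a sequence is identical to itself),
rising then falling as the expected score decays. `L` is tied to protein
length (roughly 2 bits per residue under BLOSUM62), so the package converts
between the two at that rate where a query length is needed.

### Estimation (double fit)

Per OG, using only species in the reference trait state ("present") with an
observed score, and only OGs with at least `min_species = 5` such species:

1. OLS (optionally weighted) of `ln S` on `t` gives starting values
   `(L0, R0) = (exp(intercept), -slope)`;
2. Levenberg–Marquardt nonlinear least squares on the untransformed scores
   refines them, minimising `sum_i w_i (S_i - L e^{-R t_i})^2`. Weights
   `w_i = 1 - p_miss_i` (one minus the BUSCO-missing proportion) are applied
   in both steps when enabled — assembly completeness is the only weighting
   rationale, so the two steps should see the same weights.

The optimiser runs unconstrained in (L, R): a fit with `R < 0` means the
estimated similarity *increases* with distance, which is flagged `spurious`
and excluded from every downstream stage. An internal positivity transform
would make the spurious direction unreachable, which is why it is not used.
OGs whose reference species all sit at `t < 0.05` cannot identify R
(near-collinear design) and are skipped. Nonpositive observed scores (a
synthetic-edge-case artifact) are dropped with a logged count.

### Residuals

Residuals are `observed - predicted`, so negative means *less similar than
expected*. They are computed for all species, including the non-reference
states, but only at `t < t_max = 0.7`: the reference group contains no
species beyond that distance, and extrapolating the decay curve outside the
fitted range is not trusted. Within each OG, residuals are summarised per
trait state by the median across species; a state with no contributing
species is reported missing, never as zero. A holdout validator refits on a
retained subset of reference species and evaluates residuals on the held-out
rest; under the generating model those held-out residuals are centred on
zero.

## Detection probability

An E-value threshold `E` converts to a bit-score threshold via the
Karlin–Altschul identity

    threshold = log2(m * n / E),

with `m` the query length (the focal sequence's residue count, or the
OG's recorded focal length in score-only mode) and `n` the database size.
No effective-length (edge-effect) correction enters the `m*n` product.
Defaults: `E = 0.001`, `n = 853,740,050` residues.

The probability of detecting a homolog at the reference distance
`t* = 0.7` is the mass of `Normal(S(t*), sigma(t*))` above the threshold:

    P_detect = 1 - Phi((threshold - S(t*)) / sigma(t*)).

When `sigma(t*) = 0` the deterministic limit applies (1 if `S(t*)` exceeds
the threshold, else 0, equality counting as undetected). An OG is
"detectable" iff `P_detect > 0.90` strictly. Only detectable OGs enter the
presence/absence regression: for them, a missing sequence is *not*
explicable by detection failure, so other explanations are on the table.

## Pairwise scoring

Where gapped amino-acid alignments are the input, each member sequence is
gap-stripped and locally aligned against the gap-stripped focal sequence
(affine-gap Smith–Waterman, BLOSUM62, gap open 11 / extend 1, BLAST's
`open + k*extend` convention), and the raw score is converted to bits with
the published gapped constants (lambda = 0.267, K = 0.041). BLAST's
seeding heuristics and composition-based adjustments are intentionally not
reproduced: the downstream screen depends only on (L, R, threshold), not on
bit-for-bit BLASTP equality. One optimal score is emitted per pair.

## Phylogenetic probit model of presence/absence

Per detectable OG, species `i` (restricted to `t < 0.7`, mirroring the
residual analysis) has latent liability

    l_i = x_i' beta + u_i + e_i,   u ~ MVN(0, sigma_p^2 C),   e_i ~ N(0, 1),

and the sequence is observed iff `l_i > 0`. `C` is the shared-ancestry
matrix of the ultrametric tree normalised to root depth 1 (entry (i,j) =
depth of the MRCA of i and j; unit diagonal). The residual variance is
fixed at 1 for identification, so every reported effect is on that probit
scale. `beta` uses cell-means coding: one coefficient per bristle state,
summarising each state's expected liability without the phylogenetic
deviations.

Priors are proper and weakly informative: `beta_j ~ N(0, 4)` and
`sigma_p^2 ~ inverse-gamma(2, 1)`. This is a deliberate choice, not a
convenience: binary responses identify the common scale of
(liabilities, effects, sigma_p^2) only weakly, and near-flat priors
(improper on beta, IG(eps, eps) on the variance) place substantial posterior
mass at probit values in the tens to thousands — the chain wanders there,
effective sample sizes collapse, and interval estimates become uselessly
wide and mis-centred. With the weakly informative choices the posterior
stays on the interpretable probit scale and 95% intervals for a true
1.5-probit state contrast achieve ~94% coverage in simulation.

Inference is a seeded single-chain Gibbs sampler:

- liabilities: truncated-normal draws (Albert–Chib data augmentation);
- `beta`: conjugate Gaussian update;
- `u`: Gaussian update in the eigenbasis of `C` (eigendecomposition cached);
- `sigma_p^2`: conjugate inverse-gamma update;
- a parameter-expanded scale move: the likelihood sees only the signs of
  `l`, so the joint scale of `(l, beta, u, sigma_p^2)` is weakly identified
  and plain Gibbs explores it by slow drift. A generalized-Gibbs move
  samples a scale-group transformation exactly (the squared scale is Gamma
  distributed given the current state, with a rejection step for the
  inverse-gamma tail term) and rescales the whole state, restoring mixing
  without changing the posterior.

Chain defaults: 13,000 iterations, 3,000 burn-in, thinning 10 (1,000
retained draws), all configurable; minimum effective sample size across
state coefficients is reported per OG. Constant responses cannot be fitted
(skip reasons `all-present` / `all-absent`), nor can OGs with a single
represented state; skips are logged and tabulated because these filters are
results in their own right.

An OG is called a **candidate** when the entire 95% credible interval of
the "absent" state lies below the interval of the "present" state —
i.e., the probability of observing a sequence is credibly lower in
hypodermically inseminating species even though detection failure was ruled
unlikely.

## Group tests

Per-OG summaries (median residuals; posterior state means) are compared
across bristle states within each annotation category (and optionally within
the adult-biased subset) by tie-corrected Kruskal–Wallis tests, with
Dwass–Steele–Critchlow–Fligner all-pairs post hoc contrasts: each pair is
re-ranked jointly, the rank-sum statistic standardised with the tie-corrected
variance, and `sqrt(2)*|z|` referred to the studentized-range distribution
(k groups, infinite df). A compact letter display (maximal cliques of the
non-significance graph) summarises the pairwise decisions. OGs are treated
as independent; no multiplicity correction is applied across strata.

The asymptotic DSCF reference cannot match an exact permutation enumeration
uniformly at tiny group sizes — at n = 4 per group the exact null has
probability atoms ~0.03 wide — but agrees within 0.02 in the tails where
accept/reject decisions are made; the test suite checks exactly that,
against a full C(8,4) enumeration oracle.

## Synthetic data generator

The generator produces data with precisely the structure the analysis
assumes, so that every stage is testable with known ground truth:

- **Tree**: constant-rate birth–death conditioned on the tip count
  (pure-birth by default), rescaled to root depth exactly 1.
- **Trait shifts**: a configurable number (default 9, matching the order of
  convergent origins in the emulated system) of irreversible
  present→{reduced, absent} transitions on internal, non-nested edges off
  the focal lineage, so derived clades are monophyletic, disjoint, and
  contain at least two species each.
- **Genetic distances**: patristic distances to the focal species on an
  auxiliary "substitutions" tree (each time-tree edge multiplied by an
  independent log-normal rate, median 0.3, log-sd 0.2). This mimics the
  distinction between a time-calibrated tree and substitution-scale
  distances, and reproduces the emulated design: most species inside the
  `t < 0.7` trust horizon, with the deepest clades occasionally beyond it.
- **Decay parameters**: `L ~ log-uniform[100, 2000]` bits,
  `R ~ log-uniform[0.3, 5]` per unit distance. At the default threshold
  (~47 bits for a 200-residue query) these put the fraction of detectable
  OGs near 0.82, inside the realistic 75–90% range for transcriptome-scale
  screens.
- **Scores**: per (OG, species), `Normal(S(t_i), sigma(t_i))` with the
  state- and category-specific multiplier applied to R; draws below the
  detection threshold are censored to "absent" (when enabled), nonpositive
  draws are truncated to absent (bit-scores are nonnegative and
  sub-threshold anyway), and each species additionally drops out with its
  assembly-missingness probability `p_miss ~ Beta(2, 8)` (mean 0.2,
  matching variable-quality de novo transcriptomes). The focal species is
  always present at score exactly L.
- **Ground truth ledger**: every drawn parameter is emitted alongside the
  data, so parameter-recovery tests are a single join.
- **Alignments** (optional): site-independent evolution under a
  uniform-exchangeability 20-state model (or a user-supplied rate matrix),
  with per-edge substitution lengths proportional to the OG's R and the
  edge's trait multiplier; non-focal residues may be gapped out at a
  configurable rate, the focal sequence never is.

What the generator deliberately does **not** emulate: transcriptome
assembly and coverage artifacts, isoform and paralog confusion in orthology
inference, length variation within an OG (all members share the focal
length), phylogenetically correlated residuals around the decay curve, and
expression-level variation. Passing tests therefore demonstrate that the
pipeline recovers the truth *when the decay model and dropout mechanism are
the truth* — they do not certify performance on real transcriptomes, where
the paper-level caveats (assembly quality, paralogy, expression turnover)
apply.

## Numerical choices and problem sizes

- Nonlinear fits: Levenberg–Marquardt, relative tolerance 1e-8, max 5000
  function evaluations; exact recovery (rel. error < 1e-6) on noiseless
  inputs is a test invariant.
- Detectability: closed-form normal tail; verified against 10^6-draw
  Monte-Carlo integration to < 0.005 across an (L, R, threshold) grid.
- Studentized-range tails: scipy's implementation at infinite df, checked
  against direct quadrature of the distribution function to 1e-6.
- The test suite and the acceptance script run the end-to-end study at
  200 OGs on a 60-tip tree with 4 convergent shifts and shortened MCMC
  chains (4,000 iterations); these sizes were chosen so the full suite
  completes in minutes while keeping every qualitative contrast
  overwhelmingly clear (the affected-category Kruskal–Wallis p-values are
  ~1e-36 at this size).

## Known limitations

- Posterior state means are compared across states whose species counts
  differ; the differing shrinkage can shift the *distribution* of per-OG
  state means between states even without a true effect, and with few
  species in a derived state (e.g., two reduced-bristle species inside the
  trust horizon) the across-OG rank tests can flag such mechanical
  differences. The candidate rule (disjoint credible intervals per OG) is
  far more conservative and, in the simulated studies, calls candidates
  only in the category carrying the true effect.
- The decay fit assumes independent Gaussian errors with the model's own
  variance law; phylogenetically correlated deviations are not modelled.
- Reported probit-scale effects are defined relative to the residual
  variance being fixed at 1 and to the stated priors; they are comparable
  across OGs within a run, not across tools with different conventions.
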