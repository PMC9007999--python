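# Methods

`oncodag` infers how an oncogene's expression reshapes the cellular
composition of a tissue from a samples × features table of digital-cytometry
outputs.  This note records the model, the numerical choices, what the
synthetic benchmark does and does not emulate, and the known limitations.

## The model

Each feature (cell prevalence, cell-state metric, oncogene expression, 0/1
sample attribute) is a node of a directed acyclic graph.  The joint
distribution is a linear-Gaussian Bayesian network: every node is normally
distributed with mean linear in its parents,

    Y_j | pa(j)  ~  N( b0_j + Σ_k b_jk · Y_k ,  σ_j² ),

fitted per node by ordinary least squares (the maximum-likelihood estimate;
residual variance divided by *n*).  The intercept `b0_j` is the average
normalized value of the node when all parents are zero; the sign of `b_jk`
distinguishes promoting from inhibitory influence.  Parentless 0/1 attributes
(e.g. a "Cancer" tissue label) are modelled as Bernoulli with their empirical
frequency rather than as Gaussians, so that conditional queries that filter at
near-0 / near-1 evidence retain sampling mass.  A Gaussian alternative can be
selected via `fit_linear_gaussian(..., attribute_nodes=())`.

## Structure learning

Ten algorithms are implemented over two statistical kernels:

* a conditional-independence test — the exact *t*-test on the partial Pearson
  correlation, `t = r·sqrt(df)/sqrt(1−r²)` with `df = n − |Z| − 2` — used by
  `pc_stable`, `gs`, `iamb`, `iamb_fdr`, `mmpc`, `si_hiton_pc` at a default
  α = 0.05 (`iamb_fdr` applies Benjamini–Hochberg over each candidate set);
* the decomposable Gaussian BIC local score, profiled log-likelihood minus
  `(k/2)·ln n` with `k = |parents| + 2`, used by `hc`, `tabu` and the
  maximize phase of `mmhc` / `rsmax2`.

All quantities are computed from one Gram (covariance) matrix per dataset
snapshot, so each test or local score is a small linear solve; this is what
makes 10⁴-replicate bootstraps affordable.  Residual variances are floored at
1e−24 so noiseless fixtures cannot produce infinite likelihoods, and exact
±1 correlations return the smallest positive double rather than p = 0.

Greedy score search uses add/delete/reverse moves under acyclicity and
constraint checks.  Two details matter in practice:

* **Plateau handling.** The network score is recomputed from cached local
  scores after every move; tracking it incrementally lets floating-point
  drift manufacture endless micro-"improvements" on plateaus.  Improvements
  below 1e−8 are ignored and a hard iteration cap guarantees termination.
* **Tie-breaking.** The two orientations of an isolated arc score identically
  (score equivalence), so a fixed enumeration order would orient every
  reversible arc the same way in every bootstrap replicate and across all
  score-based algorithms — manufacturing spurious "direction-consistent"
  ensemble votes.  Under bootstrap resampling each replicate therefore breaks
  score ties uniformly at random from its own seeded stream; reversible arcs
  then wash out to ≈ 0.5 direction frequency while genuinely compelled arcs
  keep consistent majorities.  A single un-seeded `learn_structure` call
  remains fully deterministic (enumeration-order ties).
* **Restarts.** `LearnConfig(restarts=r)` runs iterated local search: the
  incumbent optimum is perturbed by a few random legal arc changes and
  re-climbed, keeping the better structure.  Fresh random starting graphs
  measured distinctly worse than perturbation restarts and are not used.
  The default is `restarts=0`: inside a bootstrap the resampling itself
  provides the diversification, and determinism per seed stays trivial.

Constraint-based learners orient unshielded colliders from recorded
separating sets and close under Meek's rules R1–R4; reversible edges remain
undirected in their output.  Blacklisted directions are pre-oriented the
allowed way before propagation, so no learner can emit a forbidden arc;
whitelisted arcs are inserted up front and protected from deletion.
`mmpc` and `si_hiton_pc` return undirected parents–children adjacencies
(AND-symmetrized) and serve as the restrict phase of `mmhc` and `rsmax2`
(restrict = `si_hiton_pc`, maximize = `tabu`, both members of the named set).

## Bootstrap averaging and the inclusion threshold

Arc strength is the fraction of bootstrap networks (resampled with
replacement at the original *n*, default `n_boot = 10,000`; tests and the
acceptance runs use 200 to keep runtimes in minutes) containing an edge in
either direction; the direction probability is the frequency of one
orientation among edge-containing replicates, with undirected occurrences
voting half for each side.  The averaged network keeps edges at or above a
threshold chosen automatically: the value minimizing the L1 distance between
the empirical strength CDF and an ideal CDF in which every arc has strength
exactly 0 or 1 (nominally 0.5 for well-separated strength distributions).
Candidate thresholds are the observed unique strengths plus one value just
above the maximum (retaining nothing); ties break toward the sparser network.
If the directed part of an averaged network contains a cycle, the weakest arc
of the cycle is dropped with a warning.

## The four-step consensus workflow

1. **Blacklist.** Node roles compile to forbidden arcs: every in-arc of a
   root, every out-arc of a leaf, every in-arc of a quasi-root from outside
   its allowed-parent set.  The oncogene is a quasi-root allowed only the
   cancer attribute as parent, which makes the "mostly a root" prior
   machine-checkable.  Heavily zero-inflated features are suggested as leaves
   by `zero_profile` (fraction ≥ 0.5 by default; suggestions are advisory).
2. **Ensemble.** Each algorithm produces a bootstrap-averaged network; the
   evidence table records per edge the detection count, whether all
   direction-voting algorithms agree, and the extreme arc-significance
   p-values across detecting networks.  For an undirected edge the
   significance conditions on the union of both endpoints' directed parents —
   the directed case ("the child's other parents") does not apply, and this
   is the closest analogue of conditioning on the rest of the network.
3. **Whitelist sweep.** For each threshold in a log-spaced grid
   (1e−20 … 1e−2, 10 points) the direction-consistent evidence arcs with
   min-p ≤ t (best evidence across algorithms; `max_p` selectable) form a
   candidate whitelist, admitted in ascending p-value with cycle-forming arcs
   skipped so the forced set is always satisfiable.  A single (non-bootstrap)
   run of the final-learning algorithm under that whitelist yields per-node
   parents; the node-level L1-BIC

       BIC_j = n_arcs · log10(n_obs) + Σ_i |Ŷ_ij − Y_ij|

   (absolute OLS residual sum plus complexity penalty) is recorded from the
   full learned parent set, while the *whitelistable* parent set is its
   restriction to candidate evidence arcs — the consensus seed never contains
   an arc the ensemble did not corroborate.  Bootstrapping every sweep cell
   would multiply runtime ~200-fold for little change in the minima.
4. **Final learning.** Each node contributes its minimum-BIC parent set (ties
   prefer fewer arcs, then the lower threshold); the union is admitted
   greedily in ascending p-value, skipping cycle-forming arcs.  `mmhc` runs
   under blacklist + seed whitelist with bootstrap averaging; whitelisted
   arcs appear with inclusion probability 1 by construction.

## Queries

Conditional probability queries use logic sampling: forward ancestral
sampling (default 10⁵ samples) followed by rejection against evidence
predicates such as `Cancer < 0.05`.  Likelihood weighting is deliberately not
used — the filtered-samples semantics is the point, and the summaries report
survivor counts (with a warning below 100).  Trend slopes of reported
features against a key feature are least-squares fits on the surviving
samples, with the same slope on the observed data reported alongside when the
data are available, since the two answer different questions.  Quantile
contrasts split samples into *k* rank-based groups (stable order breaks ties,
group sizes differ by at most one) and report the top-minus-bottom mean
difference, emulating a knock-out versus wild-type comparison across
expression quantiles.

## Preprocessing

Continuous features are mapped `x → log10(x + 1)` and min–max scaled to
[0, 1]; attributes pass through.  The log base and offset are configurable
(the min–max step makes the base immaterial for correlations; offset 1 keeps
zero scores at zero).  Equal-width discretization into *k* intervals is
provided as an optional variant, but the default analysis path is continuous:
the arc-strength test is a continuous-data test, and Gaussian scores match
it.  For discretized tables, `LearnConfig(ci_test="mi")` switches the
constraint-based and local-discovery learners to a multinomial
mutual-information G-test (`G = 2·n·MI`, chi-square reference with
`(|X|−1)(|Y|−1)·Π|Z|` degrees of freedom); the score-based learners remain
Gaussian and are not recommended on coded data.  Macrophage orientation probabilities are computed on the raw prevalence
scores before the log transform — the ratio is scale-free on raw scores,
whereas log-transformed inputs would change its meaning.  Missing values are
a hard error; no imputation rule is offered.

## The synthetic benchmark

`make_ground_truth` emulates the study's data structure: 12 nodes — one
Bernoulli(0.5) "Cancer" root, one oncogene quasi-root (child of the root),
eight free continuous features, two zero-inflated leaves with structural-zero
probabilities 0.60 and 0.75 (matching the observed zero fractions 350/582 and
439/582 that motivate leaf designation) — arc density 0.25 over
role-admissible pairs, coefficient magnitudes uniform in [0.5, 1.5] with
random sign, residual sd 0.2, roots at sd 0.2.  Sampled continuous columns
are min–max scaled (as preprocessing would leave them) and structural zeros
are then applied, so the zero excess appears as an exact point mass at 0.

What passing on this benchmark shows — and what it does not: the generator is
faithful to the linear-Gaussian assumption everywhere except the binary root
(harmless: Gaussian scores only see second moments, which still factorize
correctly) and the zero-inflated leaves, which deliberately violate it the
way real zero-heavy digital-cytometry features do.  Measured consequence: a
truth-started search (a proxy for the global BIC optimum) attains mean CPDAG
F1 ≈ 0.77 on this family at n = 500, versus ≈ 0.95 with zero inflation
disabled.  Unconstrained single-run recovery is therefore structurally capped
well below what the same data allow without structural zeros — which is
precisely the argument for designating such features as leaves and not
interpreting their in-arcs.  Real tables additionally feature non-Gaussian
marginals, compositional coupling between prevalence features, and
deconvolution noise that the generator does not emulate; benchmark results
say nothing about those.

Problem sizes in the shipped tests and acceptance runs (chosen to keep the
whole suite in minutes on one core): n = 500 samples, 20 truth seeds,
n_boot = 200, a 4-algorithm ensemble (`hc`, `tabu`, `pc_stable`, `mmhc`) for
the end-to-end checks; the model default remains all ten algorithms and
n_boot = 10,000.

## Degenerate inputs and tie rules

* All-zero macrophage triples → NaN probabilities plus a warning, never a
  division error.
* Constant continuous columns normalize to all-zero with a warning; constant
  test columns raise a named error.
* Singular conditioning designs name the collinear columns.
* Node-BIC ties prefer fewer arcs, then the lower threshold; averaged-network
  direction ties (exactly 0.5) stay undirected; threshold ties prefer the
  sparser network; seed-admission order is ascending p-value with
  lexicographic tie-break.

## Known limitations

* Structure search is greedy; even with tabu memory and iterated local
  search restarts it can stop short of the global score optimum on dense
  instances.
* Arcs into heavily zero-inflated features are unreliable by construction;
  the package surfaces this (zero profile, leaf suggestions) rather than
  fixing it.
* The linear-Gaussian model cannot express interactions or saturating
  dose–response shapes; coefficients are partial linear effects on the
  normalized scale.
* p-values in the evidence table are model-selection-conditioned and should
  be read as ranking evidence, not as calibrated hypothesis tests.
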