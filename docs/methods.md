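# Methods

This note documents the models, numerical choices and limitations of
`ctrlred`. It describes what the code computes and why each default is what
it is; every number quoted here is produced by the package's own tests or
acceptance script.

## Network construction

A subject's connectome is a square symmetric matrix of nonnegative
streamline counts between parcels, zero on the diagonal. Validation is
strict: asymmetry, negativity, nonzero diagonals and size mismatches raise
errors naming the offending cell; nothing is silently repaired.

**Thresholding.** Edges strictly below `fraction × max(weights)` are
removed; weights equal to the cutoff are kept. The maximum is taken over
the subject's whole matrix (one cutoff per subject): thresholding is part
of whole-network construction, and per-subnetwork maxima would treat
within- and between-network edges inconsistently. A `scope="network"` flag
switches to per-block maxima for sensitivity analyses. Four fractions
(0.001 primary; 0.005, 0.010, 0.015 for robustness) define the standard
sweep; edge sets are nested across fractions by construction, and the
pipeline asserts that nesting on every run. Isolated nodes are retained
with degree 0 so parcel indexing is stable across subjects and thresholds.

## Average controllability

The connectome drives a discrete-time linear model `x(t+1) = A x(t) +
B_k u(t)` with a one-hot input at control node `k`. The weighted,
thresholded (not binarized) adjacency is first divided by one plus its
spectral radius, so the normalized matrix has spectral radius
`r/(1+r) < 1` and the infinite-horizon controllability Gramian
`W_k = Σ_t A^t B_k B_kᵀ (Aᵀ)^t` converges. Average controllability of node
`k` is `trace(W_k)`; for symmetric `A` this is the `k`-th diagonal entry of
`(I − A²)⁻¹`, the closed form used by default. Two independent methods — a
per-node discrete Lyapunov solve and a truncated power series — are kept
for cross-checking; on 100 random normalized 50×50 matrices the closed form
and a 1,000-term series agree to ~6e−15 (asserted at 1e−8). Values are
always ≥ 1, with equality exactly for nodes isolated in `A²`.

Design points: normalization is applied to the weighted matrix (the
normalization constant is recorded with the output); only single-node
control sets are computed; modal controllability and control-energy
trajectories are out of scope.

## Redundancy

`R_ij = Σ_{k=1}^{L} P(i,j,k)` counts simple (vertex-distinct) paths of
length ≤ L between `i` and `j` on the binarized thresholded matrix, with
`L = 4` by default. Each undirected path is counted once; a `double_count`
flag restores the per-direction convention, which scales every value by two
and cannot change rank-based inference. Direct edges (`k = 1`) are
included, so nodal redundancy (row sums of `R`) is always ≥ degree, and at
`L = 1` equals it exactly.

The fast implementation uses exact corrected walk-count identities: walks
of `A^k` between distinct endpoints are purged of vertex-revisiting walks
by inclusion-exclusion (classical identities for k ≤ 3; for k = 4 the
correction removes walks whose interior touches an endpoint or repeats the
second/fourth vertex). For `L > 4` the code falls back to exhaustive
enumeration. Exact integer equality with a brute-force depth-first
enumerator is mandatory and asserted on 100+ random graphs per run;
`networkx.all_simple_paths` serves as a second, external cross-check on
small graphs. The DFS oracle refuses graphs above a 60-node cap to prevent
runaway enumeration.

## Cohort filtering

Subjects older than 65 with MoCA < 23/30 are excluded, as are subjects aged
65–90 with a cognitive-flexibility, executive or vocabulary score more than
2 SD below the cohort mean; younger subjects are retained regardless. The
2-SD rule is iterated to a fixed point (cohort statistics recomputed after
each exclusion pass) so that filtering is exactly idempotent — a single
pass would leave the filter's output sensitive to re-application, since
removing the tail shifts the mean and SD. At the default cohort sizes the
fixed point differs from a single pass by at most a subject or two.

## Statistical inference

- **Covariate-adjusted rank correlation**: all variables are rank
  transformed (average ranks for ties) and the partial Pearson correlation
  of the ranked variables given the ranked covariates is computed; with no
  covariates this is exactly the plain Spearman coefficient. p-values use
  the t approximation with `n − 2 − k` degrees of freedom, and
  cross-checks against `pingouin.partial_corr` agree to 1e−10.
- **Group contrasts**: ANCOVA (education-adjusted) and Welch's
  unequal-variance ANOVA, both via pingouin; ANCOVA without covariates
  reduces to one-way ANOVA. The age split is `middle = [40, 65)`,
  `old = [65, 90]`.
- **Sex contrasts**: Fisher z,
  `z = (atanh ρ_F − atanh ρ_M) / sqrt(1/(n_F−3) + 1/(n_M−3))`.
- **Mediation**: product-of-coefficients with OLS paths, covariates in
  every equation, and a seeded percentile bootstrap over subjects
  (default 10,000 draws) at level `1 − α/m`; significant iff the CI
  excludes zero. The algebraic identity `a·b + c′ = c` holds to 1e−8 (it
  is exact for nested linear models with identical covariates). The
  bootstrap resamples are solved as batched 3–5 parameter normal equations,
  which is why the full 10,000-draw default is affordable even inside the
  17-network × 2-mediator × 4-threshold sweep. In the redundancy
  mediation, ranked degree enters as a covariate so the test isolates
  multi-step structure beyond first-order edges. A condition-number cap
  (1e10) on the outcome design rejects collinear mediator/covariate sets.
- **Multiple comparisons**: Bonferroni, `min(1, p·m)`, with `m = 17`
  (networks) or the number of hubs tested (15 by default; always
  user-settable, since reasonable analyses have used 15 or 16).

Type-I error of the null mediation test at the Bonferroni-adjusted level
α/17 is verified against the binomial 95% band over 1,000 replicates
(with 1,000 bootstrap draws per replicate inside the test suite; the
pipeline default remains 10,000).

## Breakpoint regression and reserve models

The two-segment continuous piecewise-linear fit profiles the breakpoint:
for each candidate `b`, slopes come from least squares on the hinge design
`[1, age, (age−b)₊]`; a 201-point grid over the central 96% of the age
range locates the minimum-SSE candidate, refined by bounded scalar
minimization (tolerance 1e−4 on the breakpoint). More segments use
Nelder-Mead over sorted breakpoints with the same profiled least squares.
Per-segment Pearson correlations are computed on the raw data within each
segment. Perfectly linear data triggers a degenerate-breakpoint warning.
On noise-free two-segment data the breakpoint is recovered to ~1e−4 years;
with noise at 10% of the response range and n = 480 it is recovered within
±2 years in ≥ 90% of seeds.

The residual method adjusts a volume for intracranial volume by
intercept-included regression residuals; the output is exactly orthogonal
to ICV, and correlating it with an outcome equals the semi-partial
correlation (checked against pingouin at 1e−8).

Feature-set comparison fits one Gaussian-identity GLM (OLS) per combination
of the grey-matter block (ICV-adjusted hippocampal + subcortical + cortical
volume), the controllability block (17 network means) and the redundancy
block (17 network means) — seven models — on the identical complete-case
sample of subjects older than the fitted hippocampal breakpoint (or a fixed
age override). Outcome and predictors are z-scored on the analysis sample;
this changes coefficients, not R²/LL/AIC/BIC. The OLS (maximum-likelihood
scale) log-likelihood is used so that nested models never lose
log-likelihood, and `AIC = 2k − 2LL`, `BIC = k ln n − 2LL` hold exactly
with `k` = number of mean parameters.

## Synthetic cohort generator

The generator is first-class, tested code. It emulates the statistical
structure the pipeline assumes, per seeded cohort:

- **Demographics**: n = 480 subjects (default), ages uniform on [40, 90],
  female fraction 281/480, education discrete uniform 8–22 years
  (independent of age: it serves only as a covariate), MoCA ≈ N(27, 2)
  clipped to [0, 30], three cognitive screening scores ≈ N(100, 15).
- **Connectomes**: 100 parcels / 17 networks by default (contiguous blocks
  with Schaefer-style labels; 400 parcels for full-scale runs). Shared
  log-normal node propensities (σ = 0.4) give a stable hub structure;
  edges are Bernoulli with probability `clip(0.2·u_i·u_j, 0, 0.95)`, and
  weights are rounded log-normal "streamline counts" (scale 50, σ = 0.8),
  giving heavy-tailed positive integers.
- **Age-dependent edge loss**: edges whose endpoints both lie in a
  designated decline network (default DefaultB, ContB, LimbicB) are
  deleted with probability `decline_rate × (age − 40)`; edges with one
  endpoint inside at half that rate. The default rate 0.005/yr was fixed
  by Monte-Carlo calibration so that each designated network shows
  per-network Spearman correlations of roughly −0.25 (age vs mean average
  controllability) and −0.5 (age vs mean degree) at n = 480 — the
  magnitudes the inference stages are built to detect, and the band the
  emulated study design reports for its default-mode / frontoparietal /
  limbic subnetworks.
- **Processing speed**: intercept 50 plus coefficients (default 2.0 each,
  in cohort-SD units) times the z-scored decline-network means of average
  controllability and redundancy, plus the z-scored ICV-adjusted
  hippocampal volume, plus N(0, 5) noise. Because each channel is
  injected explicitly, the full grey-matter + controllability + redundancy
  model must outperform every sub-model in R², which the end-to-end test
  asserts.
- **Volumes**: two-segment linear age trajectories with a breakpoint at 67
  (hippocampal slopes +3/−45 mm³/yr, subcortical +40/−400, cortical
  −800/−2500), an ICV-proportional component (ICV ≈ N(1.5e6, 1.3e5) mm³)
  and Gaussian noise.
- A `sex_offset` knob multiplies male edge probabilities for ANCOVA
  exercises; by default sex is independent of network structure.

**What the generator does not emulate — and what passing tests therefore do
not show.** Real connectomes have geometry, modular and rich-club structure
and subject-level correlations that Bernoulli edge loss does not produce.
Two consequences observed in the shipped acceptance outputs: (i) because
deletion removes edges wholesale, redundancy is nearly a deterministic
function of degree, so after partialling out ranked degree the redundancy
mediation of the age → controllability path is typically non-significant
in every network — unlike real data, where multi-step structure carries
independent information; (ii) the group-level degree-regressed
redundancy-vs-controllability association is negative here (residual
curvature around an almost perfect degree relationship), whereas real
cohorts report it positive. Passing the end-to-end tests demonstrates that
the pipeline detects the structure the generator injects at the stated
power — not that real data would show the same effect sizes.

## Reproducibility

Every source of randomness flows from a single integer seed:
`numpy.random.default_rng(seed)` drives the generator, and the pipeline
derives per-stage bootstrap seeds from the run seed. Cohort phenotypes are
written with shortest-round-trip float formatting and read back with
round-trip parsing, so a written cohort reloads bit-identically; the run
manifest stores a SHA-256 of every output file, and rerunning with the same
config and seed reproduces every hash. Problem sizes used by the test
suite and acceptance script (100 parcels, 480 subjects, 2,000-draw
bootstrap in recovery simulations, 1,000-draw in null-calibration
replicates) are the package's chosen study conditions for desk-scale
verification; the pipeline defaults (10,000 draws) match the emulated
study's analysis settings.
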