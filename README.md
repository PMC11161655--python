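# ctrlred

Average controllability and multi-step path redundancy of structural brain
connectomes across aging cohorts.

## The scientific problem

Cross-sectional aging studies of the structural connectome ask how the
brain's capacity for *network control* changes with age, and which
topological features buffer that change. `ctrlred` implements that analysis
as a tested, reusable pipeline for anyone working with parcellated
streamline-count matrices (e.g. a Schaefer 400-parcel / 17-network
parcellation) joined to phenotypes (age, sex, education, cognition,
grey-matter volumes):

- **Average controllability.** The connectome is treated as a discrete-time
  linear system `x(t+1) = A x(t) + B_k u(t)` with a single control node
  `k`. After stabilizing the adjacency as `A ← A / (1 + |λ_max|)`, the
  infinite-horizon controllability Gramian
  `W_k = Σ_{t≥0} A^t B_k B_kᵀ (Aᵀ)^t` converges, and node `k`'s average
  controllability is `trace(W_k)` — for symmetric `A` the `k`-th diagonal
  entry of `(I − A²)⁻¹`. High values mark nodes that can push the network
  into easy-to-reach states.
- **Redundancy.** On the binarized network, `R_ij = Σ_{k=1}^{L} P(i,j,k)`
  counts simple (non-circular) paths of length at most `L` (default 4)
  between nodes `i` and `j`; nodal redundancy sums `R_ij` over partners.
  Multi-step paths are a candidate substrate of brain reserve.
- **Inference.** Education-adjusted Spearman correlations of age and
  processing speed with per-network metric means (Bonferroni over 17
  networks), control-hub classification (mean + 1 SD, or top decile) with
  Welch ANOVA / ANCOVA age-group contrasts, Fisher z sex contrasts, and
  parallel bootstrap mediations of the age → controllability path through
  degree and through redundancy (with ranked degree as covariate).
- **Reserve models.** Data-driven breakpoint (continuous piecewise-linear)
  regression of grey-matter trajectories on age, residual-method adjustment
  of volumes for intracranial volume, and comparison of Gaussian GLMs
  predicting processing speed from every combination of the grey-matter,
  controllability and redundancy feature blocks (R², log-likelihood, AIC,
  BIC on the identical sample).

Because suitable public cohorts are access-restricted, the package ships a
seeded synthetic cohort generator that reproduces the *statistical
structure* these stages assume — age-dependent edge loss in designated
networks, metric-coupled processing speed, piecewise volume trajectories
with a breakpoint near age 67 — so the whole pipeline is testable end to
end.

## Worked example

```python
import numpy as np
from ctrlred import (CohortSpec, generate_cohort, filter_cohort,
                     threshold_connectome, binarize,
                     nodal_average_controllability, network_means,
                     count_simple_paths, nodal_redundancy, partial_spearman)

spec = CohortSpec(n_subjects=120, n_parcels=100, seed=7)
records, connectomes = generate_cohort(spec)
records = filter_cohort(records)                      # MoCA + 2-SD rules
kept = {r.subject_id for r in records}
connectomes = [c for c in connectomes if c.subject_id in kept]
parc = connectomes[0].parcellation
print(f"n = {len(records)} subjects after cognitive-health filtering")

ac, red, age, edu = [], [], [], []
for rec, con in zip(records, connectomes):
    thr = threshold_connectome(con, 0.001)            # 0.001 x max weight
    binr = binarize(thr)
    ac.append(network_means(nodal_average_controllability(thr), parc)
              .means["DefaultB"])
    red.append(network_means(
        nodal_redundancy(count_simple_paths(binr, 4)), parc).means["DefaultB"])
    age.append(rec.age); edu.append(rec.education_years)

for name, y in (("controllability", ac), ("redundancy", red)):
    r = partial_spearman(age, y, covariates=np.array(edu)[:, None],
                         family_size=17)
    print(f"DefaultB age~{name}: rho = {r.rho:.3f}, p_bonf = {r.p_adjusted:.2e}")
```

prints

```
n = 118 subjects after cognitive-health filtering
DefaultB age~controllability: rho = -0.268, p_bonf = 6.01e-02
DefaultB age~redundancy:      rho = -0.604, p_bonf = 9.62e-12
```

i.e. in this 118-subject demo cohort the default-mode subnetwork loses
redundancy with age decisively (Bonferroni-corrected over the 17 networks),
while the controllability decline of the same magnitude as the full-size
study is only borderline at one quarter of the sample — exactly the power
behavior the full 480-subject conditions are designed around.

## Full pipeline

```bash
ctrlred run --seed 1 --out results/run1          # all defaults
ctrlred simulate --seed 1 --out cohort/          # cohort files only
ctrlred infer --cohort cohort/ --threshold 0.001 --out results/infer
```

`run` executes every stage for each threshold fraction (default
0.001/0.005/0.010/0.015) and writes tidy CSVs (cohort tables, age/speed
correlations, mediations, sex contrasts, hub reports, breakpoints, model
comparison, threshold-robustness summary) plus a `manifest.json` with a
content hash of every output; a rerun with the same config and seed is
bit-identical. A YAML config (`--config`) can override any knob; an empty
config means synthetic-demo defaults.

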