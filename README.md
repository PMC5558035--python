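# connfrag

Fragmentation analysis of lesioned structural brain connectomes.

After a left-hemisphere stroke, language outcome depends not only on which
grey-matter regions were destroyed but on how badly the *residual* white
matter network is disorganized: regions that survived the lesion can be
disconnected from their networks and stop contributing.  `connfrag`
quantifies this disorganization from per-subject weighted structural
connectomes (region × region streamline-density matrices, computed upstream
by any tractography pipeline) and relates it to aphasia severity scores
across a cohort.  It is aimed at researchers studying post-stroke network
topology who have connectome matrices, per-region lesion-damage fractions
and behavior scores in hand.

## The quantities

For each hemisphere the weighted network is partitioned by stochastic
greedy modularity maximization (resolution γ = 1 by default), where the
modularity of a partition into m modules is

    Q = Σᵢ (eᵢᵢ − γ·aᵢ²),   i = 1..m

with eᵢᵢ the fraction of total edge weight inside module i and aᵢ the
fraction incident to it.  Because the optimizer is stochastic, it is rerun
`n_runs` times (100 by default) and the runs are summarized by a
**community affiliation matrix** A, with A_ij the fraction of runs that
co-assign regions i and j.  The mean of A's strict upper triangle is the
**community affiliation index** C — high C means a stable, integrated
community structure.  The left/right contrast

    FI = (RH_C − LH_C) / (RH_C + LH_C)

is the **fragmentation index**: positive FI means the left hemisphere's
community structure is more fragmented than the right's (the subject's own
intact hemisphere serves as the control).  On top of these the package
computes node strength, rich-club hubs (against a degree-preserving
rewired null), participation coefficients, intra-modular degree and module
sizes, and runs the cohort statistics: one-tailed Pearson and partial
correlations against WAB-AQ and its four subscores, nested OLS severity
models (damage; damage + hubs; damage + modularity), and gated
Bonferroni-corrected pairwise co-membership t-tests.

Because no subject-level MRI cohort ships with the package, a synthetic
generator (`connfrag.simulate`) produces lesioned cohorts with full ground
truth: paired sparse planted-module hemispheres, spatially contiguous
necrotic lesions on the left, damage fractions, and behavior scores
decreasing with the injected fragmentation.  All tests and the worked
example below run on it.

## Worked example

```python
from connfrag import AnalysisConfig, FragmentationModel
from connfrag.simulate import SyntheticConfig, generate_cohort

cohort = generate_cohort(SyntheticConfig(n_subjects=90, seed=5))
results = FragmentationModel(cohort, AnalysisConfig(n_runs=25, seed=1)).fit()
print(results.summary())
```

```
Connectome fragmentation analysis
======================================================================
subjects: 90 (0 flagged/excluded)   consensus runs: 25   gamma: 1

Per-subject metrics (mean over cohort):
  left-hemisphere modularity Q             0.4084 (sd 0.0589)
  right-hemisphere modularity Q            0.3502 (sd 0.0189)
  left community affiliation index C       0.0751 (sd 0.0426)
  right community affiliation index C      0.1857 (sd 0.0196)
  fragmentation index FI                   0.4584 (sd 0.2322)
  WAB-AQ                                  91.5629 (sd 12.2827)

Key brain-behavior correlations vs WAB-AQ (one-tailed):
  Q_L              r = -0.5135   p = 1.133e-07   (expected negative)
  C_L              r = +0.4795   p = 8.676e-07   (expected positive)
  FI               r = -0.5068   p = 1.73e-07   (expected negative)
  mean_strength_L  r = +0.4798   p = 8.568e-07   (expected positive)

Severity regressions (WAB-AQ response):
  damage               adj R2 = 0.227   F = 27.2   terms: grey_damage_total (p=1.22e-06)
  damage+hubs          adj R2 = 0.219   F = 13.5   terms: grey_damage_total (p=0.000308), n_hubs_L (p=0.824)
  damage+modularity    adj R2 = 0.317   F = 21.7   terms: grey_damage_total (p=0.0036), Q_L (p=0.000629)

Pairwise co-membership tests: 1596 pairs, 294 executed, 0 significant after Bonferroni
```

Reading the output: the lesioned left hemispheres are *more* modular than
the intact right ones (mean Q 0.41 vs 0.35) — damage segregates the
surviving network into many small modules — and their community structure
is far less stable across optimization runs (C 0.075 vs 0.186, mean FI
+0.46).  Subjects with higher left modularity, lower left affiliation
stability, or higher fragmentation have lower WAB-AQ (worse aphasia), in
the expected directions.  Adding modularity to the damage-only severity
regression raises adjusted R² from 0.23 to 0.32 with a significant
modularity coefficient, while the hub count adds nothing — network
disorganization explains variance that lesion size does not.

The same analysis is scriptable from a shell:

```bash
connfrag simulate --out cohort_dir --seed 5
connfrag analyze --cohort cohort_dir --out results_dir --n-runs 25 --seed 1
connfrag report --results results_dir
```

`FragmentationResults.plot_fragmentation()` and `.plot_affiliation()`
produce the FI-vs-score scatter and per-subject affiliation-matrix
heatmaps.

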