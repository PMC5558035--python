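# Methods

This note documents the models, algorithms, numerical choices and design
decisions behind `connfrag`, and what the synthetic-cohort tests do and do
not establish about real data.

## Community detection and consensus

Modularity of a partition of a weighted undirected network is
`Q = Σᵢ (eᵢᵢ − γ·aᵢ²)` over modules i, where eᵢᵢ is the fraction of total
edge weight internal to module i and aᵢ the fraction incident to it.  The
resolution γ defaults to 1, at which the expression is the classical
Newman form; `modularity_score` exposes the full module-pair decomposition
(its fractions sum to one by construction).

`detect_communities` is a multilevel greedy maximizer (Louvain family)
implemented as a numba kernel: nodes are visited in a freshly shuffled
order; each node moves to the neighboring community with the largest
modularity gain, with ties within 1e-12 broken uniformly at random from
the run's random stream; when no single-node move improves Q by more than
1e-12 the communities are aggregated into super-nodes (internal weight on
the diagonal, keeping total weight and row sums invariant) and the sweep
repeats, so the result is locally optimal under both single-node moves and
community merges.  Zero-strength regions always end as singleton modules.
The optimizer is validated against exhaustive partition enumeration on
small graphs (best-of-100 runs equals the global optimum within 1e-9 on
≥95% of random instances and can never exceed it, since every run returns
a realizable partition).

A single partition of a noisy connectome is an unstable summary, so each
network is analyzed by consensus: `n_runs` independent optimizations
(default 100; the cohort-scale tests and the acceptance script use 25, and
the 500-replicate null calibrations use 10 — problem sizes chosen so the
full suite runs on one CPU in minutes) accumulated into the community
affiliation matrix A.  A's entries are exact multiples of 1/n_runs; its
diagonal is fixed at 1 but excluded from the community affiliation index
C = mean of the strict upper triangle, so C is 0 for always-singleton
regions and 1 for a single stable module.  Per-network modularity is
reported as the best Q over the runs (Q_mean and Q_sd, sample sd, ride
along).  The fragmentation index FI = (RH_C − LH_C)/(RH_C + LH_C) is
antisymmetric and bounded in [−1, 1]; it is undefined (an error) when both
indices are zero.

Randomness policy: one top-level seed; per-subject, per-hemisphere and
per-run substreams are derived with `numpy` SeedSequences keyed by the
seed, a CRC-32 of the subject id and a purpose counter.  Results are
therefore bit-reproducible and invariant to subject ordering, and subjects
can be processed in any order or in parallel.

## Hemispheres and whole-network analysis

Per-hemisphere analyses use only intra-hemispheric edges; commissural
edges are discarded by `hemisphere_submatrix` (per-hemisphere affiliation
matrices are hemisphere-local objects).  Whole-network modularity is
computed on the full matrix including interhemispheric edges.  The number
of regions per hemisphere is a parameter (default 57, the grey-matter
scale of the bundled parcellation; whether such a count is per hemisphere
or total varies between atlas conventions, so it is parameterized rather
than hard-coded).

## Node and module metrics

Node strength is the summed incident weight.  Hub identification follows
the rich-club logic: the binary rich-club coefficient
φ(k) = 2Eₖ/(Nₖ(Nₖ−1)) over nodes of degree > k is normalized by its mean
over `n_null` (default 100) degree-preserving Maslov–Sneppen rewirings
(10·|E| double-edge swaps each, rejecting self-loops and multi-edges);
hubs are the nodes above the smallest k whose normalized coefficient
exceeds 1 with empirical null exceedance p < 0.05, and the set is empty
when no threshold qualifies.  Degree here is binary degree on the support
of the weight matrix — a deliberate choice, since weighted rich-club
variants need a different null.  Note that some degree sequences *force*
a rich club (e.g. a complete core whose periphery is all degree-1 leaves
leaves the null no rewiring freedom); the detector correctly reports
nothing in such cases because the core is then a property of the degree
sequence, not of the wiring.

The participation coefficient uses the standard within/between-module
weight-fraction form, Pᵢ = 1 − Σₛ (k_is/kᵢ)², evaluated on the best-Q
partition of the consensus runs, with Pᵢ = 0 for isolated nodes.
Intra-modular degree of a module is the mean over members of their
within-module strength.  Per-region co-membership frequency is the mean
off-diagonal affiliation entry; its average over regions equals C exactly
(both are means of the off-diagonal of A), which the tests assert to
1e-12.

## Statistics

Brain–behavior correlations are one-tailed Pearson tests with the
direction fixed a priori per metric (negative for Q and FI, positive for
C and strength; configurable), using the t-transform
t = r·√(df/(1−r²)).  Partial correlations use the residual method — x and
y each regressed (OLS with intercept) on the covariates, residuals
correlated — with df = n − 2 − q; the estimator is cross-checked against
pingouin and against a closed-form trivariate construction in the tests.
The unpaired t-test defaults to pooled-variance Student (a Welch flag is
exposed).  Bonferroni adjustment multiplies by the number of tests
actually executed.

The pairwise co-membership battery tests, for every left-hemisphere
region pair, whether subjects with affiliation entry exactly 1 score
higher than the rest.  A subject enters a pair's test only if both regions
are ≥ 50% preserved *for that subject* (the alternative, dropping a pair
cohort-wide unless every subject preserves it, is available behind
`preservation_scope="cohort"`); the test runs only when both groups have
at least `min_group = 5` subjects, and skipped pairs are reported with a
reason rather than dropped.  Under a null generator the family-wise error
of the battery stays below nominal (Bonferroni is conservative), which the
suite verifies over 200 simulated cohorts.

The severity regressions are three nested OLS models with WAB-AQ as
response: damage only; damage + number of left hubs; damage + left
modularity, compared on adjusted R².  If a predictor is degenerate in a
given cohort (e.g. a constant hub count), that model is skipped with a
logged warning rather than fitted rank-deficient.  The per-region
module-size and co-membership correlations for the language-specific and
domain-general subnetworks are reported uncorrected, with an explicit log
warning saying so.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not brain anatomy.  Each hemisphere is a sparse weighted planted-partition
network: 57 regions in 4 modules, within-module edges present with
probability 0.30 at mean weight 1.0, between-module edges with probability
0.10 at mean weight 0.8, weights Normal with CV 0.4 truncated at zero.
These defaults were calibrated so the *intact* hemisphere has best-Q
around 0.35 with an unstable 4–6-module consensus — the modularity regime
of real adult structural connectomes — because the lesion phenomenology
depends on it: against a cartoonishly crisp block structure (dense
complete blocks), multiplicative damage merely rescales modules and
*lowers* Q, the opposite of what lesions do to real connectomes.

Module membership is interleaved with region index (region i belongs to
module i mod 4) so that a spatially contiguous lesion cuts across every
module, as strokes cut across functional systems; index adjacency is the
package's 1-D proxy for spatial adjacency (no atlas geometry is shipped).
A planted rich club (8 evenly spaced hubs with doubled spoke density, a
fully dense mutual core, and spoke weights scaled to 0.25 of the block
means) gives the hub detector something real to find without washing out
the modular weight structure — binary degree carries the rich club, edge
weight carries the modules.

Lesions: an extent (fraction of left regions) is drawn from U(0.05, 0.8),
a contiguous index window of that size is placed uniformly, and each
damaged region is completely destroyed (severity exactly 1) with
probability 0.9 — the necrotic core — or partially damaged with severity
U(0.8, 1.0), the penumbra.  Damage acts multiplicatively on edges,
w′ᵢⱼ = wᵢⱼ(1−dᵢ)(1−dⱼ), emulating tractography restricted to surviving
tissue without modeling tracts.  Complete destruction matters: only exact
zeros disconnect regions, producing the isolated nodes, split modules and
missing affiliation-matrix entries that define fragmentation.  Under
these defaults the lesioned hemisphere has *higher* mean best-Q (≈0.41)
than the intact one (≈0.35), ~28 modules against ~5, and recovered FI
tracks injected lesion extent with Spearman ρ ≈ 0.9.

Behavior: WAB-AQ = clip(β₀ + β_FI·FI_z + β_dmg·dmg_z + β_Q·Q_z + ε, 0, 100)
with β₀ = 100 (a ceiling-limited scale: mildly affected subjects cluster
near the maximum, as on the real instrument), β_FI = −15 points per SD of
internal fragmentation, noise sd 20, and β_dmg = β_Q = 0 by default (they
exist so regression-recovery tests can generate behavior from damage and
modularity).  The internal FI/Q used for generation come from the
generator's own consensus detection (25 runs per hemisphere), standardized
across the cohort; they are stored in the ground truth together with the
lesion extents, coefficients and seed.  The four subscores share a latent
severity factor with loading 0.9 so they intercorrelate positively.  The
null-calibration tests set β₀ = 70 so null scores are unclipped Gaussians;
ceiling ties are a scale feature, not part of the calibration contract.
Derived covariates: grey-matter damage is the mean regional damage
fraction; the white-matter proxy is the strength-weighted mean (damage to
well-connected regions destroys more connective tissue); lesion volume is
the summed damage times a nominal 7 cm³ region volume.  Homotopic
interhemispheric edges of mean weight 0.05 keep the whole-brain network
connected.

What passing tests show — and do not.  The generator shares with real
cohorts the analysis-relevant structure: paired hemispheres from one
distribution, destructive spatially-clustered left-hemisphere damage, and
behavior monotone in network disorganization.  It does not emulate real
streamline-count weight distributions (heavy tails), anatomical module
geometry, interhemispheric tract anatomy, bilateral hub asymmetries, or
right-hemisphere remodeling after stroke.  Parameter recovery on it
demonstrates that the pipeline's estimators are consistent and calibrated
under the assumed generative family, not that the biological effect sizes
of any particular cohort will be reproduced.

## Degenerate inputs and edge cases

Zero-total-weight networks raise an explicit undefined-modularity error;
in the cohort pipeline a subject with a degenerate hemisphere is flagged,
logged and excluded from cohort statistics rather than aborting the run.
Asymmetric matrices are symmetrized as (M + Mᵀ)/2 only within a 1e-9
relative tolerance — larger asymmetry is a data error.  Nonzero diagonals
are zeroed with a logged warning.  Constant metrics or scores make the
affected correlation row (not the run) fail, with a log entry.  Matrix
writers use 17 significant digits so write→load round-trips are exact.

## Known limitations

The optimizer explores local optima; on large degenerate landscapes the
best-of-n Q is a lower bound on the global optimum (the oracle tests
bound the gap only at small n).  Hub detection on networks whose degree
sequence nearly forces the observed rich club has low power by
construction.  The pairwise battery's preservation gate interprets the
50% rule per subject per pair; cohort-level gating changes which pairs are
testable.  The generator's 1-D contiguity proxy makes lesion geometry
unrealistically simple, and FI inherits any true right-hemisphere
variability as noise — both chosen for transparency over realism.
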