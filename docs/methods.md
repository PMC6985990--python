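# Methods

This note documents the models, estimators and design choices behind
`neurophenoclust`, in the order the pipeline runs them.

## Segmentation volumes and fractions

Inputs are integer label grids (NIfTI) with voxel spacing in mm; the
default acquisition convention is 0.9 × 0.9 × 4.0 mm (thick-slice 2D
FLAIR-era imaging). Label volume = voxel count × voxel volume; volumes
are reported in ml. Total brain volume is the sum of white matter,
grey matter, WMH and infarct volumes; ICV adds the lateral ventricles
and peripheral CSF — so BPF + CSF fraction + ventricular fraction ≡
100% by construction, which the property tests enforce on random
inputs. Whether ICV should include anything beyond these labels is
ambiguous in the source material; the direct reading above is used.

Cerebral blood flow is normalized per 100 ml of total brain volume
("fraction of total brain volume" has no stated unit; per-100-ml is the
field convention and is recorded in the scaling metadata so it can be
changed).

Exclusion accounting assigns each enrolled patient to at most one
category with first-match precedence *no MRI → missing sequences →
artefacts*, the order the categories are conventionally reported; this
reproduces a printed partition even when flags overlap.

## WMH classification

The distance map is the exact Euclidean distance transform of the
ventricle-mask complement with anisotropic sampling, i.e. the distance
from each voxel center to the nearest ventricle voxel center (ventricle
voxels are at 0). A voxel is periventricular/confluent when that
distance is ≤ 3 mm (boundary inclusive). A connected lesion
(26-connectivity) is classified CPWMH when *any* of its voxels is
within the threshold — confluent lesions touch the ventricle margin by
definition — with a majority-vote alternative behind a config switch.
Growing the ventricle mask can only move voxels toward CPWMH
(threshold monotonicity; property-tested).

## Lesion shape estimators

Each lesion mask is resampled to an isotropic grid at the minimum
in-plane spacing (nearest neighbour) before meshing and box counting,
because 4-mm slices otherwise distort areas and counts. The isosurface
comes from marching cubes at level 0.5 after Gaussian smoothing whose
physical width is one voxel of the *original* spacing per axis (so
slice staircases are rounded at their own scale). Without smoothing the
staircase mesh overestimates a ball's surface area by ~9% and pushes
small-lesion solidity above 1; with it, a digital r = 10 mm ball gives
solidity 0.999, convexity 1.000 and surface area within 3% of 4πr².

* **volume** — voxel count × voxel volume on the native grid (reported);
  **mesh volume** — enclosed by the isosurface (divergence theorem).
* **solidity** = mesh volume / hull volume, with the hull taken over the
  isosurface vertices. Using the mesh volume in the numerator keeps
  numerator and denominator on the same surface representation, which
  guarantees solidity ≤ 1 up to mesh tolerance.
* **convexity** = hull area / mesh surface area (≤ 1 up to tolerance,
  since projection onto a convex set is area-non-increasing).
* **concavity index** = 2 − convexity − solidity. The source material
  names but never defines this statistic; this is the simplest form
  that is 0 for convex bodies and grows with irregularity, and it is
  recorded as an assumption.
* **eccentricity** = sqrt(1 − λ_min/λ_max) of the second-moment
  eigenvalues of voxel coordinates in mm — the standard 3D extension of
  the planar definition (0 = sphere, → 1 elongated). Planar or linear
  lesions fall back to the nonzero moments. Note that on a 4-mm-slice
  grid a 3-mm ball genuinely *is* elongated across slices; eccentricity
  reflects the sampled object.
* **fractal dimension** — boundary voxels (any 6-neighbour outside) are
  covered with boxes of edge ε; FD is the least-squares slope of
  log N(ε) against log(1/ε). Default scales are powers of two capped at
  one eighth of the largest extent: coarser boxes saturate on closed
  surfaces (N(ε) → (L/ε)³) and bias the slope upward — with scales up
  to L/2 a cube boundary measures ≈ 2.36 instead of 2. Explicit scales
  (e.g. 1, 3, 9 for the Menger-sponge phantom, where the box counts are
  exactly 400/20/1 at level 2) are capped at the extent only. Fewer
  than three usable scales yields NaN, flagged rather than defaulted —
  per-lesion FD of small WMH is therefore often undefined, while the
  per-class pooled FD (all CPWMH voxels of a patient pooled, likewise
  DWMH) usually is defined; both are computed and the pooled variant
  feeds clustering by default.

Single-voxel or otherwise mesh-degenerate lesions fall back to
voxel-face geometry and are flagged.

One deliberate deviation from a naive convergence expectation: refining
*in-plane* resolution at fixed 4-mm slices does **not** drive ball
solidity/convexity monotonically to 1, because finer sampling resolves
the genuinely non-convex stepped-disc geometry of a thick-slice ball
rather than removing it. The tests therefore assert absolute accuracy
bands (gap from 1 below 0.005 isotropically, below 0.07 on thick-slice
grids) instead of monotone convergence.

## Feature matrix and normalization

The clustering feature set (31 columns): BPF, WM, GM, peripheral-CSF
and ventricular fractions; CPWMH and DWMH fraction per lobe (% of ICV;
frontal, parietal, temporal, occipital — the lobe set is configurable);
mean solidity, convexity, concavity index, eccentricity and the pooled
FD per WMH class; counts of lacunes, cortical and subcortical infarcts;
a cortical-infarct indicator and lacune count per lobe; normalized CBF.
The per-lobe denominator is ICV (not lobe volume), consistent with the
other fractions.

Normalization is declared per column in config rather than decided by a
data-driven normality test (which would silently switch methods):
roughly symmetric continuous markers are Z-scored; counts, indicators
and zero-inflated lobe fractions are affinely mapped so the observed
minimum → 0 and maximum → 2 (binary columns land on {0, 2}). The
scaling record makes every column invertible, and imputation fills
missing entries at the column's post-normalization center (0 for
Z-scores — neutral in Ward distance — else the observed median), with
counts logged. Complete-case analysis is available by flag.

## Clustering and cut selection

Ward linkage follows the ward.D2 convention (Lance–Williams update on
Euclidean distances, merge heights on the distance scale), matching the
default of the mainstream scientific implementations; the merge
sequence is verified against an exhaustive greedy oracle on 100 small
instances. Cut levels k = 2…20 are scored by

* average silhouette width (singletons score 0), and
* Dunn index = minimum single-link inter-cluster distance / maximum
  intra-cluster diameter,

both on the imputed normalized matrix without feature weighting. The
chosen k minimizes the rank sum of the two indices (ties → smaller k);
`--force-k` reproduces a human override, mirroring analyses where the
quantitative indices are blended with visual heatmap inspection.
Subgroups are renumbered by ascending mean age, so subgroup 1 is always
the youngest. The heatmap shows patients in dendrogram leaf order on a
diverging scale centered at 0; WMH frequency maps are voxelwise means
of the masks per subgroup on a common grid (no registration — grids
must match or the map is skipped with a warning).

## Subgroup comparisons

Continuous variables: ANCOVA as OLS on subgroup indicators plus
covariates, partial F-test for the subgroup block, all pairwise
adjusted-mean contrasts with Bonferroni correction over the number of
pairs. Discrete variables: multinomial logistic regression with the
subgroup as outcome and the feature plus covariates as predictors;
per-subgroup odds ratios vs a reference with 95% Wald intervals, and an
overall likelihood-ratio test of the feature block (well calibrated at
the simulated sizes; the Wald per-contrast tests are reported
alongside). Perfect separation is flagged and the interval reported
unbounded. The default covariate set is age + sex with an age-only
switch (the source material states both variants in different places).
Skewed positive variables can be log-transformed with an offset of half
the smallest positive observation, recorded in the result.

## Survival analysis

Outcome coding from raw follow-up rows: overall mortality; vascular
mortality (death from myocardial infarction, stroke, sudden death,
congestive heart failure, ruptured abdominal aortic aneurysm, or
another vascular cause) as a cause-defined subset — non-qualifying
deaths censor the vascular model at the death time; ischaemic stroke,
with death and loss to follow-up censoring. Patients with a non-fatal
stroke remain at risk in the mortality models. Coding enforces that
vascular events are a subset of overall-mortality events.

Hazards are estimated with a Cox proportional-hazards model (lifelines,
Efron tie handling) on indicator columns for each non-reference
subgroup — the merged low-burden reference (subgroups 1, 2, 3, 7 at
k = 11, pooling groups for a sufficient event count) shares the zero
vector — adjusted for age and sex. HR = exp(coef) with normal-theory
95% intervals. A subgroup without events is reported non-estimable
rather than fitted toward infinity; constant covariates (e.g. a
single-sex fixture) are dropped. Estimates are invariant to time-unit
rescaling, and at β = 0 the score statistic equals the log-rank
statistic (both tested).

## Synthetic data

The generators define the study conditions for every test.

* **Phantoms.** Voxelization is by voxel-center membership. The head
  phantom nests peripheral-CSF/GM/WM ellipsoid shells with two lateral
  ventricles and paints WMH/infarct balls into white matter (overlap is
  an error); the construction's voxel counts are the exact volume
  truth. Default grid 96 × 96 × 41 at 0.9 × 0.9 × 4.0 mm, one WMH
  tangent to a ventricle and the rest placed > 3 mm away. Lobes are
  axis-aligned quadrants about the brain centroid — a deliberate
  simplification; real lobar anatomy is not modelled.
* **Cohort.** Features are drawn directly in normalized space
  (centroids in within-cluster-SD units), since published subgroup
  profiles are contrasts, not raw generative distributions. Eleven
  qualitative profiles emulate the subgroup phenotypes (low-burden
  groups, a cortical-infarct group with high infarct indicators, a
  lacunar group, a small-vessel group with high WMH load and shape
  irregularity, an atrophy group, a multi-burden group). The profile
  *directions* are Gram-Schmidt orthogonalized and their magnitudes
  square-root compressed, then scaled so the minimum pairwise
  separation equals 6 SD (others range up to ~13): orthogonalization
  prevents any subgroup pair from being left uniquely close through
  shared burden patterns — the single-close-pair geometry defeats any
  silhouette-type cut selection — while the kept magnitude spread
  preserves "strongly contrasting groups sit farther apart". Default
  sizes (160…46, summing to 1003) mirror the reported 46–188 range;
  ages are truncated normal per subgroup (means 50–70 years ascending,
  range 25–82, cohort mean ≈ 59 ± 10); sex is 80% male, a realistic
  proportion for a manifest-arterial-disease cohort. Missingness is
  MCAR at the reported per-feature rates (0.4% shape, 38.5% deep-WMH
  FD/eccentricity, 6.4% CBF). Real missingness is informative (deep-WMH
  shape is missing exactly when no deep lesion exists); the MCAR
  simplification means the imputation-robustness results bound the
  benign case only.
* **Survival.** One latent exponential time per outcome with rate
  h₀·exp(subgroup offset + 0.05·(age − 59) + 0.3·sex), censored at the
  earlier of a 14-year administrative horizon and exponential dropout
  (rate 0.006/year, matching ~80 of 1000 lost over follow-up). Default
  baseline rates 0.012 / 0.006 / 0.004 events per person-year (overall
  mortality / vascular / stroke) approximate the reported event counts
  at the cohort's scale. Outcomes are simulated independently
  (cause-specific view; no competing-risks machinery, matching the
  analysis model). The coherent follow-up generator instead draws
  vascular and non-vascular death times and takes their minimum, so
  coded datasets automatically satisfy the subset invariant.

## Experiment sizes used by tests and the acceptance script

Cluster-count recovery runs 10 seeds at n = 1003 with complete data —
the experiment probes the cut selection on the planted geometry;
imputation robustness is a separate test (38.5% missing in the deep-WMH
columns, ARI ≥ 0.8 against planted labels). Cox recovery uses 200
replicates of n = 1000 with baseline rate 0.0063 (≈ 200 events at a
planted HR of 4). Type-I calibration uses 1000 null replicates (ANCOVA
at n = 60, multinomial at n = 200). Ward-oracle equivalence uses 100
instances of n ≤ 6. These sizes keep the full suite around half a
minute while leaving Monte-Carlo error well inside the asserted bands.

## Known limitations

* Segmentation itself, registration, partial-volume effects and
  realistic MRI intensities are out of scope; segmentations are inputs.
* The surface-index, curvature and complexity shape features are not
  implemented (they are absent from the clustering feature set).
* The lobe parcellation is a geometric quadrant split, not anatomy.
* Synthetic centroids are loosely calibrated to published group
  contrasts, not a reconstruction of any cohort; passing recovery tests
  demonstrates correctness of the machinery under the stated generative
  conditions, not performance on real data.
* Breslow tie handling is not currently exposed (lifelines fits Efron);
  the config validates the choice so an alternative backend can slot in.
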