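# Methods

## Overview

`wmnet` analyses the structural connectivity of the working-memory (WM)
network at two parcellation scales.  The input is one weighted, undirected
whole-brain connectome per subject — a symmetric nonnegative 379 × 379
matrix in the HCP-MMP1 + subcortex convention, with edge weights derived
from SIFT2-weighted probabilistic tractography — together with a subject
covariate table (group, age, sex) and a per-region anatomical volume
table.  The pipeline is:

1. **Volume normalization.**  Edge weights are rescaled by inverse region
   volume to remove the mechanical dependence of streamline counts on
   parcel size.  The default rule is the symmetric form
   `w'_ij = w_ij · 2/(v_i + v_j)`, which is the identity under unit
   volumes and homogeneous of degree −1 in the volumes.  A product form
   `w_ij/(v_i·v_j)` is available (`norm=product`).  Normalization is
   applied at the whole-brain scale, before sub-network extraction, so
   both output scales inherit exactly the same edge values.
2. **Sub-network extraction.**  The 76 WM nodes (35 bilateral cortical
   HCP-MMP1 areas + caudate, putamen, thalamus bilaterally) are selected
   via a (parcel, hemisphere) → whole-brain-index lookup, yielding a
   76 × 76 sub-matrix ordered coarse-group-major, left hemisphere before
   right.
3. **Coarse-graining.**  The 76 nodes are aggregated into 24 bilateral
   anatomical regions (9 cortical groups + 3 subcortical structures per
   hemisphere) by summing all fine edges between region pairs.  Edges
   internal to a region (the within-group mass) are excluded from the
   24 × 24 graph — the nodal metrics are defined on loop-free graphs —
   but returned separately, so total connectivity is conserved:
   fine off-diagonal mass = coarse off-diagonal mass + 2 × Σ within-group
   mass (checked to 1e-9 relative on every subject).
4. **Nodal metrics** (below) per subject at both scales.
5. **Group statistics** per node × metric, and **cross-scale
   classification** per region × metric.

## Nodal graph metrics

All four metrics operate on symmetric nonnegative loop-free matrices and
are invariant to a global positive rescaling of the weights.

**Clustering coefficient (CC).**  Onnela geometric-mean form:
`CC_i = 2/(k_i(k_i−1)) · Σ_{j<h} (ŵ_ij ŵ_ih ŵ_jh)^{1/3}`, with
`ŵ = w/max(W)` and binary degree `k_i`; `CC_i = 0` for `k_i < 2`.  This
is the de-facto standard weighted clustering coefficient for undirected
brain graphs (it is also what NetworkX computes for weighted clustering),
bounded in [0, 1].

**Eigenvector centrality (EC).**  The dominant eigenvector of W,
nonnegative with unit L2 norm, computed by power iteration on the
spectrum-shifted matrix `W/max(W) + I` (relative tolerance 1e-10, cap
10 000 iterations).  The shift makes the dominant eigenvalue unique in
magnitude, so the iteration cannot oscillate on bipartite components.  On
a disconnected graph the vector is still computed on the full matrix — it
then concentrates on the component with the largest eigenvalue — with a
logged warning naming the components; this keeps one vector per subject.

**Local assortativity (LA).**  There is no canonical weighted local
assortativity; the implementation uses an edge-decomposition
reconstruction chosen to be self-validating.  Over ordered node pairs
(i, j) weighted by `w_ij`, let μ and σ² be the stub-weighted mean and
variance of endpoint strengths `s_j = Σ_k w_jk`.  Then
`LA_i = Σ_j w_ij (s_i−μ)(s_j−μ) / (σ² Σ w)`.  By construction
`Σ_i LA_i = r`, the global weighted strength-assortativity coefficient
(the weighted Pearson correlation of endpoint strengths over stubs), and
the test suite verifies this identity on every computed instance.  LA is
undefined (degenerate-strengths error) when all endpoint strengths are
equal, e.g. on a regular equal-weight ring; such subjects are recorded as
missing with a log entry.

**Participation coefficient (PC).**  `PC_i = 1 − Σ_m (s_i(m)/s_i)²` over
the modules m of a node partition, with `PC_i = 0` for isolated nodes;
bounded by 1 − 1/M for M modules.  The module partition is the 24
anatomical groups at the fine scale and the 4 bilateral systems (frontal,
parietal, posteromedial, subcortical) at the coarse scale; both are
configurable, and a data-driven Louvain partition is available as an
option.  The anatomical defaults were preferred over modularity
optimization because they are deterministic and identical across
subjects, which keeps nodewise group comparisons well defined.

## Group statistics

For each node and metric, an ordinary-least-squares model
`metric ~ 1 + group + age + sex` is fitted over subjects, with the group
coefficient (ALL − HC; HC coded 0, so positive β means ALL > HC) as the
effect of interest.  Inference uses heteroskedasticity-consistent
sandwich standard errors — HC3 by default, chosen for its small-sample
behaviour at n ≈ 140 (HC0/HC1 available) — with a t reference on n − 4
degrees of freedom, which is mildly conservative relative to the normal
reference at this sample size.  A constant response is flagged degenerate
with p = 1 by convention.

P-values are adjusted with the Benjamini–Hochberg step-up procedure
across nodes, within each (metric, scale) family; pooling all metrics of
a scale into a single family is available by option.  The per-family
default matches the per-metric presentation of nodewise results.
Significance is FDR-adjusted p < 0.05.

Cohort construction support: `frequency_match` selects controls from a
pool by greedy nearest-age matching without replacement within each sex,
accepting only controls within ±1 year of a case, then trims the
selection (dropping the worst age matches) so the male-to-female ratio of
the controls equals the cases' ratio exactly.  The greedy algorithm is
one reasonable implementation of group-level frequency matching with
±1-year tolerance bins; exhaustive matching is not attempted.

## Cross-scale classification

Per coarse region × metric, with left/right pooled by default (the
hemispheres of a region are combined; a region is coarse-significant when
either hemispheric coarse node is, with a direction only when the
significant hemispheres agree), each cell receives exactly one scenario:

| scenario     | coarse | fine significant nodes                       |
|--------------|--------|----------------------------------------------|
| consistent   | yes    | ≥1 in the coarse direction, 0 opposite       |
| convergent   | yes    | both directions, or none                      |
| fine_only    | no     | ≥1, all one direction                         |
| cancelling   | no     | both directions                               |
| null         | no     | none                                          |

Coarse-significant cells with zero significant fine nodes are binned as
*convergent*, read as sub-threshold same-direction fine shifts summing to
a coarse effect; this is one defensible formalization of a narrative
taxonomy, and the rule lives in a single pure function
(`classify.scenario_rule`) so alternatives are easy to swap.  The summary
grid encodes each region × metric × scale cell as increase / decrease /
heterogeneous-or-none (blue / red / grey in the optional plot).

## Synthetic cohorts

The generator emulates the *statistical structure* of a two-group
paediatric cohort study, not tractography physics.  Defaults:

| parameter                 | default     | meaning                               |
|---------------------------|-------------|---------------------------------------|
| `n_per_group`             | 70          | subjects per group                    |
| `male_fraction`           | 40/70       | males per group (40 M / 30 F)         |
| `age_range`               | 6.2–20.3 y  | imaging age, uniform, both groups     |
| `base_weight_shape/scale` | 4.0 / 0.25  | gamma background edges (mean 1)       |
| `within_module_boost`     | 2.0         | edge-mean boost inside a coarse group |
| `subcortical_block_weight`| 6.0         | edge mean among the 6 subcortical nodes |
| `homotopic_weight`        | 16.0        | edge mean of same-parcel L–R edges    |
| `homotopic_shape`         | 1024        | gamma shape of homotopic edges        |
| `density`                 | 1.0         | fraction of nonzero non-anchor edges  |
| `effect_subcortical_seg`  | 1.0         | ALL-group multiplier, subcortical block |
| `effect_cortical_int`     | 1.0         | ALL-group multiplier, hub cross-module edges |

Edge weights are gamma distributed with a constant scale parameter, so
stronger edge classes are proportionally more reliable across subjects —
mirroring the fact that large bundles are reconstructed far more
consistently than weak streamline connections, while background edges
stay right-skewed.  Homotopic (same parcel, opposite hemisphere) cortical
edges are modeled as strong, low-variability anchors; besides being the
most reproducible edges in real connectomes, they pin the max-weight
normalization of the Onnela clustering coefficient, whose stability
otherwise dominates between-subject metric noise.  The default density of
1 reflects the near-complete density of probabilistic-tractography
connectomes before thresholding; sparser regimes are available but add
binomial degree noise to all metrics.

Group effects are multiplicative on the patient group's edge means: the
segregation effect scales the 15 edges among the six subcortical nodes
(at the 24-region level each subcortical group is a single node, so
"within-module" subcortical edges only exist at the system level), and
the integration effect scales the cross-module edges of designated hub
parcels (default: the DLPC parcels), excluding homotopic anchors.  Ages
and sexes are sampled identically in both groups; metrics are invariant
to weight scale, so no age trend is imposed on the weights.  Random
streams are split per subject (keyed by seed, group index, subject
index), so enlarging the cohort never perturbs earlier subjects.

What the generator does **not** emulate: geometric/distance-dependent
connectivity, reconstruction biases (gyral bias, false positives),
head-motion artefacts, hemispheric asymmetries, age- or sex-dependent
connectivity, and site effects.  Passing recovery benchmarks on these
cohorts therefore demonstrates that the pipeline detects and classifies
the kinds of effects it claims to detect under its own assumptions — not
that identical effect sizes would be recovered from real tractography
data.

## Numerical and design choices

- Matrix symmetry tolerance on input: relative 1e-8; smaller asymmetries
  are symmetrized as (W + Wᵀ)/2, larger ones rejected as directed.
  Nonzero input diagonals are zeroed with a logged warning.
- The fine node order is deterministic (coarse-group-major, left before
  right, table row order), so matrix files are comparable across runs.
- The packaged whole-brain lookup uses the standard HCP-MMP1 area
  numbering (left = area − 1, right = 180 + area − 1) with a documented
  19-slot subcortical block (indices 360–378, left structures then right
  then brainstem).  Other conventions are supported by supplying a
  different lookup table; only coverage and injectivity are required.
- The premotor group is labelled PMC throughout to avoid collision with
  the participation-coefficient abbreviation PC.
- Monte-Carlo problem sizes: calibration suites use 5000 null regression
  replicates, 1000 BH comparison vectors, 500 oracle graphs and 20 cohort
  replicates at n = 70 per group — sizes at which the binomial error of
  the estimated rates is well below the decision margins used.

## Known limitations

- The LA reconstruction is *a* weighted local assortativity, not *the*
  one used by any particular toolbox; only its node-sum identity with the
  global coefficient is canonical.
- EC on disconnected graphs assigns near-zero centrality to smaller
  components rather than per-component vectors.
- The cross-scale rules treat conflicting left/right coarse directions as
  a region without a single coarse direction (classified via the
  convergent/cancelling branches); per-hemisphere reporting avoids the
  pooling entirely.
- Real diffusion-MRI inputs must already be connectome matrices; no
  imaging data are read.
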