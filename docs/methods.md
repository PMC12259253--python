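# Methods

`tme-spectra` re-implements, as a tested pipeline, a comparative analysis of
the tumor microenvironment (TME) in imaging mass cytometry (IMC) data from
two patient groups — here labelled PWH ("people with HIV"-like) and PWOH
(control). The pipeline has two arms: a cell-segmentation arm (nuclear
segmentation → gating → clustering → per-group statistics → spatial
statistics) and a segmentation-free spectral-graph arm (CK-centred image
patches → personalized-PageRank steady-state features → diffusion-map
embedding → leave-one-case-out SVM → marker ranking). A synthetic cohort
generator supplies ground-truth data with the statistical and spatial
structure the analyses assume, so every stage can be validated by recovery
of planted signals.

## Synthetic cohort generator

Each case contributes one region of interest (ROI), a 200×200 px image at
1 µm/px (the ablation spot size of IMC instruments). The tissue model is
deliberately minimal:

* **Tumor nest.** A union of two overlapping disks near the ROI centre
  (radius ≈ 0.25–0.3 of the ROI side). CK+ tumor cells are placed uniformly
  inside the nest; everything outside is stroma. This reproduces the
  CK+/CK− compartment structure of NSCLC cores without modelling histology.
* **Immune compartment.** CD4 T cells, CD8 T cells, CD68+ macrophages (TAMs)
  and CD20+ B cells are placed in the stroma at distances from the nest edge
  drawn as `Exponential(20 µm) + shift(group)`. The exclusion shift defaults
  to 15 µm in the PWH-like group and 0 in the control group, producing the
  immune-exclusion phenotype (larger immune-to-tumor distances) in one group.
  Placement retries at the *same* drawn distance when the hard-core
  constraint rejects a position, so crowding does not bias the realized
  distance distribution.
* **Hard-core packing.** Cell centres keep a minimum separation of 9 px
  (nucleus diameter + margin), guaranteeing segmentability. Infeasible
  configurations raise rather than degrade.
* **Intensities.** Cell *i* of population *P* draws, for marker *m*,
  `exp(mu[P, m, group] + delta_case[m] + noise_sd * z)` with
  `delta_case ~ N(0, 0.25)` shared by a case's cells (the between-patient
  variability the mixed model is meant to absorb) and `z ~ N(0,1)` per cell
  (`noise_sd = 0.4`). Lognormal draws keep intensities non-negative and
  right-skewed, as IMC counts are; no published noise model exists for IMC
  signal, so the family is isolated behind the config. Default group
  log-means for the differential markers follow the magnitudes of the
  random-effects estimates the pipeline is meant to recover (e.g. KI67 on
  CD8 T cells 1.62 vs 0.53; PD-1 0.27 vs 0.18; PD-L2 on TAMs 0.30 vs 0.20);
  note the *raw* group mean of a lognormal is `exp(mu + sigma²/2)·E[e^δ]`,
  about 12% above `exp(mu)` at the default variances.
* **Exhausted T-cell subpopulation.** A fraction of CD4/CD8 T cells
  (defaults 35.2%/19.9% in the PWH-like group vs 9.8%/4.7% in the control,
  matching the reported cluster expansions) is flagged "exhausted" and draws
  high PD-1/LAG3/KI67 and low GRZB, giving the clustering stage a planted
  subpopulation whose group enrichment it must recover.
* **Rendering.** Each cell paints a nuclear disk (radius 3 px) on the DNA
  and histone channels and a cytoplasm/membrane disk (radius 6 px) carrying
  its lineage and functional markers at the drawn per-cell value; overlaps
  take the pixel-wise maximum; the background is Poisson(0.05) counts.
  Pixel-level texture within a cell is *not* modelled — per-cell variability
  enters through the lognormal draw. `render=False` skips painting and
  returns truth tables only, which is how the statistics-calibration
  experiments run at scale.

What passing tests on this generator do **not** show: robustness to
segmentation errors under dense cell contact, isotope spillover, acquisition
artefacts, or marker co-expression structure beyond the planted effects.
The generator validates the *statistical machinery*, not instrument physics.

## Segmentation

Nuclei are detected on the summed DNA channels: Gaussian smoothing
(σ = 1 px), threshold (Otsu by default — the original workflow used an
interactive tool, an automatic default keeps the pipeline headless; an
absolute threshold can be supplied), 4-connected components (no diagonal
bridges), minimum nucleus area 4 px. Each nucleus is expanded by a fixed
Euclidean radius (default 3 px): a background pixel joins a cell iff it lies
within the radius of some nucleus pixel; pixels reachable from several nuclei
go to the nearest nucleus *centroid*, which places the inter-cell boundary on
the perpendicular bisector — the locus at the median of the two nucleus
distances. Exact ties go to the lowest label (deterministic). Per-cell
mean raw intensities, area, and centroid form the cell table; intensities
are never transformed at this stage.

## Phenotyping

**Gating** is ordered rule evaluation on marker positivity (first match
wins): CD4 T = CK− CD68− CD20− CD3+ CD4+ CD8−, CD8 T mirrored, TAM =
CK− CD68+ CD20− CD3−, tumor = CK+ CD68− CD20− CD3−, plus a B-cell rule.
Unmatched cells are "unassigned" — the labels partition the population.

**Clustering** follows the PhenoGraph recipe: arcsinh (cofactor 5) then
per-marker z-score (standard for mass-cytometry intensities; the transform
is isolated in `ClusterModel`), exact Euclidean kNN (default k = 15),
Jaccard shared-neighbour edge weights, Louvain community detection at
resolution 1.0 with a fixed seed (networkx's implementation). The number of
clusters is emergent, not imposed; tests assert recovery of planted
structure, not a particular count. Note Louvain at resolution 1 splits
large homogeneous blobs — recovering coarse structure exactly needs a lower
resolution, which the model exposes.

**Group statistics.** Per cluster: group proportions, fold change
(PWH-like group in the numerator), two-sided Fisher exact test on the
(in-cluster / not) × group table, Holm adjustment across clusters. Per
marker: a pooled two-sided Wilcoxon rank-sum test *and* a linear mixed model
(`y ~ group` with a random intercept per case, REML via statsmodels), both
Holm-adjusted across the marker panel. The pooled rank test treats cells as
independent and is anti-conservative when between-case variance exists —
that is precisely why the mixed model is the inferential test; the null
calibration experiment checks the mixed-model p-values, and the default
optimizer is the statsmodels BFGS path (L-BFGS collapses the variance to
the boundary on these data), with a conjugate-gradient retry and an OLS
fallback for genuinely singular fits (flagged, never silently dropped).
Cluster × marker heatmaps min-max scale cluster mean intensities to [0, 1]
per marker; constant markers map to 0.

## Spatial statistics

Minimum Euclidean distances between cell types are computed within each ROI
(cells in different tissue cores have no meaningful mutual distance) and
pooled across ROIs per group; same-type queries exclude the cell itself.
Group comparison: two-sided Wilcoxon rank-sum with tie-corrected normal
standardization Z, and effect size r = Z/√N with N = n₁ + n₂ the total
number of minimum-distance measurements (positive r ⇔ group-1 distances
stochastically larger). The p-value is scipy's (exact for small tie-free
samples). Neighborhood enrichment standardises observed co-neighbour edge
counts on a fixed spatial graph (default: symmetrized kNN, k = 6) against a
label-permutation null (default 1000 permutations, seeded; an exhaustive
mode enumerates all distinct labelings when feasible, used by the oracle
tests). Pairs with zero null variance get z = 0.

## Spectral patch classifier

Per case, 14 square patches of side 35 µm are selected greedily at
successive maxima of the box-filtered CK channel, excluding overlaps
(35 µm² appears alongside 35 mm² in the source material; 35 mm exceeds a
tissue core, so the side is taken as 35 µm and is configurable). Patch
feature = mean expression per marker.

Per case, a Gaussian-kernel affinity graph over its patches is built on
per-case-standardized expression vectors, ε = median squared pairwise
distance. For each marker, a personalized PageRank walk runs on this graph
with the marker's per-patch expression as the restart distribution; its
steady state (SSD, a probability vector over the case's patches) is the
marker's feature. Damping defaults to **α = 0.5**: on a ~14-node dense
graph one damped step mixes almost completely, so the classical web-graph
value 0.85 leaves the steady state ≈85% graph-stationary — identical across
markers — and nearly erases the per-marker signal (in pilot simulations,
planted-marker ranking recovery fell from 12/12 at α = 0.3 and 11/12 at
α = 0.5 to 4/12 at α = 0.85). Stacking SSDs gives the markers × patches
representation matrix; each (case, marker) row block sums to 1. An
alternative construction that walks over a *marker* graph within each patch
is available behind `strategy="marker_graph"`.

**Embedding and classification.** Patch columns are centred over markers
before embedding — the across-marker mean of a column is a
marker-independent connectivity quantity of the patch (it reflects only the
patch's position in its case graph) and otherwise dominates distances.
Diffusion maps use a Gaussian kernel (ε = median squared distance),
Coifman–Lafon density normalization (α = 1; without it the leading
eigenvectors localize on tight patch clusters and carry no usable
structure), and the row-normalized Markov matrix; the trivial (λ = 1,
constant) eigenpair is excluded and the default embedding keeps 10
components. Held-out patches enter by Nyström extension, which reproduces
training coordinates exactly by construction. Coordinates are standardized
(training-fold statistics) before an RBF SVM (C = 1, γ = "scale",
class-balanced weights — in leave-one-case-out folds the held-out case's
group is always the training minority, and an unweighted SVM predicts the
majority class for ambiguous patches, which systematically inverts case
votes). The case label is the majority vote over its patches; an exact vote
tie is broken by the sign of the summed SVM decision values, keeping the
vote deterministic while leaving the label-permutation null at chance.
Leave-one-case-out hygiene: kernel bandwidth, eigenbasis, coordinate
scaling, and the SVM are all fit per fold on the training cases only (the
fold embeddings are label-independent and are cached so permutation nulls
rerun cheaply). Accuracy is reported at both patch and case level; the
headline is case level.

**Marker ranking.** Patch identities are not comparable across cases, so
each case's SSD per marker is sorted descending (rank alignment), averaged
within group (aligned on the common minimum patch count when unequal), and
markers are ranked by the L1 distance between the two group-average sorted
vectors.

## Validation experiment sizes

The recovery and calibration experiments run at sizes chosen to give stable
pass/fail behaviour at desk scale: classifier recovery uses 20 cases/group
(14 patches each, planted log-shift 2.0 on PD-L2/CD25), ranking recovery 50
replicate cohorts of 8 cases/group (single planted marker, log-shift 2.5 on
PD-L2 over TAMs and tumor cells), null calibration 200 replicate truth-only
cohorts of 8 cases/group, and the spatial-direction check 50 replicate
truth-only cohorts of 4 cases/group at the default 15 µm exclusion shift.

## Numerical choices and degenerate inputs

* PageRank: power iteration to an L1 residual of 1e-12 (cap 10⁴
  iterations; non-convergence raises with the residual). A marker expressed
  nowhere in a case falls back to a uniform teleport. Zero pairwise patch
  distances fall back to ε = 1 (equal weights).
* Diffusion map: eigenvector signs fixed (largest-magnitude entry positive);
  requesting more components than the nontrivial spectrum raises.
* Wilcoxon Z uses the tie-corrected variance; zero variance gives Z = 0.
* Min-max heatmap scaling maps constant markers to 0, not NaN.
* Empty populations in summaries are reported with n = 0 and NaN, never 0.
* All simulation randomness flows from numpy `SeedSequence` spawning — one
  master seed reproduces a cohort bit-for-bit.

## Known limitations

* The tissue model is two-compartment and 2-D; no vasculature, necrosis, or
  tertiary lymphoid structures, and only one ROI per case by default.
* The spectral arm's discrimination relies on patch composition
  heterogeneity; a marker shifted uniformly across *all* patches of a case
  is invisible to SSD features by construction (teleport normalization), as
  it is to any per-case-normalized representation.
* MCD files are out of scope; images enter as multipage TIFF/OME-TIFF.
* Survival analysis and the in-vitro functional assays of the source study
  are out of scope.
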