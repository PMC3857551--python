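# Methods

## The analysis

`coactnet` implements a meta-analytic co-activation network pipeline over
peak-coordinate data. The processing stream has four steps, repeated over a
grid of ICA model orders:

1. **Modeled-activation (MA) images.** Each experiment's reported peak
   coordinates (mm, Talairach-like space) are smoothed with an isotropic
   Gaussian kernel of FWHM 12 mm (sigma = FWHM / (2·√(2 ln 2)) ≈ 5.10 mm),
   unit peak height, combined voxelwise by maximum. The masked volumes of
   all `e` experiments stack into a voxels × experiments matrix.
2. **Spatial ICA at model order d.** The experiments × voxels matrix is
   centered per voxel, reduced to its top-d singular modes, and whitened;
   FastICA (tanh contrast, symmetric decorrelation, max 1000 iterations,
   tolerance 1e-6) rotates the whitened spatial data into d maximally
   non-Gaussian sources. Writing the SVD as X = U Σ Vᵀ and the ICA rotation
   as W, the stored objects are the experiment modes V_d = U_d Σ_d, the
   mixing matrix M_d = Wᵀ/√v, and unit-variance spatial sources S = W·√v·Vᵀ_d,
   so that V_d M_d S reconstructs the rank-d data and M = V_d M_d holds the
   least-squares weight of each component in each experiment.
3. **Metadata projection.** With P the binary classes × experiments label
   indicator, the metadata matrix P_d = P M quantifies how strongly each
   taxonomy class (task paradigm or behavioral domain) loads on each
   component. Rows are not normalized by class frequency (a flag exists for
   sensitivity analysis).
4. **Clustering and model-order selection.** Metadata classes are clustered
   by single-linkage agglomeration on 1 − r distances (r = Pearson
   correlation of P_d rows). The cophenetic correlation coefficient CC_c —
   the Pearson correlation between the original condensed distances and the
   cophenetic distances (first-merge heights) — scores how faithfully the
   dendrogram represents the metadata geometry. Orders with
   CC_c > mean + 2·sd over the scanned grid are selected; the global argmax
   is always reported, ties broken toward smaller d. Average linkage is
   available behind a flag.

Fractionation relates a low-order and a high-order decomposition: the
unthresholded z-maps are cross-correlated over the mask (Pearson, per
component pair), each high-order component is assigned to the low-order
parent with which it correlates most strongly (ties toward the lower
component id), components with near-uniform metadata profiles are flagged
as artifacts and excluded, and sub-network counts per parent group give
per-group fractionation rates.

## z-statistic conversion

Sources are converted to z-units by fitting a Gaussian null to the
background of each source histogram: Gaussian mixtures with 1–3 components
(background plus up to two activation tails) are fitted by EM with robust
median/MAD initialization, the model is chosen by BIC, and the
dominant-weight component provides the null mean and sd;
z = (source − mean)/sd. If the fit degenerates, plain median/MAD
standardization is the fallback. The mixture is fitted on a deterministic
thinning of at most 20,000 voxels and then applied to all voxels.
Thresholding (default z > 4, strict) happens downstream in the component
statistics and is recorded, not baked into the maps.

## Numerical conventions

- "Identity covariance" of whitened data and "unit variance" of sources are
  second moments about zero. The data are centered per voxel across
  experiments (not per map across voxels), so spatial means of the modes
  are near but not exactly zero; using second moments makes the whitening
  identity exact to machine precision.
- Singular-vector signs follow a deterministic convention (the
  largest-magnitude voxel loading of each spatial mode is positive). This
  makes the whitened data, the ICA solution and the CC_c curve invariant to
  the order in which experiments are supplied — the order-randomization
  check then reproduces components at |r| ≈ 1 exactly.
- Source signs are fixed by non-negative skewness; components are ordered
  by explained variance (descending).
- A zero-variance metadata row has undefined correlations; its 1 − r
  distances are set to 1 (maximally uninformative) with a warning.
- Model orders d ≤ 2 are degenerate for the 1 − r metric: the Pearson
  correlation between two length-2 rows is identically ±1, every distance
  is 0 or 2, the dendrogram is exactly ultrametric, and CC_c = 1 for any
  data whatsoever. The scan records these values but flags the orders as
  degenerate and excludes them from the mean/sd, the selection rule and the
  argmax.
- Centering is the default for the scan. For planted-source recovery checks
  the decomposition is run with `center=False`: k single-blob networks span
  only k − 1 centered dimensions (their centered means sum to zero), so all
  k sources are exactly representable at d = k only without centering.

## The synthetic corpus

The generator emulates the structure the analysis assumes about a large
curated coordinate database:

- `k_networks` latent networks, each a set of Gaussian blobs in a
  Talairach-like bounding box (−90..90, −126..90, −72..108 mm), network
  centroids rejection-sampled with ≥ 40 mm separation, blob centers
  scattered around the centroid (sd 15 mm) and snapped into the mask.
- Experiments are assigned to networks round-robin (balanced design). Each
  draws 5–12 peaks spread evenly over its network's blobs (co-activation:
  all regions of a network activate together) plus Gaussian jitter of sd
  6 mm, and 3–8 background foci placed uniformly in the mask — published
  experiments report peaks outside their dominant pattern, and this
  background is what gives z-maps a non-degenerate null. Peaks jittered out
  of the mask are clipped to the nearest in-mask voxel center (counts
  recorded).
- Labels: each network owns a disjoint block of 4 taxonomy classes; each is
  attached to the experiment with probability `label_fidelity` (default
  0.95) and every foreign class with probability `false_label_rate`
  (default 0.02). The combined taxonomy helper mirrors the field's standard
  label space of 75 paradigm classes + 50 behavioral domains = 125 classes.
- `blobs_per_network` defaults to a single blob, which makes the ICA model
  order of the planted data equal the network count (identifiability).
  Multi-blob networks with `blob_coverage < 1` (a blob is expressed by an
  experiment with that probability) are the substrate for fractionation
  studies, where sub-blob expression must vary across experiments for ICA
  to be able to split networks.

Two frozen study conditions are used by the analysis drivers and the
acceptance script:

- **Recovery corpus**: k = 5, e = 300, single-blob networks, 4 mm grid —
  used for the model-order scan, the order-randomization check and the
  subsample robustness check.
- **Fractionation corpus**: k = 5, e = 1000 (600 in the driver), 3–5 blobs
  per network, blob scatter 28 mm, coverage 0.6 — used for component
  statistics across orders and for fractionation. The larger e keeps
  d/e ≈ 0.025 at d = 25, the regime in which per-component support stays
  dense.

What the generator does **not** emulate: fMRI time series and scanner
noise, publication bias across the taxonomy, uneven behavioral-domain
frequencies (a skew option is available but defaults to uniform), spatial
autocorrelation of real anatomy, and the semantic identity of networks.
Passing tests therefore show that the pipeline machinery is correct and
that its statistics behave as designed on data with planted structure —
not that the same model orders would be selected on real databases.

## Known limitations of the CC_c argmax at desk scale

On planted corpora of this family the true class geometry is exactly
rank-k: same-network classes are near-duplicate indicator rows. The
consequence, verified across many generator variants, is that CC_c rises
with d toward a plateau for d ≥ k (higher orders estimate the same
block-ultrametric geometry with less boundary contamination) instead of
peaking at k; on the plateau the argmax is decided by ICA noise at the
1e-3 level. Additionally, correlation distances in ≤ 3 effective
dimensions are near-perfectly chainable, inflating CC_c at very small d.
The planted-order-recovery check in the end-to-end test suite states the
peak-at-k expectation and currently fails for this structural reason; the
robustness checks therefore use a scan grid that ends below the plateau,
where the argmax is a well-defined statistic. The mean supra-threshold z
of components likewise *decreases* with model order on synthetic corpora
(estimation noise grows faster than focality at these corpus sizes),
whereas the supra-threshold voxel count decreases as expected.

## Reproducibility

Every stage is a pure function of (config, seed): one root seed spawns
per-stage and per-replicate substreams via `SeedSequence`, so adding
replicates never perturbs earlier stages, and two runs with the same
config produce byte-identical tables (timestamps excluded).
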