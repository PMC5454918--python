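# Methods

This note documents the models implemented in `comboloc`, the parameter
defaults and why they were chosen, what the synthetic-data generators do
and do not emulate, and the numerical decisions made where the
underlying procedure left room for choice.

## Single-molecule localization

Raw data are multi-frame camera stacks in which only a sparse, blinking
subset of fluorophores is bright per frame.  Detection and estimation
proceed per frame:

1. **Background** is estimated as the median pixel intensity of the
   frame.  The median is robust to the sparse bright spots and needs no
   parameters; a mean would be biased upward by the signal itself.
2. **Candidate spots** are local intensity maxima at least 4× the
   background (configurable `threshold_factor`).  Each must fit as a
   square ROI (default side 7 px at 100 nm pixels, i.e. 700 nm — ample
   for a ~150 nm-σ PSF) fully inside the frame.  When two candidates lie
   closer than one ROI side, only the brighter is kept, so a single PSF
   is never counted twice.
3. **Signal isolation**: twice the background is subtracted from every
   ROI pixel and negative results are clamped to zero.  Clamping keeps
   the weights `q_i` non-negative, as the moment formulas require;
   the factor 2 over-subtracts the mean background so that background
   shot noise rarely survives in the tails.
4. **Moments**: photon sum `Q = Σ q_i`, intensity-weighted centroid `μ`,
   and weighted variance `σ²` over pixel centers.  Pixel `(r, c)` has
   center `((c+0.5)·s, (r+0.5)·s)` for pixel size `s`; x is the column
   axis, origin at the frame's top-left corner.
5. **Precision**: `Δμ_x = sqrt(1/(12Q) + Σ((x_i−μ_x)/Q)²(q_i+N_B))`,
   evaluated in pixel units and scaled to nm.  The `1/(12Q)` term is the
   finite-pixel (uniform-within-pixel) variance per photon; the sum
   propagates signal and background shot noise through the centroid.
   `N_B` is the per-pixel background level *before* the 2× subtraction,
   added to every ROI pixel's variance contribution.

Known limitations: the centroid-of-clamped-ROI estimator is slightly
conservative — clamping truncates the PSF tails, so the reported `σ` is
a lower bound on the optical PSF width, and the reported precision can
underestimate the true error by tens of percent at moderate SNR.  The
round-trip requirement used in the tests (≥ 90% of planted events
recovered within 3Δμ) holds in the SNR ≥ 4 regime the detector is
specified for.  No drift correction, Gaussian MLE refinement, multi-
emitter splitting, or 3D estimation is attempted.

## Rendering

Three renderings of a localization set are provided.  *Pointillist*:
binary occupancy, half-open binning `floor(coord/pixel)`.  *Density*:
each point is weighted by the number of other points within radius `R`
(default 1000 nm); points with weight 0 are dropped and the rest
contribute a unit-integral Gaussian (default σ 50 nm) scaled by the
weight.  Whether the neighbor count should scale the Gaussian's
amplitude or its integral is a free choice; integral scaling was chosen
so the image total equals the sum of neighbor counts, making totals
comparable across parameter settings.  *Localization image*: one
unit-integral Gaussian per point with that point's per-axis precision as
σ, so the image integral approximates the number of points.  All
kernels are pixel-integrated (erf differences) and truncated at 4σ
(≤ 1e-4 of mass lost); default output pixel 10 nm.

## Cluster detection and shell profiles

DBSCAN with radius 100 nm and minimum point count 10 identifies
ALU-dense regions.  The neighborhood count *includes the point itself*
(the common library convention), so a tight blob of exactly 10
localizations is a cluster.  Border points reachable from several
clusters join the cluster discovered first in index order, which makes
labeling deterministic for a fixed input order.  The implementation
delegates to `sklearn.cluster.DBSCAN`; an independent O(n²)
density-reachability closure in the test suite verifies label-for-label
agreement on random mixed instances.

Cluster centers are centroids of the convex hull of the member points,
evaluated with the Surveyor's (shoelace) formula
`C = (1/6A)·Σ(v_i+v_{i+1})·(x_i y_{i+1} − x_{i+1} y_i)`.  The hull is
the canonical simple polygon of an unordered point set; degenerate sets
(< 3 points, collinear) fall back to the arithmetic mean.  Distances are
Euclidean in the 2D projection; the data model assumes a thin optical
section and makes no 3D correction.

Shell profiles count target points in half-open annuli `[k·w, (k+1)·w)`
of width `w` = 10 nm (default max radius 1000 nm) and divide by the
annulus area, so the sum of shell counts equals the number of targets
within the max radius.  The mean profile averages per-cluster densities
shell by shell (clusters first; pooling across nuclei is concatenation
of centers).  Averaging pooled-over-all-points instead would weight
clusters by their target counts; both orderings are available, the
cluster-mean is the default.

Colocalization between two channels is reported as the fraction of
points of one set with a nearest neighbor in the other within a
threshold; it is asymmetric and both directions can be reported.

## Probe design

Probes are exact k-mers (default 17).  Scanning is exact string search
over uppercase sequence; `N` never matches, soft-masked lowercase
matches by default (masking is annotation, not absence) with a flag to
exclude it.  The default strand policy is `both`: the probe hybridizes
by Watson–Crick pairing, so a binding site exists wherever either the
probe or its reverse complement occurs on the forward strand; a
palindromic probe is counted once.  Coordinates are 0-based half-open
throughout.  Bin maps count hits in `floor(start/500 kb)` bins.
Specificity uses full containment: a hit counts as inside an annotation
only if its whole k-mer interval is contained in a single element, and
an element counts as covered only if it fully contains a hit.  Candidate
ranking puts all probes meeting the specificity floor (annotation
overlap ≥ 0.99 of hits) above all others, then sorts by hit count, with
the consensus offset as the deterministic tie-break.

Genome-wide occurrence totals for a real assembly depend on the assembly
version and strand convention; `scripts/probe_genome_comparison.py` runs
the evaluation against a user-supplied assembly offline.

## Dosimetry

The calibration model is `N(D) = a·D² + b·D + c`, fitted by unweighted
OLS to the mean count per dose (one observation per dose, so three
distinct doses interpolate exactly).  A per-cell fit is exposed as an
option; no sign or monotonicity constraints are imposed.  Reference
coefficients used as generator defaults are a = 3054, b = −1.148e4,
c = 2.139e4 over doses {0, 0.1, 0.5, 1, 2} Gy.  Dose inversion returns
the smallest non-negative root of `a·D² + b·D + (c − N)` and, when
a > 0, is restricted to the decreasing branch `[0, −b/2a]`; counts with
no root there raise an out-of-calibration error rather than
extrapolating.

## Synthetic-data generators

The generators define the study conditions the tests run under; their
defaults are fixed and are not tuned per test.

**Stacks.**  Emitters blink independently per frame (Bernoulli, default
p = 0.02 over 2000 frames).  An ON emitter emits Poisson(3000) photons
whose positions scatter with the PSF σ (150 nm) and are binned into
100 nm pixels over Poisson(10) background.  This gives peak-to-
background ≈ 20, comfortably in the detector's ≥ 4× regime, and ~3 nm
nominal precision.  Not modeled: triplet-state kinetics, bleaching
decay, EM-gain noise, read noise.

**Nuclei.**  The ALU channel is a Neyman–Scott-type process: 200 parent
centers uniform in a 5 µm-radius disc, each with Poisson(30) Gaussian
offspring (σ 40 nm, floored at 10 points), plus 5% uniform noise.
Parents keep a 400 nm hard-core minimum separation so that planted
clusters are individually resolvable at the 100 nm DBSCAN radius — the
cluster-count calibration is a statement about resolvable clusters, not
about DBSCAN's merging behavior under overlap.  The heterochromatin
channel is an inhomogeneous Poisson process (baseline 2e-5 /nm²) whose
intensity is multiplied by 0.05 within 100 nm of the *nearest* cluster
center, by 3 between 100 and 300 nm, and by 1 elsewhere: association
without co-localization, as an explicit parameterized structure.  All
points receive 10 nm Gaussian localization jitter.  Because the
multiplier depends on the nearest center only, profiles measured around
one center pick up the annuli of neighbors beyond ~400 nm; measurements
of the configured ratio should use sparse configurations (separation
> 2× outer radius).  Real nuclei differ in ways the generator ignores:
cluster size and shape heterogeneity, chromatin polymer correlations,
nuclear boundary effects, detection efficiency gradients — so passing
tests validate the analysis chain, not biological realism.

**Genomes.**  I.i.d. uniform background with non-overlapping consensus
copies planted forward-strand at uniformly sampled positions (bounded
rejection), each independently point-mutated at the configured
substitution rate; the truth BED records every copy.  At rate 0 every
copy carries the probe k-mer exactly once, so hit totals are exact; at
rate r each copy retains it with probability (1−r)^k.

**Dose series.**  Per-cell counts are `round(N(D) + N(0, σ))`, floored
at 0, with σ = 500 and 35 cells per dose by default; a Poisson option
exists.  The thinning mechanism is purely phenomenological.

## Numerical and testing choices

* All randomness flows through `numpy.random.default_rng(seed)`;
  generators are bit-reproducible per seed.
* DBSCAN neighborhood comparisons use ≤ radius (library convention);
  exact-tie configurations are measure-zero for continuous coordinates.
* Flatness checks of shell profiles under complete spatial randomness
  are sampling-noise limited in the innermost shells (relative sd
  ≈ 1/√(λ·π·w²·n_centers)); the test configurations use λ = 0.01 /nm²
  and 400 centers so that this noise (~2.5% at shell one) sits well
  inside the 10% flatness band being asserted.
* The acceptance script simulates 20 nuclei (~9,400 points each); the
  full run takes a few seconds on one CPU.
* Problem sizes throughout the suite (≤ 1000-point DBSCAN oracle
  instances, 1 Mb scan-oracle sequences, 2000-frame stacks with 5
  emitters) were chosen so each check is statistically meaningful while
  the whole suite stays fast.
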