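# Methods

`protocol_lab` is a simulation laboratory for a question that comes up
whenever diffusion-MRI connectomics is moved from a heroic reference
acquisition to a population protocol: how far can the angular sampling
(number of diffusion directions) and the spatial resolution be reduced
before fiber-orientation estimates and the resulting connectome
degrade?  The package reproduces the full chain of such a protocol
study on synthetic data with known ground truth: gradient-scheme
design, conditioning audits, signal simulation, retrospective angular
and spatial downsampling, multi-fiber model fitting with uncertainty,
probabilistic tractography, and connectome comparison.

## Gradient schemes

Direction sets are built by electrostatic repulsion of antipodal
charge pairs: minimize

    E = sum_{i<j} 1/|v_i - v_j| + 1/|v_i + v_j|

over unit vectors, by L-BFGS on an unconstrained parametrization
(vectors normalized inside the objective), starting from a
deterministic golden-angle spiral plus seeded random restarts (default
3), keeping the lowest-energy optimum.  The generator seed defaults to
20200421 and is treated as a *design constant*: the gradient table is
part of the protocol under study, not a noise source.  With
`iterations=0` the spiral start is returned unoptimized, which is
already near-uniform and is the practical choice for very large sets
(thousands of directions).

Angular subsets mirror retrospective extraction from an acquired
table: an ideal n-direction set is generated, then each ideal vector
is snapped to the acquired direction maximizing the absolute dot
product (diffusion is antipodally symmetric, so g and -g are
equivalent).  Selected indices are unique; collisions fall through to
the next-best unused vector, assigned greedily in descending match
quality over all pairs.

b0 volumes are stored as zero vectors with b-value 0, interleaved one
per 12 weighted volumes by default, and excluded from all
direction-set mathematics.

## Conditioning

The stability of a scheme is measured through the N x 6 second-order
design matrix with rows

    (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz),

no b0/constant column.  The condition number sigma_max/sigma_min is
computed from the eigenvalues of the 6 x 6 Gram matrix (identical to
the SVD ratio, much cheaper in batch).  Rotational stability applies
Haar-uniform random rotations — unit quaternions from normalized 4D
Gaussians — to the whole direction set and summarizes the condition
number across rotations (default 50,000).  Degenerate draws are kept
as +inf and counted, never dropped.

For a perfectly uniform direction distribution the Gram eigenvalues
are N/3, 4N/15 (x2) and 2N/15 (x3), so the condition number tends to
sqrt(5/2) = 1.5811 as N grows.  Note this is a *limit*, not a bound:
finite schemes fluctuate around it and can dip below (a well-placed
60-direction set can sit near 1.56 at a favorable orientation).  The
package asserts convergence to the limit, with finite-N slack, and
makes no strict lower-bound claim.

The stability audit (`conditioning_table`) evaluates the snapped
subsets — the same objects the imaging pipeline uses.  With the
default design seed the full 120-direction table gives unrotated CN
1.5815, rotation-mean 1.5818 and std 6.7e-4, and the snapped
60-direction subset ranks second by mean CN.  The 12-direction
subset's mean CN is strongly realization-dependent (1.65-1.72 across
generator optima): with so few directions, individual snap errors of a
few degrees move the Gram spectrum appreciably.

## Phantom

The synthetic brain is an ellipsoid of isotropic tissue (about 40% of
a 64^3 grid at 43 um voxels) containing a small hippocampal-system
circuit per hemisphere:

| region  | kind | geometry                          | sticks                       |
|---------|------|-----------------------------------|------------------------------|
| fi      | wm   | straight slab, 5x5 voxels         | along the bundle, f = 0.70   |
| cc      | wm   | straight slab crossing both fi    | along x, f = 0.70            |
| cross   | wm   | fi-cc intersection                | two sticks at 90 deg, f = 0.35 each |
| fx      | wm   | curved Bezier tube, 1-2 voxels    | local tangent, f = 0.65      |
| ac      | wm   | curved Bezier tube, ~2 voxels     | local tangent, f = 0.70      |
| Hc, Spt, Hyp, Th, Ctx | gm | spheres | one stick per voxel, random orientation, f = 0.25 |

Region sizes are calibrated so the hippocampus-like blobs occupy ~2.6%
of the brain and the thin fornix-like bundle ~0.05% — the two ends of
the robust/vulnerable spectrum the study design probes.  Overlapping
shapes are painted rarest-last so thin structures keep their labels.

Two modelling choices matter and are deliberate:

* **Curved thin bundles.**  The fornix-like and association bundles
  follow quadratic Bezier arcs with the stick along the local tangent,
  so orientation turns by 60-70 degrees along each tract.
* **Orientationally incoherent gray matter.**  Each gray-matter voxel
  draws its own stick orientation.

Both create intra-voxel orientation heterogeneity once voxels are
enlarged.  This is the physical mechanism by which losing spatial
resolution degrades orientation estimates in real tissue.  Without it,
retrospective k-space cropping only averages noise down (SNR rises by
factor^3) and downsampling would — unphysically — *improve* every
estimate.

Signal follows the ball-and-stick forward model at a single shell,
b = 4,000 s/mm^2, shared diffusivity d = 1.0e-3 mm^2/s, S0 = 1 (the
b-value is the acquisition's; the tissue parameters are conventional
ex-vivo-scale choices, as the study protocol itself fixes no tissue
model).  Noise is Rician — magnitude of two Gaussian channels with
sigma = S0/SNR, default SNR 30.  Unlabelled brain tissue is a pure
ball; outside the brain the signal is zero (noise floor only).

What the phantom does **not** emulate: anatomically accurate geometry,
T1/T2 contrast, eddy currents, susceptibility, gradient
nonlinearities, spatially varying SNR, or fiber populations beyond two
per voxel.  Passing tests show the *estimation and comparison chain*
behaves as the study reports under the stated mechanisms; they do not
certify quantitative percentages for real mouse tissue, which depend
on the specimen.

## Downsampling

Lower spatial resolution is simulated by cropping the central
(dim/factor)^3 block of the centered 3D DFT of each volume, scaling by
1/factor^3 so the image mean is preserved, inverse transforming and
taking the magnitude.  The DC bin sits at floor(dim/2); for even
dimensions the crop window is asymmetric and the Nyquist plane is
dropped.  Cropping composes exactly in the linear (complex) domain;
through the magnitude pathway composition is exact only for
band-limited content, since the magnitude is nonlinear — the tests
distinguish the two.  Coarse label maps assign each block the globally
rarest label present in it, so 1-voxel structures remain addressable
after downsampling (majority voting would delete them).

## Fitting

`fit_tensor` is the standard log-linear least-squares tensor fit (the
second-order design augmented with a constant column for log S0),
giving MD, FA and eigenvectors; it seeds the multi-fiber fit.

`fit_ball_and_stick` fits, per voxel, models with 0..4 sticks:

    S(g) = A0 e^{-b d} + sum_i A_i e^{-b d (g.v_i)^2}

with log-amplitudes and log-diffusivity (positivity and
sum f_i <= 1 for free) and stick orientations as spherical angles.
All voxels are advanced together by a batched Levenberg-Marquardt
loop (per-voxel damping, accept/reject, analytic Jacobians, voxels
leaving the active set on relative-SSE convergence at 1e-12).
Initialization comes from the tensor eigenvectors with a fraction
ladder (0.35/0.25/...); multi-stick models add one perturbed restart.
Model order is chosen by BIC (the SSE is floored at 1e-12 of the
signal energy so noiseless voxels do not produce degenerate
likelihoods; any over-fitted extra stick then falls below the support
threshold).  Sticks with volume fraction below 0.05 are not counted as
dyads — the usual secondary-fiber cutoff.  A model with k sticks is
attempted only when the acquisition has at least 2(3k + 2) volumes,
which caps 12-direction protocols at one stick unless extra b0s are
carried.

Uncertainty is residual bootstrap rather than MCMC: resample each
voxel's residuals with replacement, refit warm-started (8 LM
iterations), match replicate sticks to the original dyads by absolute
dot product, and report per dyad

    dispersion = 1 - || mean of sign-aligned replicate dyads ||,

a scalar in [0, 1] (0 = perfect agreement, ~0.5 for isotropic
scatter).  Default 50 replicates (the experiment grid uses 25).

## Tracking

Probabilistic streamlines: each seed voxel contributes
`samples_per_voxel` samples started at uniform random positions and
propagated bidirectionally in 0.5-voxel steps.  At each step the
nearest voxel's dyad set is consulted; a dyad is drawn with
probability proportional to its (supported) fraction, sign-aligned
with the heading, then perturbed by a tangent Gaussian kick of angular
scale asin(sqrt(dispersion)) — for a small-angle spherical Gaussian,
dispersion ~ sigma^2, so this converts the stored scalar back to an
angular standard deviation (floored at 0.02 rad).  Termination: mask
exit (a step is only taken into voxels with a supported dyad, so
endpoints always carry a label or sit at the tract end), a turn above
the 80-degree curvature threshold, or the step cap.  The paper-scale
defaults (100 samples/voxel, 2,000 steps) are config-exposed; the
experiment grid uses 16 samples and 260 steps, which saturates the
64^3 phantom.

## Connectomes and comparison

A streamline adds one count from its seed region to the region of each
terminal point; endpoint counts in unlabelled voxels go to an
"unassigned" tally.  The matrix is symmetrized as (W + W^T)/2; raw
counts, no normalization.  Left-left subgraphs are extracted by
hemisphere tag, mirroring the study's restriction to left-seeded,
left-targeted connections.

* **Global similarity** — Spearman rank correlation over the
  off-diagonal upper triangle (average ranks for ties; constant
  vectors are an error, not a silent NaN).
* **Per-node similarity** — the Blondel coupled iteration
  S_{k+1} = B S_k A^T + B^T S_k A from the all-ones matrix, normalized
  to unit Frobenius norm, converging on even iterates (tol 1e-9, max
  1,000).  For connectome inputs the adjacency diagonal is removed
  first: seed-region self-counts are an order of magnitude larger than
  any edge and would otherwise dominate the fixed point.  When both
  graphs share a region set, the diagonal of S scores each region;
  thresholding (the 0.1 level in the reporting convention) exposes
  sparsity differences.

## Experiment grid and problem sizes

`run_experiment` simulates the full 120-direction acquisition once and
derives every reduced protocol from it — angular subsets by extracting
the matching volumes (all b0s kept), spatial factors by k-space
cropping — so all protocols share one noise realization, exactly as a
retrospective downsampling study does.  Defaults: 64^3 phantom,
angular subsets {12, 45, 60, 120}, factors {1, 2, 4}, SNR 30, 25-30
bootstrap replicates, 16 samples per seed voxel; roughly ten minutes
on one CPU.  All randomness flows through named seeds derived from one
master seed (the scheme seed stays a design constant), outputs are
CSVs with fixed float formatting, and a manifest hash lets reruns with
an unchanged configuration load the stored tables instead of
recomputing.  Runs with the same configuration are byte-identical.

## Known limitations

* The fitter is Gaussian least squares on Rician magnitude data; at
  very low SNR the noise-floor bias would shift fraction estimates
  (negligible at SNR 30 with S0 = 1).
* BIC plus a support threshold replaces automatic relevance
  determination; three-fiber voxels are rare in the phantom, so the
  k = 3, 4 paths are exercised mostly by noise.
* Orientation lookup in tracking is nearest-voxel; no interpolation,
  no anatomical constraints, no loop checks beyond the step cap.
* The 12-direction subset's condition number is dominated by which
  local optimum the 120-direction table lands in; single-scheme values
  at low N should be read with that realization spread in mind.
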