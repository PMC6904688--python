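# Methods

`penpet` is a desk-scale, self-contained simulation-and-analysis pipeline for
comparing two PET reconstruction strategies on digital phantoms:

* **OSEM** with clinical settings — 3 full iterations, 16 interleaved angle
  subsets, 5.0 mm Gaussian post-filter; and
* **BSREM** — block-sequential regularized expectation maximization, a
  convergent optimizer for the Poisson log-likelihood penalized by a
  relative-difference penalty (RDP), swept over the penalty weight β.

Image quality is scored with NEMA NU-2-style phantom metrics (contrast
recovery, background coefficient of variation, contrast-to-noise ratio) and a
clinical-style lesion suite (41%-of-maximum VOIs, SUV statistics, liver
reference noise, lesion SNR, contrast, MATV).

## Phantoms

**NEMA IQ analog.** Torso cross-section approximated as a 300 × 230 mm
ellipse, constant across slices; six fillable spheres (10, 13, 17, 22, 28,
37 mm) centered on a 57.2 mm ring at 60° spacing, all centered axially on the
central slice; a 44.5 mm cold cylindrical lung insert on the axis. Background
activity 5.3 kBq/ml (the fill arithmetic of 52 MBq in 9800 ml);
sphere-to-background ratios 8:1, 6:1, 4:1, 2:1. Attenuation uses standard
511 keV coefficients: water 0.096 cm⁻¹ inside the body, 0.025 cm⁻¹ in the
lung insert, 0 outside. Voxel membership is a voxel-center-inside-shape
test; partial-volume effects arise from the PSF and the grid, not from
sub-voxel weighting.

**Lesion phantom.** The whole-body-study analog: the same body outline with a
uniform liver-like cylinder (radius 45 mm) and six spherical lesions of 0.5,
1, 2, 4, 8 and 15 ml. The liver maps to SUV-analog 2.2 (the calibration
reference), lesions carry twice the liver uptake (SUV-analog 4.4), and the
surrounding soft-tissue background carries SUV-analog 0.55. Lesions sit in
the low-uptake background rather than inside the liver: a 41%-of-maximum
threshold (0.41 × 4.4 ≈ 1.8) lies *below* the liver level, so a lesion
embedded in liver could not be segmented by that rule — in the clinical
situation being emulated, lesions are distributed through the body and the
liver serves only as the reference region.

**Default grid.** 128 × 128 pixels of 2.5 mm, 19 slices of 2.78 mm. This
preserves the slice-thickness-dependent ROI offsets of the NEMA protocol
(±1 cm → ±4 slices, ±2 cm → ±7 slices) while keeping a full study desk-fast;
the clinical 256 × 256 matrix is available by configuration.

## Acquisition model

2D multi-slice (slice-independent) parallel-beam acquisition: 96 views over
[0, π), 128 radial bins of 2.5 mm. The projector is pixel-driven with linear
interpolation between bins, assembled once as a sparse matrix; forward and
back projection use the matrix and its exact transpose, so the projector pair
is matched by construction. Resolution is modeled as an isotropic in-plane
Gaussian of FWHM 4.5 mm applied in image space (consistent with the ~4.1–4.7
mm FWHM of the emulated scanner near the isocenter); there is no axial blur.

The mean prompts sinogram is assembled as

1. attenuated trues, scaled so that total trues = sensitivity × total
   activity × duration — exactly linear in duration;
2. a scatter term: the trues convolved radially with a 100 mm FWHM Gaussian,
   normalized so scatter/prompts equals the scatter fraction (default 41.7%);
3. an optional flat randoms term (default 0 — no randoms rate is available
   for the emulated system).

Counts are independent Poisson draws per bin. Shorter acquisitions are
produced by binomial thinning of the sampled sinogram — the count-statistics
equivalent of a retrospective list-mode selection, and distributionally
identical to a proportionally shorter Poisson acquisition.

**Effective sensitivity.** The emulated scanner's NEMA sensitivity
(7.5 cps/kBq) counts coincidences over all oblique planes of a 15 cm axial
FOV. A slice-independent 2D model accepts only in-plane coincidences, so the
default sensitivity is scaled by the geometric per-slice axial acceptance,
7.5 × 2.78/150 ≈ 0.139 cps/kBq. This keeps the per-bin count density — and
therefore the image-noise regime, on which every noise-propagation property
of the study rests — comparable to the real acquisition. Applying the 3D
figure verbatim would concentrate the full 3D count budget into 19 direct
planes and produce an almost noiseless simulation in which background
variability is dominated by deterministic reconstruction bias; in that regime
COV neither scales as 1/√T for OSEM nor decreases monotonically with β. The
3D figure remains available (`SENSITIVITY_3D_CPS_PER_KBQ`) and the count
budget identity holds exactly for any configured sensitivity.

What the simulator deliberately omits: TOF (out of scope — findings
attributable to TOF are not reproduced), fully-3D oblique sampling, detector
normalization, dead time, decay during acquisition, and estimated (rather
than exact) attenuation/scatter corrections. Attenuation factors and the
scatter+randoms mean enter the reconstructions as known quantities.

## Reconstruction

Both algorithms share the forward model ȳ = f ⊙ (A P x) + b, with A the
sparse projector, P the image-space PSF, f the per-LOR multiplicative factor
(attenuation × count-budget scale) and b the known additive background.

**OSEM.** Standard multiplicative EM updates over interleaved angle subsets
(subset k takes views k, k+16, …), exactly iterations × subsets updates
(early stopping, as in clinical practice), then the Gaussian post-filter
(σ = FWHM/2.3548, reflective boundaries, in-plane). Voxels with zero
sensitivity (grid corners beyond the circular FOV) are excluded by mask and
reported. Non-negativity holds by construction; the Poisson log-likelihood
trace is recorded per full iteration.

**RDP.** For each unordered in-plane 8-neighbor pair (j, k), with
inverse-distance weights w (1 orthogonal, 1/√2 diagonal):

R(x) = β Σ w_jk (x_j − x_k)² / (x_j + x_k + γ|x_j − x_k| + ε),  γ = 2,
ε = 10⁻⁹·max(x).

R is convex, zero iff the image is uniform, 1-homogeneous in the image, and
its analytic gradient is verified against central finite differences
(< 10⁻⁵ relative) in the test suite.

**BSREM.** Relaxed preconditioned subset ascent on Φ(x) = loglik(x) − R(x):

x ← Π₊[ x + α_n (x/s_m) (∇L_m(x) − ∇R(x)/M) ],  α_n = α₀/(1 + η n),

with s_m the subset sensitivity image, α₀ = 1, η = 0.05, and projection onto
the non-negative orthant. A trust region limits any single subset update to
shrink a voxel by at most 10×: the multiplicative preconditioner makes x = 0
absorbing, and without the bound a strong penalty gradient can capture
background voxels irrecoverably (observed as background collapse at large β);
fixed points are unaffected, and with β = 0, one subset and α ≡ 1 the update
reduces exactly to MLEM (asserted to 10⁻⁸ in the tests). Stopping: relative
objective change below 10⁻⁶ between full iterations or the iteration cap
(30 by default; the headline study uses 15, verified indistinguishable from
80-iteration runs on this system). A divergence guard aborts if the
objective falls more than 10% below its running maximum. This is a
literature-standard BSREM/RDP analog, not a bit-exact clone of the vendor
algorithm, whose internal iteration count and stopping rule are unpublished.

**Calibration.** A single global factor scales each reconstruction so that
the mean over an eroded central background region equals the true background
concentration — the analog of a cross-calibration scan. SUV-analog images
additionally map the liver's true concentration to SUV 2.2.

## Metrics

* Sphere ROIs: one circle per sphere, at the true center, diameter equal to
  the sphere's inner diameter, on the central slice (known geometry, no
  detection step).
* Background ROIs: a fixed template of 12 positions near the phantom
  periphery, replicated on 5 slices (central, ±1 cm, ±2 cm as nearest-slice
  offsets), concentric diameters per position → 60 ROIs per sphere diameter.
  Placement rule: ROI edge ≥ 15 mm inside the body boundary, no overlap with
  spheres or lung, ROI center ≥ 15 mm from their surfaces. (A full 15 mm
  edge-to-edge clearance for the concentric 37 mm ROIs is geometrically
  unsatisfiable against the 37 mm sphere on the NEMA ring; the rule above is
  the closest satisfiable reading and is validated at placement time, with
  violations reported explicitly.)
* CR = ((C_H/C_B) − 1)/((a_H/a_B) − 1); COV = sample SD (n−1) of the 60
  background ROI means over their average (the NEMA background-variability
  convention, as a fraction); CNR = CR/COV. The 2:1 "60 ROIs per slice
  thickness" phrasing is interpreted as 60 ROIs per sphere diameter.
* Lesion VOIs: threshold at 0.41 × (maximum voxel in the seed component),
  6-connected component containing the maximum, ties included. VOIs are
  delineated on the OSEM reconstruction and propagated unchanged. Voxel SD
  inside VOIs uses the population (n) divisor. MATV is implemented verbatim
  as SUV_mean × volume (dimensionally a total-lesion-glycolysis-like
  quantity, not a volume).

## β-matching

Penalty weights do not transfer from the emulated vendor system (they depend
on count level and system model), so the pipeline defines its own matching
procedure: sweep β over a fixed ladder (0.05, 0.1, 0.2, 0.4 — chosen once so
the CR range of the 37 mm sphere brackets OSEM's CR on this system) and
select the β whose seed-averaged CR at 37 mm, 8:1, full counts is closest to
OSEM's, ties toward more regularization. The matched β* plays the role the
β = 750 setting plays on the vendor system and is reused across ratios,
count levels and the lesion study.

## Headline study conditions

The noise-reduction study uses the default grid and geometry, ratio 8:1 at
the 20-min-analog budget (ratios 6:1 and 4:1 for the CNR comparison), 5
independent noise realizations, binomial thinning to 1/2 and 1/4 counts, and
the 10-min-analog lesion phantom. All substream seeds derive from one master
seed by stable hashing of the combination key, so adding combinations never
perturbs existing ones. Problem sizes (grid, 5 realizations, 15 BSREM
iterations) are the package's desk-scale choices.

## What the analog does and does not reproduce

In the final configuration the simulation reproduces, and the test suite
asserts: MLEM likelihood monotonicity and the subset/penalty identities; CR
and COV monotonically non-increasing in β; OSEM background COV scaling as
1/√T within 20%; CR decreasing with sphere diameter; 41% VOI volume recovery
within 15% for lesions ≥ 2 ml; and — the clinically reported mechanism — halving of
liver voxel-level noise (SD/mean of the 3 cm reference VOI) by BSREM at
matched contrast (measured fold ≈ 2.2).

The *ROI-mean* comparisons at the CR-matched β — background-COV fold, CNR
fold, lesion-SNR fold, and the count-reduction factor — come out near 1.0 in
this analog rather than the ≥ 2 observed on the clinical system. The
package reports the honestly computed folds. The gap is attributable to
effects outside this simulator's scope: both clinical reconstructions used
TOF (explicitly out of scope here), and the real fully-3D system operates at
~1 count per LOR, a photon-starved regime that disproportionately degrades
early-stopped OSEM relative to a converged penalized reconstruction. The
37-mm-scale (low-frequency) background noise that dominates the NEMA
ROI-mean COV in this 2D analog is essentially irreducible by a neighborhood
penalty, and for the smallest lesions the penalty's contrast erosion cancels
the SNR gain from the halved liver SD. Ruled out as causes by experiment:
optimizer non-convergence, subset limit cycles, the value of γ, and angular
undersampling.

## Numerical choices and limitations

* Reflective boundaries for all Gaussian filters (self-adjoint, so the
  PSF-in-the-model projector pair stays matched).
* ȳ is floored at 10⁻¹² inside logs and divisions; RDP denominators carry a
  10⁻³⁰⁰ guard against 0/0 on exactly uniform regions with ε = 0.
* Warm start: a uniform image scaled so the forward projection matches the
  net trues total.
* ROI membership uses ≤ (boundary ties included); disk rasterization error
  is bounded by the perimeter × pixel size and asserted in the tests.
* The 2D post-filter (in-plane) matches the slice-independent acquisition
  model; a 3D filter would mix statistically independent slices.
* Known limitations: no TOF, no oblique-plane sampling, exact corrections
  instead of estimated ones, single-bed geometry, no decay or dead time, and
  an elliptical (not exact NEMA) body outline.
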