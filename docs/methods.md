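# Methods

## Coordinate and axis conventions

Array index 0 is axial (superior–inferior), index 1 coronal
(anterior–posterior), index 2 sagittal (right–left).  A short-axis slice
is a fixed-index-2 plane.  Normalized sampler coordinates run over
[−1, 1] spanning the centers of the first and last voxels, so the
geometric volume center is an exact fixed point of every rotation.
Angles are degrees at every public surface.  Display planes are drawn
with the sagittal axis pointing right (axial plane: coronal axis up;
coronal plane: axial axis up); positive in-plane angles are
counterclockwise.

`rotate_volume` resamples on the grid `g(v) = M·n(v)`; the sampled
content therefore appears rotated by `M⁻¹`, and composing a rotation
with its transpose is an exact involution up to interpolation.  For
anisotropic voxels the matrix is conjugated by the per-axis physical
half-extents (`S⁻¹MS`) so the rotation is rigid in millimeters.

## Rotation composition

The reorientation rotation is `Ry(α)·Rx(β)·Rz(γ)` — the product of the
three elementary factors as printed, whose third factor has z-rotation
structure even though a y–x–y label would suggest otherwise.  Both
readings are implemented (`euler_convention` ∈ {`as_printed_yxz`,
`yxy`}); `as_printed_yxz` is the default because the explicit matrices
are taken as authoritative over the label.  Derivatives of the
composition (per degree) feed the training chain rule.

## Reorientation network

The localization network is a fully connected regressor over
mean-pooled volume features (48³ input pooled to 12³, hidden widths
128/64) with a scaled-tanh head bounding predictions to ±180°, matching
the augmentation range.  The output layer is zero-initialized so the
transformer starts at the identity rotation with the tanh head
unsaturated.  A dense-feature regressor was chosen over a deep 3D
convolutional encoder because at phantom scale the pooled intensity
profile determines the pose; the architecture is configurable.

Gradients are analytic end to end: loss → voxels → sampling grid
(∂out/∂grid from the trilinear weights) → rotation matrix → Euler
angles.  Training is per-sample Adam with gradient accumulation over
mini-batches of 4; all stochasticity (initialization, data order,
augmentation) flows from one seed, making runs bit-reproducible on one
device.

Loss weights are μ₁ = 0.6 (single-modal) and μ₂ = 0.4 (cross-modal).
The cross-modal slice mapping anchors CMR slice 1 at the basal-most
sagittal slice whose LV cross-section keeps ≥ 50 % of the maximal area
(basal = lower sagittal index), then steps apex-ward by
`round(slice spacing / sagittal voxel size)`.  The phantom generates its
CMR slices at positions chosen by the same rule, so the mapping is
consistent by construction; with real data the mapping tolerates a
slice of anchor error.  Phantom CMR frames share the CT in-plane grid,
so no resampling precedes the cross-modal MSE; with foreign grids the
CMR slice would be bilinearly resampled to the CT grid first.

Fine-tuning replaces the global template with per-sample pseudo-labels
from the refinement and uses the single-modal loss only.

Desk-scale optimizer settings: the phantom training helpers use a step
size of 3·10⁻³ (reorientation) and 10⁻³ (SDN) rather than the 10⁻⁴
default kept in the configs, compensating for the small number of
gradient steps (a few thousand) in these runs.

## Anatomical-prior refinement

The LV long axis is estimated from the LV mask: the center is the
in-slice centroid on the short-axis slice through the mask centroid, the
apex the rightmost mask voxel (ties broken toward the center ray, and
the apical cap averaged for sub-voxel placement).  The deviation
*angles* are measured from the mask's principal second-moment
eigenvector oriented toward the apex — for an ellipsoidal LV this
coincides with the center–apex chord but is sub-voxel accurate.  The
moments are intensity-weighted: a resampled mask keeps its fractional
(partial-volume) values, because hard-thresholding a twice-resampled
mask introduces correlated aliasing that biases moment estimates by a
degree or more.  Masks with principal-axis elongation below 1.05 (e.g.,
a sphere) or an apex within 2 voxels of the center are rejected as
degenerate.

Alignment applies axial-plane then coronal-plane corrections by minus
the measured deviation, re-estimating between corrections, and sweeps
until both residuals fall below 0.1° (at most 3 sweeps).  Two numerical
points matter: each incremental correction is right-multiplied onto the
accumulated grid matrix so it acts on the *current* content orientation
(left-composition would conjugate the increment through the earlier
correction and overshoot), and the volume/mask are always resampled
once from the originals so interpolation error never compounds.  The
returned mask is fractional; threshold at 0.5 where a crisp mask is
needed.  The axial-then-coronal order is configurable; the procedure is
idempotent within the tolerance floor.

## CMR preprocessing and classical registration

Frame selection keeps the last k = 10 of 90 time points; the final frame
is the motion-correction reference.  Rigid correction searches a
coarse-to-fine rotation grid (±5° in 2.5° then 0.5° steps) with
FFT-cross-correlation shifts and parabolic sub-pixel refinement.  The LV
is localized by a circular Hough transform on a Sobel edge map
(strongest accumulator peak) and slices are cropped to a fixed 105×75
field of view with zero padding.

The classical nonrigid step is a multiresolution cubic B-spline
free-form deformation (control spacing ≈ 8 px, six pyramid levels)
optimized with L-BFGS-B on analytic gradients.  Binary masks are
softened to signed distance maps (saturated at ±8 px and normalized so
the regularization weight is dimensionless) because binary MSE has zero
gradient almost everywhere.  The objective is
`MSE + 0.6 × bending energy`; the 0.6 "grid regularization" is
interpreted as this bending-energy weight, the only dimensionless
reading available.  A centroid pre-alignment absorbs bulk shifts
(mirroring the LV-center alignment that precedes cropping).  The
returned field never worsens mask overlap: if the optimum would, the
zero field is returned.  At the default weight, ≥ 99 % of pixels keep a
non-negative Jacobian determinant.

## Deformation network (SDN)

A two-level U-Net (base width 8, zero-initialized final convolution =
identity deformation at start) maps the concatenated fixed-CTCA /
moving-CMR slice pair to a dense displacement field; the loss is the MSE
to the pseudo-label CMR plus a first-difference smoothness penalty
(weight 0.01).  The smoothness term is an explicit addition — a pure MSE
objective admits folded fields.  Training triplets pair slices at the
cropped-LV scale (cavity radius ≈ 15 px, CT wall ≈ 5 px, CMR wall
thicker by a 1.15–1.35 factor) with in-plane shifts up to ±3 px
emulating residual inter-modality misalignment, plus an RV crescent,
coronary dot, and perfusion-deficit sector so the training distribution
matches pipeline slices.  Perfusion maps are warped with nearest-neighbor
interpolation at inference: they are quantitative labels, and bilinear
smearing at the wall edge would read as spurious deficits.

## Metrics

AR is the minor/major principal-extent ratio of the (hole-filled) LV
cross-section, extent = 4·√eigenvalue of the second-moment matrix plus
the 1/12 per-pixel variance; this equals the analytic ratio for a
filled ellipse and is robust to boundary noise.  DSC is 2|A∩B|/(|A|+|B|)
with the both-empty case defined as 1.  Hausdorff distance is the
symmetric maximum boundary-to-boundary distance in millimeters; the
per-volume figure is the maximum over slices (mean also recorded).
Long-axis deviations are reported as magnitudes.  AR, DSC and HD are
per-slice then aggregated; the deviation angles are volume-level.

## Synthetic phantom

The phantom emulates the acquisition geometry the pipeline assumes: a
truncated prolate-ellipsoid LV (cavity semi-axes 32/15 mm, wall 5 mm on
a 96³, 1 mm grid; scaled proportionally for smaller grids), apex toward
increasing sagittal index, basal truncation at −0.55 of the long
semi-axis; an RV crescent abutting the wall; one coronary tube on the
epicardial surface; and a 3-slice × 90-frame short-axis CMR stack
(8 mm slice spacing) whose cavity follows a logistic enhancement curve
with a small upward drift (strictly non-decreasing to the final frame)
and whose wall enhancement is delayed and scaled by the perfusion map.
The CMR-phase wall is thicker by a factor 1.25.  A deficit sector
(default 90° wide, hypoperfusion fraction 0.5) reduces the wall plateau.
Intensities are min–max-normalized synthetic look-alikes, not Hounsfield
units — the cross-modal MSE presumes comparable [0, 1] ranges — with
truncated additive Gaussian noise (σ = 0.01).  Contrast levels are free
parameters chosen to rank background < wall < RV < coronary < cavity as
in an arterial-phase scan.

Geometry is evaluated analytically at the requested orientation
(implicit surfaces on rotated coordinates), so masks are crisp at any
tilt, generation is bit-deterministic for a config + seed, and a phantom
generated at tilt θ equals the canonical phantom resampled by θ up to
interpolation.

What the phantom does **not** emulate: cardiac motion and contraction,
papillary muscles and valves, atria, realistic tissue texture and
scanner artifacts, perfusion kinetics beyond a two-level plateau, and
through-plane CMR motion.  Passing tests therefore demonstrate the
pipeline's geometric and optimization machinery, not clinical-grade
accuracy on patient data.

## Study sizes and limitations

The seeded studies run at desk scale: 200 phantoms at 48³ (±30°
rotations, 20 epochs) for reorientation with 20 held-out phantoms;
60 pseudo-label pairs and 5 epochs for fine-tuning; 100 slice triplets
at 64×64 (30 epochs) for the SDN with 15 held-out; end-to-end inference
on a fresh 96³ phantom.  These sizes are the package's reference
configuration — large enough for the recovery properties to hold with
margin, small enough to rerun routinely.

Known limitations: recovery beyond ±90° tilt is not guaranteed (the
apex-side disambiguation assumes the rough orientation is right, as the
rightmost-point rule requires); the reorientation network's raw angle
predictions are coarse at this training scale and the deterministic
refinement provides most of the final precision, mirroring the
pretrain → refine → fine-tune design; the deficit threshold for the
fused labelmap (0.6 × median wall perfusion) is a documented stand-in
for an unspecified clinical rule; and RV-wall registration is out of
scope.
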