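# Methods

`tibmech` re-creates, on synthetic data with known ground truth, the full
analysis chain used to characterize the compressive behavior of distal tibia
sections: micro-CT image analysis, homogenized finite-element (hFE)
simulation, force-displacement curve metrics, registration-based strain
mapping (digital volume correlation, DVC), and the statistical comparison of
predictions against measurements. This note documents the models, the
parameters that matter, the numerical choices, and what the synthetic data
do and do not emulate.

## Synthetic data

**Sections.** A section is a tubular cortical shell (solid bone of stated
thickness) around a trabecular compartment. The trabecular texture is a
thresholded anisotropic Gaussian random field: white noise smoothed with an
anisotropic Gaussian whose in-plane correlation length is 0.35 mm and whose
vertical correlation length is `anisotropy_ratio` (default 1.6) times
larger, giving vertically elongated trabeculae. The threshold is the
empirical quantile of the field inside the compartment, so the realized
BV/TV matches the target essentially exactly (a quantile is the fixed point
the usual threshold bisection converges to; we evaluate it directly).
Gray values are `tissue_density` (default 700 mgHA/cm^3) on bone plus
Gaussian noise (default 25 mgHA/cm^3). An optional weak band applies a
locally raised threshold, reducing BV/TV by a stated multiplier inside a
horizontal band. Full-size defaults follow the study geometry: ~30 mm
diameter, 30.6 mm height, 72.5 um voxels (the working resolution of
micro-CT downscaled by a factor 3; a 3x block-mean downscaler is provided
for pipeline parity). Tests and the study driver generate smaller sections;
the generator is scale-free.

What the generator does **not** emulate: scanner physics (beam hardening,
ring artifacts, partial-volume blur), realistic marrow gray levels, plate/rod
architecture transitions, and cortical porosity. Passing tests therefore
demonstrate the correctness of the pipeline's computations, not its
performance on scanner data.

**Load curves.** Records consist of elastic preconditioning cycles (default
5), a monotonic ramp, post-ultimate linear softening to a plateau, and an
unload at the elastic slope. The ramp is piecewise linear in displacement:
exactly linear at the input stiffness up to 85 % of the yield force, then
through the 0.2 %-offset yield point and the ultimate point, with samples
inserted at the kinks. By construction the noise-free curve round-trips
through the structural extractors exactly (the maximal moving-regression
slope is the input stiffness because the linear stretch exceeds the 1/3
window; the offset intersection is the input yield force; the absolute
maximum is the input ultimate force). Gaussian force noise (default
0.05 kN) emulates load-cell noise; the 2.5 Hz Butterworth filter recovers
the inputs to well within 2 %.

**Deformation ground truth.** `GroundTruthDeformation` couples an analytic
displacement with its exact inverse and gradient. Provided families:
identity, rigid rotation about the vertical axis, uniform dilation, and a
compaction band (uniform vertical ramp across a band of width w and total
shortening delta, so F = diag(1, 1, 1 - delta/w) inside the band; requires
delta < w). `apply_deformation` resamples the pre volume through the exact
inverse map (linear interpolation; identity is grid-exact).

## Image analysis

Gray-to-density calibration is an ordinary least-squares affine fit to
phantom rod measurements. Segmentation applies Gauss smoothing (sigma 0.8
voxels, truncation radius 1 voxel) and thresholds at 450 mgHA/cm^3 inside
the cortical compartment and 320 mgHA/cm^3 inside the trabecular
compartment, producing the 3-label image. The periosteal contour - drawn by
an operator in the clinical workflow - is automated here: Otsu foreground,
morphological closing (ball radius 3), per-slice hole filling. The cortical
compartment is the sub-periosteal peel (default 1.5 mm) surviving the 450
threshold after closing; the trabecular compartment is the remaining
interior. These mask rules are this package's documented substitute for
scanner-software internals.

Morphometry: BV/TV is the direct voxel-count ratio. Tb.Th and Tb.Sp use the
distance-ridge variant of the maximal-sphere method: twice the mean
Euclidean distance transform over its local maxima inside the phase
(zero-padded so cut surfaces count as boundary). This is exact for ideal
parallel plates and standard for trabecular structures. Tb.N uses the
plate-model relation 1/(Tb.Th + Tb.Sp). DA is the eigenvalue ratio of the
MIL fabric tensor over the whole trabecular mask. vBMD is the mean
calibrated density over the periosteal mask; BMC is the mean density over
bone-labeled voxels times the bone volume in cm^3.

## Fabric tensor (mean intercept length)

For quasi-uniform directions on a Fibonacci hemisphere (default 30-49),
parallel line probes (spacing 2 voxels, step 0.7 voxels) are cast through
the domain; MIL(d) is the probed bone length divided by the number of
bone-entry interface crossings between consecutive in-domain samples (so
domain entry does not count as an interface; solid or empty content yields
no interfaces and falls back to the isotropic tensor, flagged). An ellipsoid
d^T A d = 1/MIL^2 is fitted by least squares; eigenvalues of A are floored
at 1 % of the largest (ideal plates give a rank-deficient quadric; the floor
caps DA at 10), and the fabric tensor M = A^(-1/2) is normalized to mean
eigenvalue 1. Rotation equivariance holds exactly under 90-degree rotations
and to a few percent for interpolated rotations of smooth structures.

## Homogenized finite elements

**Mesh.** Cubic 8-node hexahedra; the layer count is ceil(height/1.27 mm)
and the edge is height/n_layers (30.6 mm gives 25 layers of 1.224 mm,
inside the 1.20-1.25 mm range of the protocol). Elements exist where the
periosteal-mask occupancy exceeds a configurable fraction (default: any
mask).

**Material.** Per element, BV/TV (rho) and MIL fabric are evaluated in a
sphere at the centroid - radius 2x edge in the trabecular phase, 1x edge in
the cortical phase (the phase-dependent radii are configurable; the
protocol only states that the radius changes by phase). The Zysset-Curnier
orthotropic law gives, in the fabric eigenframe, E_i = E0 rho^k m_i^(2l),
nu_ij = nu0 (m_i/m_j)^l, G_ij = mu0 rho^k (m_i m_j)^l, assembled as the
standard orthotropic compliance and rotated to the global frame. Constants
default to the literature calibration family (E0 = 9759 MPa, nu0 = 0.2278,
mu0 = 3117 MPa, k = 1.91, l = 1.1) and are configuration values. Stiffness
is scaled by 0.942 and strength by 0.78. rho is floored at 0.01 to avoid
singular elements (flagged).

**Yield and plasticity.** The yield surface is an ellipsoid in Mandel
stress space, diagonal in the fabric eigenframe, with radii sigma_y,i =
0.78 sigma0 rho^p m_i^(2q) and shear radii tau_y,ij = 0.78 tau0 rho^p
(m_i m_j)^q (defaults sigma0 = 57 MPa, tau0 = 29 MPa, p = 1.82, q = 1.1).
Perfect plasticity with associated flow: the return mapping sigma =
(I + dgamma D Q)^(-1) sigma_trial reduces, through the eigen-decomposition
of D^(1/2) Q D^(1/2), to a scalar monotone equation solved by Newton; the
algorithmic tangent is P - (P n)(P n)^T/(n^T P n) with P =
(I + dgamma D Q)^(-1) D and n = Q sigma, plus a 1e-6 elastic
regularization that keeps the global tangent factorizable when whole cross
sections reach the plateau.

**Boundary conditions and solve.** Bottom nodes fully constrained; top
nodes kinematically coupled (rigid-body, small-rotation) to a virtual
reference node on the central vertical axis whose vertical translation is
prescribed (default 0.3 mm, ~1 % apparent strain of a 30.6 mm section) with
the other five generalized DOFs free. A frictionless verification mode
constrains only vertical motion top and bottom (plus minimal rigid-body
anchors) and couples only the vertical top DOFs, so a homogeneous block has
the closed-form stiffness E A/L and a perfectly plastic plateau sigma_y A.
Small strain, displacement control in equal increments (default 20), full
Newton with an elastic predictor for the first increment, proportional
scaling of the start iterate afterwards, a residual-norm line search, and
adaptive increment bisection (down to 1/16 of an increment) when Newton
stalls. Convergence: reduced-residual norm below 1e-6 of the reaction
scale, at most 25 iterations per attempt. Under monotonic loading with
perfect plasticity the reaction force is non-decreasing - there is no
strain softening in the constitutive model, which is exactly why the
simulated curves plateau instead of dropping after the maximum.

## Structural analysis

Records are resampled to uniform time steps and filtered with a zero-phase
(forward-backward) order-2 Butterworth low-pass at 2.5 Hz; channels can be
synchronized on their first preconditioning peak. The monotonic ramp runs
from the last near-zero-force upcrossing to the first sample attaining the
absolute force maximum. Stiffness is the maximum slope of a moving OLS
regression whose window is one third of the ramp's sample count ("1/3 of
the data range" is interpreted in samples; earliest window wins ties).
Displacements are referenced to the zero-force origin back-extrapolated at
the elastic slope, which makes the noise-free round trip exact. Yield uses
the 0.2 % apparent-strain offset criterion (0.0612 mm for a 30.6 mm
section); no intersection before the ultimate point is reported as
undefined and flagged. Energy to the ultimate point is the trapezoidal area
(kN mm = J). Apparent properties divide by the mean cross-sectional area
(modulus = stiffness x height / area) and height (strain); the energy
density integrates the apparent stress-strain curve to the apparent
strength.

## Strain mapping (DVC)

Initial alignment translates the centers of gravity, segments both volumes
with 3-class Otsu (background/marrow/bone; voxels above the second
threshold are bone; degenerate histograms fall back to single Otsu,
flagged), and searches rotations about the vertical axis (default
-180..180 degrees in 1-degree steps, scored by Dice of the masks via
nearest-voxel lookup; ties prefer the smallest rotation). Registration is
rigid (Euler 6 DOF) then B-spline with final control-point spacing equal to
the hFE element edge so both methods share one field grid. Metric and
optimizer are recorded in the result: correlation metric on a seeded random
20 % voxel subset; regular-step gradient descent for the rigid stage
(2-level pyramid); gradient descent with per-iteration learning-rate
estimation for the B-spline stage. Dice QC uses a common threshold - the
mean of the two second Otsu thresholds - after each stage.

The displacement sampled at cell centers gives F = I + grad(u) by central
differences (one-sided at boundaries); J = det F; the isovolumic part
F_tilde = J^(-1/3) F has det F_tilde = 1 by construction (verified to
1e-9) and Frobenius norm >= sqrt(3) with equality exactly for rigid motion.
Cells with J <= 0 are flagged invalid and excluded from summaries.
Mid-plane maps extract one axial slice of J and ||F_tilde|| on the common
element grid, in the original configuration.

## Comparison and the synthetic study

Regressions are ordinary least squares with R^2, the standard error of the
estimate sqrt(SS_res/(n-2)), and two-sided 95 % t-based confidence
intervals (n-2 dof). Outliers are residuals beyond 1.5 IQR from the first
or third quartile. The strain-pattern agreement - a visual call in the
laboratory workflow - is operationalized here as the Spearman rank
correlation between the hFE and DVC mid-slice ||F_tilde|| maps over the
common valid cells, classified good (>= 0.6), partial (>= 0.3), or bad.
Rank correlation is used because the two fields live at different load
levels (FE at ~1 % strain, registration after failure), so only the
localization pattern is comparable; the thresholds are package choices
recorded in every report.

The study driver sweeps 10 sections across BV/TV 0.05-0.40 at a reduced
size (12 mm cube, 0.15 mm voxels, 0.4 mm shell - preserving the
shell-to-diameter ratio of the full-size section) so the element grids stay
in the ~10^3-element class; one shared texture realization is used across
the sweep, making the thresholded bone masks nested and isolating the BV/TV
effect (a controlled experiment, not a population draw). Per sample it runs
segmentation, densitometry, meshing, material mapping, the elastoplastic
solve to 1 % apparent strain, and an "experimental" record - either the hFE
curve itself (self-consistency mode: regression of hFE on experiment must
give slope 1, R^2 = 1) or a generated noisy test record whose inputs are
the hFE results perturbed by 5 % relative noise. Per-sample multipliers on
the experimental stiffness/yield (``exp_weak_factors``) emulate local
structural defects that neither densitometry nor the homogenized model can
see - geometric defects alone do not reproduce this, both because BMC falls
along with stiffness and because homogenization smears sub-element damage.
Study outputs: the sample table, BMC-vs-mechanics and hFE-vs-experiment
regressions with outlier flags, and (optionally) DVC-vs-hFE agreement
classes.

## Problem sizes and tolerances

Default test problems use 48^3-80^3-voxel sections and meshes of 500-2000
elements. The rotation-recovery check runs at 128^3 voxels (72.5 um); the
compaction-band recovery runs at 96^3 voxels and 0.15 mm spacing - a
14.4 mm tall domain, so enough element-grid rows lie away from both the
band edges (>= 1.5 mm, the B-spline kernel's smoothing range) and the
volume-boundary layer (one-sided differences), which the recovery metric
excludes. Newton
tolerance 1e-6 (relative), return-mapping tolerance 1e-12, fabric fit by
least squares over >= 21 directions. The acceptance script
(`scripts/acceptance.py`) states the size used for every quantity in its
JSON output (`n` field).

## Known limitations

- Geometrically linear, small-strain FE; no buckling, no strain softening,
  voxel-stepped cortex (no smooth shell meshing).
- The MIL estimator uses nearest-voxel sampling; fabric eigenvalues of
  near-degenerate structures are floored (DA capped at 10).
- The periosteal/cortical mask rules replace operator contouring and are
  not byte-compatible with any scanner software.
- DVC accuracy is limited by the coarse B-spline grid tied to the element
  edge; displacement errors concentrate near band edges and volume
  boundaries, which the recovery metric excludes by a stated margin.
- The agreement classifier is a quantitative surrogate for a visual
  assessment; its thresholds (0.6/0.3) are package conventions.
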