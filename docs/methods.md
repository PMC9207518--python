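# Methods

`lumitomo` reconstructs a three-dimensional bioluminescent source from
multispectral surface light measurements while simultaneously estimating the
tissue's optical properties, so that no second imaging modality and no
assumed optical parameters are required. This note describes the model, the
algorithms, the defaults and their rationale, and the limits of what the
synthetic validation demonstrates.

## Light propagation model

Light transport is modeled with the continuous-wave diffusion approximation

    -div( kappa grad Phi ) + mu_a Phi = q,      kappa = 1 / (3 (mu_a + mu_s')),

discretized with linear (P1) tetrahedral finite elements. The tissue/air
interface carries a Robin (type III) condition, `Phi + 2 A kappa dPhi/dn = 0`,
with the internal-reflection parameter `A` computed from the standard
Fresnel-derived polynomial at a default refractive index of 1.33 (soft tissue
against air); `A = 1` for a matched boundary. Measured intensity is the nodal
boundary fluence — no free-space or Lambertian camera model is applied,
because the spectral-derivative data described below cancels per-detector
effects.

Two numerical choices matter and are non-default relative to textbook P1:

* **Mass blending.** The absorption mass matrix is 75% row-lumped and 25%
  consistent. Full lumping keeps the system an M-matrix (nonnegative fluence,
  essential for logarithmic data) but biases the discrete attenuation
  coefficient low; the consistent matrix errs in the opposite direction. The
  25% blend was chosen by a forward-consistency study between a fine and a
  2x-coarser mesh (it minimized the residual spectral tilt without losing
  positivity at tissue-like `mu_a h^2`). The Robin boundary mass is lumped.
* **Body-fitted meshes.** Cylindrical phantom meshes are built by mapping a
  structured Freudenthal (6-tets-per-cube) lattice onto the disk with the
  elliptical square-to-disk map, so every lateral surface node lies exactly
  on the cylinder. Staircase (voxel) surfaces were found to sample the
  boundary fluence with an O(h) position error which, at `mu_eff ~ 1/mm`,
  acts as tens-of-percent per-detector gain noise. Box and sphere meshes use
  the plain lattice with a cell-centroid inclusion test.

Linear systems are solved by sparse LU factorization (reused across the many
right-hand sides of one wavelength) or, for single right-hand sides on large
meshes, by Jacobi-preconditioned conjugate gradients.

## Tissue optics

Absorption is a linear mix of oxy- and deoxy-hemoglobin,
`mu_a = cTHb (StO2 eps_HbO2 + (1-StO2) eps_Hb) + background`, using a shipped
extinction table (natural-log convention, mm^-1 mM^-1, 580-680 nm) compiled
from standard published hemoglobin data; the table and a constant background
term (default 0) are configurable. Oxygen saturation is fixed (default 70%)
and is not estimated. Reduced scattering follows the Mie-type power law
`mu_s' = a (lambda/1000 nm)^(-b)`, so the amplitude `a` is `mu_s'` at the
1000 nm reference in mm^-1.

## Source reconstruction

The data for each adjacent wavelength pair are spectral derivatives — the
differences of log-intensity, `d = ln I(lambda_i) - ln I(lambda_{i+1})` per
detector — which cancel any per-detector gain shared across wavelengths. The
reconstruction objective adds a second, equally gain-invariant block: the
mean-removed per-wavelength log-intensity *pattern* across detectors, i.e.
the shape of each wavelength's surface spot. Log-ratios constrain the
spectral attenuation along the path (hence depth times `Delta mu_eff`), while
the spot width constrains depth geometrically; together they remove a
depth/size ambiguity that ratios alone leave almost flat (about +-0.5 mm in
depth, which maps to -+20% in recovered total intensity). The pattern block
is weighted by beta = 2, the inverse-variance ratio for independent
per-(detector, wavelength) log errors (a difference of two logs carries twice
the variance of one mean-removed log).

Minimizing this misfit over arbitrary nonnegative nodal sources is massively
non-unique — an entire polytope of distributed sources reproduces the
per-detector ratios exactly — but over *compact* sources it is well posed: a
point source's three coordinates are overdetermined by the data. The solver
is therefore greedy, in the compressive-sensing sense of atom detection plus
refinement:

1. **Matched-filter scan.** The log-difference misfit of a unit point source
   is evaluated at every interior node in closed form from the columns of
   the forward operators; nodes are ranked.
2. **Blob fit.** Over the best-ranked nodes, an axially anisotropic Gaussian
   atom (center, transverse width `sigma_xy`, axial width `sigma_z`) is
   grid-searched and then refined by multi-start Nelder-Mead on the full
   objective. Anisotropy matters: against an elongated source, the best
   isotropic blob trades width against depth and lands systematically deep.
3. **Rasterization.** The fitted blob is scattered to nodal masses by
   barycentric interpolation of volume samples. Barycentric scattering
   reproduces linear moments, so the nodal field retains the fitted
   sub-grid center of mass.
4. **Optional nodal polish.** A Gauss-Newton/conjugate-gradient iteration on
   the blob support with projection onto `x >= 0` and a trust-region pull
   toward the blob. It is off by default: after the five-parameter fit the
   residual misfit sits at the forward-model discretization floor (verified
   against the exactly embedded true source), so further nodal freedom only
   absorbs model error and was observed to bias the recovered total by a few
   percent. Enable it (`n_outer > 0`) when the source is expected to deviate
   from a single compact blob.

Both data blocks are blind to the overall source magnitude, so a single
global amplitude is calibrated last, as the geometric-mean ratio of measured
to modeled intensities over all detectors (equal weight per detector in log
space; a plain least-squares fit would be dominated by the near-field
detectors where coarse-grid error is largest). Absolute amplitude therefore
comes from absolute counts: scaling all measured intensities by a common
gain scales the recovered source by the same factor, while the *shape*
(support, FWHM, center of mass) is exactly gain-invariant.

The reconstruction is summarized by the paper-style metrics: the FWHM
support (all nodes at or above half the maximum), its intensity-weighted
center of mass, the FWHM distance (largest pairwise distance within the
support), and the total and maximum intensity.

## Property estimation

With the source fixed as the uniform "diffuse source" on the FWHM support,
the sensitivity of each log boundary intensity to the nodal absorption and
diffusion coefficients is computed by the adjoint method (direct field times
adjoint field, element by element; the adjoint fields are the same
`K^{-1} e_d` columns used as the forward operator rows, so they are free).
Nodal `mu_a`/`kappa` sensitivities are chained to the spectrally constrained
parameters — total hemoglobin `cTHb` (through the extinction coefficients
and the induced `kappa` change), and optionally the scattering amplitude and
power — and rows are differenced across adjacent wavelength pairs so the
update sees the same gain-cancelled data as the source reconstruction.

The update solves the underdetermined regularized normal equations
`dp = J^T (J J^T + 0.1 diag(J J^T))^{-1} r` (regularization 0.1, held fixed).
For the homogeneous update the Jacobian is first summed over the model's
nodes (or over a labelled region), which is the exact derivative with
respect to a global parameter change; averaging a nodal minimum-norm update
instead was found to under-step by an order of magnitude.

By default only `cTHb` is estimated. Scattering amplitude and power are
frozen (flags enable them): over the 610-650 nm band the Mie power law is
nearly flat, so two difference blocks constrain it weakly, and the
literature this method builds on reports hemoglobin as the recovered
quantity. Parameter bounds (cTHb in [0.001, 1] mM, a in [0.05, 5], b in
[0, 3]) guard against divergence from bad early source estimates.

## The joint loop

Each iteration reconstructs the source under the current properties, forms
the FWHM diffuse source (dilated by one node ring if it has fewer than three
nodes), computes the adjoint Jacobian and the Moore-Penrose step, and
accepts the largest damped step (up to four halvings) whose *re-reconstructed*
projection error improves on the current one. The projection error chi is
the relative l2 misfit of the full stacked data vector (log differences plus
pattern block) for the freshly reconstructed source — the quantity the
whole pipeline actually fits. Judging property steps by the diffuse-source
misfit instead was found to converge to a biased hemoglobin value (the
uniform-blob approximation prefers more absorption), while the
reconstruction misfit is minimized at the true value on synthetic data.

Because the source re-localizes as the properties change, the landscape has
shallow local basins (a too-transparent model pushes the source deep, where
a locally self-consistent but wrong solution exists). When the loop
stagnates, or its improvement falls below the convergence tolerance, it
probes bracketing property values (cTHb times and divided by 1.5, 1.2 and
1.05) with full re-reconstruction and jumps to a probe that improves chi by
more than a quarter of the tolerance. The recorded chi trace is
non-increasing by construction: an iteration that cannot improve chi ends
the loop. Stopping follows the relative-change rule (below 2% by default)
with a cap of 50 iterations.

## Preprocessing

In acquisition order: per-projection surface maps are merged with the
per-node, per-wavelength maximum on overlaps; detectors below 10% of the
global maximum are discarded; when an open-field time series and per-image
timestamps are available, each spectral image is rescaled to the open-field
level at the first acquisition (linear interpolation, no extrapolation);
finally each wavelength column is divided by its emission-spectrum weight.
All steps are scale-covariant, and the downstream spectral derivatives are
unchanged by any per-detector gain shared across wavelengths.

## Synthetic phantom and what the tests show

The generator emulates the study conditions: a cylinder of radius 12.5 mm
and length 40 mm (mouse scale); a 0.9 mm diameter, 2 mm long cylindrical
luminescent source of known total strength, by default centered 4 mm below
the lateral surface; homogeneous tissue with true cTHb 0.145 mM at 70%
saturation, scattering amplitude 0.9 and power 1.3; wavelengths 610/630/650
nm with emission weights 1/0.893/0.633 (an implanted-source spectrum
re-anchored to 610 nm); and 1% multiplicative Gaussian noise with a fixed
seed. Data are always simulated on a fine mesh (0.75 mm edges, ~50k nodes)
and reconstructed on a coarse mesh (1.5 mm edges, ~6.3k nodes), avoiding the
inverse crime; the fine surface map is interpolated at the coarse detector
positions with a first-order moving-least-squares fit of log-fluence
(nearest-node sampling leaves a resolution-dependent amplitude bias, and
zeroth-order averaging flattens the spot peak and biases inferred depth).
Negative far-field values are clipped to zero and such detectors are dropped
with a warning when logs are formed.

On this phantom the package localizes the source to a few tenths of a
millimetre from either hemoglobin initialization, recovers consistent final
misfits and cTHb from both, orders the mis-estimation biases as expected
(under-estimated absorption reconstructs deeper and stronger), and recovers
the total source intensity within a few percent when the true properties are
fixed.

What this does **not** show: real animal surfaces are irregular and the
mapping from camera pixels to surface nodes carries Lambertian and
free-space factors. The log-difference block is immune to those per-detector
effects, but the spatial-pattern block is not — on real data its weight may
need to be reduced, at the cost of a broader depth uncertainty. Tissue
heterogeneity (organ-wise optical maps), additional chromophores (water,
lipids), and multi-source configurations are likewise outside the model; the
estimated cTHb is a whole-volume effective value.

## Problem sizes and runtime

Default problem sizes were chosen so that a complete joint run (50-iteration
cap, typically converging in well under ten) takes tens of seconds on one
CPU: ~6.3k-node reconstruction mesh with a few hundred surviving detectors,
~50k-node simulation mesh, and a 166k-node sphere for the analytic
forward-solver benchmark (Jacobi-CG, ~15 s). The forward-solver benchmark
geometry itself came from a convergence study: a 20 mm sphere keeps the
boundary effect inside the comparison shell below half a percent, and 0.6 mm
edges bring the near-source quadrature error under 3%.

## Degenerate inputs and tie-breaks

Zero spectral-derivative data returns a zero source with a warning. A
measurement whose detectors include nonpositive intensities has those
detectors excluded before logs are taken. If the whole fitted blob falls
outside the mesh it collapses to the nearest node. Element orientation is
normalized on mesh construction (positive signed volumes); degenerate
elements are rejected with the offending index. The convergence rule treats
a zero previous chi as converged.
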