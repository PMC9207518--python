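# lumitomo

Quantitative bioluminescence tomography (BLT) with joint recovery of tissue
optical properties.

Bioluminescence imaging tags cells (for example an orthotopic tumor) with a
luciferase reporter and photographs the light escaping through the animal's
skin. Turning those two-dimensional surface images into the
three-dimensional position, size and strength of the internal source
requires a model of light propagation through tissue — and that model
depends on optical properties (hemoglobin absorption, scattering) that are
usually unknown and merely assumed, compromising quantitative accuracy.
`lumitomo` implements an optimization loop that recovers the source and the
tissue's total hemoglobin concentration *simultaneously, from the same
multispectral surface data*, so no second imaging modality and no assumed
optical parameters are needed.

## Model and algorithm

Light transport follows the continuous-wave diffusion approximation on a
tetrahedral mesh (linear FEM, Robin boundary condition):

    -div( kappa grad Phi ) + mu_a Phi = q,      kappa = 1/(3 (mu_a + mu_s')),

with spectrally constrained coefficients

    mu_a(lambda)  = cTHb [ StO2 eps_HbO2(lambda) + (1-StO2) eps_Hb(lambda) ],
    mu_s'(lambda) = a (lambda / 1000 nm)^(-b).

The measured data are **spectral derivatives** — differences of
log-intensity between adjacent wavelengths, `d = ln I(λ_i) − ln I(λ_{i+1})`
per surface detector — which cancel per-detector gains (lens, viewing angle,
free-space propagation), plus the equally gain-invariant mean-removed
per-wavelength intensity pattern. The joint loop alternates:

1. reconstruct the nonnegative nodal source `x` under the current
   properties (greedy compressive-sensing scheme: point-source matched
   filter → anisotropic Gaussian blob fit → barycentric rasterization,
   with a final amplitude calibration against the measured counts);
2. threshold at half maximum (the FWHM "diffuse source"), take its
   intensity-weighted center of mass;
3. compute the adjoint-method Jacobian of the data with respect to cTHb
   (optionally scattering amplitude/power) for the diffuse source;
4. update the properties with a regularized Moore–Penrose step
   `dp = J^T (J J^T + 0.1 diag(J J^T))^{-1} r`, damped so the projection
   error χ never increases;
5. stop when the relative change of χ falls below 2% (at most 50
   iterations).

Reported metrics follow the field's conventions: center-of-mass
localization error, FWHM distance, total and maximum reconstructed
intensity, and the recovered cTHb. See `docs/methods.md` for the full
account, numerical choices and limitations.

## Worked example

Simulate a small synthetic phantom (8 mm radius cylinder, a 0.9 × 2 mm
luminescent source of total strength 100 at 4 mm depth, true cTHb 0.145 mM,
1% noise) and reconstruct it starting from a wrong hemoglobin estimate:

```
$ python -m lumitomo --seed 7 simulate --spec demo_spec.yaml --out demo/sim
INFO phantom written to demo/sim (fine 8424 / coarse 1134 nodes, 546 detectors)

$ python -m lumitomo reconstruct --mesh demo/sim/mesh.vtk \
      --data demo/sim/measurement.tsv --config demo_run.yaml --out demo/recon
INFO iter  1  chi=0.30374  cTHb=0.0791 mM  a=0.900  b=1.300  com=(4.69, 0.00, 0.13)
INFO iter  2  chi=0.20011  cTHb=0.1598 mM  a=0.900  b=1.300  com=(4.06, 0.05, 0.09)
INFO iter  3  chi=0.18086  cTHb=0.1555 mM  a=0.900  b=1.300  com=(3.98, 0.01, 0.05)
INFO iter  4  chi=0.16414  cTHb=0.1616 mM  a=0.900  b=1.300  com=(4.01, 0.00, 0.09)
INFO finished in 5 iterations (converged=True), results in demo/recon

$ python -m lumitomo metrics --result demo/recon --truth demo/sim/truth.json
{
  "localization_error_mm": 0.09511510085478093,
  "fwhm_distance_mm": 1.5384615384,
  "total_intensity": 108.06958368731779,
  "max_intensity": 37.28045299602714,
  "cthb_mM": 0.1616446092050563,
  "total_intensity_error_percent": 8.069583687317635,
  "cthb_error_percent": 11.479040831073318
}
```

Started from cTHb = 0.05 mM (a factor of three below the truth), the loop
converges in five iterations: the source lands 0.1 mm from the embedded
cylinder's centroid, its total strength is recovered within 8%, and the
hemoglobin estimate moves from 0.05 to 0.16 mM against a truth of 0.145 mM —
all from surface light alone. The χ trace decreases monotonically
(0.304 → 0.200 → 0.181 → 0.164 → 0.164) and the exit code is 0 on
convergence (2 when the iteration cap is hit).

`demo_spec.yaml` holds the phantom description (geometry, source, noise) and
`demo_run.yaml` the run configuration (wavelengths `[610, 630, 650]`,
emission weights `[1, 0.893, 0.633]`, `init_cthb: 0.05`).

The same workflow is available as a library:

```python
import lumitomo as lt

spec = lt.PhantomSpec()                      # default mouse-scale phantom
fine, coarse = lt.generate_phantom_mesh(spec)
m = lt.simulate_measurements(fine, coarse, spec)
m = lt.normalize_to_spectrum(lt.threshold_surface_data(m, 0.10))
result = lt.run_joint_reconstruction(coarse, m, lt.TissueComposition(cthb=0.05))
print(result.report(coarse, truth_com=lt.ground_truth(fine, spec)["com_mm"]))
```

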