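"""Spectral-derivative data formation and source reconstruction."""

import numpy as np
import pytest

import lumitomo as lt
from lumitomo.fem_forward import assemble_system
from lumitomo.mesh_model import boundary_nodes
from lumitomo.phantom import cylinder_mesh
from lumitomo.preprocess import (
    SpectralMeasurement,
    normalize_to_spectrum,
    threshold_surface_data,
)
from lumitomo.source_recon import (
    SourceDistribution,
    SpectralDerivativeData,
    SpectralForwardModel,
    center_of_mass,
    fwhm_support,
    make_diffuse_source,
    reconstruct_source,
    spectral_derivative,
)
from lumitomo.tissue_optics import ExtinctionTable, TissueComposition, optical_coefficients

WL = np.array([610.0, 630.0, 650.0])


# -- spectral_derivative ------------------------------------------------------


def test_log_difference_values():
    m = SpectralMeasurement([0], [600.0, 620.0], [[np.e, np.e**2]])
    d = spectral_derivative(m)
    assert d.values.ravel() == pytest.approx([-1.0])


def test_identical_wavelength_data_gives_zero():
    m = SpectralMeasurement([0, 1], WL, np.full((2, 3), 4.2))
    assert not spectral_derivative(m).values.any()


def test_shared_detector_gain_cancels():
    rng = np.random.default_rng(0)
    vals = rng.uniform(1.0, 5.0, (6, 3))
    gains = rng.uniform(0.1, 10.0, 6)
    d1 = spectral_derivative(SpectralMeasurement(np.arange(6), WL, vals))
    d2 = spectral_derivative(
        SpectralMeasurement(np.arange(6), WL, gains[:, None] * vals)
    )
    assert np.allclose(d1.values, d2.values, rtol=1e-12)


def test_nonpositive_detectors_dropped():
    m = SpectralMeasurement([0, 1], WL, [[1.0, 1.0, 1.0], [1.0, 0.0, 1.0]])
    d = spectral_derivative(m)
    assert list(d.detector_nodes) == [0]


def test_single_wavelength_rejected():
    m = SpectralMeasurement([0], [630.0], [[1.0]])
    with pytest.raises(ValueError, match="two wavelengths"):
        spectral_derivative(m)


# -- reconstruction fixtures --------------------------------------------------


@pytest.fixture(scope="module")
def crime_setup():
    """Noise-free single-node source simulated on the reconstruction mesh
    (deliberate inverse crime: isolates solver correctness)."""
    mesh = cylinder_mesh(8.0, 20.0, 1.5)
    table = ExtinctionTable.default()
    comp = TissueComposition(0.145, 0.70, 0.9, 1.3)
    weights = np.array([1.0, 0.893, 0.633])
    coeffs = optical_coefficients(comp, table, WL)
    target = np.array([4.5, 0.0, 0.0])
    source_node = int(
        np.argmin(
            np.linalg.norm(mesh.nodes - target, axis=1) + 1e9 * mesh.boundary
        )
    )
    q = np.zeros(mesh.n_nodes)
    q[source_node] = 100.0
    bn = boundary_nodes(mesh)
    intens = np.empty((len(bn), 3))
    for k in range(3):
        system = assemble_system(mesh, coeffs.mua[k], coeffs.kappa[k])
        intens[:, k] = weights[k] * system.solve(q)[bn]
    m = SpectralMeasurement(bn, WL.copy(), np.maximum(intens, 0.0), weights)
    m = normalize_to_spectrum(threshold_surface_data(m, 0.10))
    data = spectral_derivative(m)
    model = SpectralForwardModel(mesh, coeffs, data.detector_nodes)
    return dict(
        mesh=mesh, coeffs=coeffs, measurement=m, data=data, model=model,
        source_node=source_node, total=100.0,
    )


def test_inverse_crime_recovery(crime_setup):
    """Noise-free same-mesh data: the recovered support contains the true
    node and the COM lands within one element edge of it."""
    s = crime_setup
    x = reconstruct_source(
        s["mesh"], s["coeffs"], s["data"], s["measurement"].weights,
        model=s["model"], measurement=s["measurement"],
    )
    support = fwhm_support(x)
    assert s["source_node"] in support
    com = center_of_mass(s["mesh"], x, support)
    max_edge = 1.5 * np.sqrt(3.0)
    err = np.linalg.norm(com - s["mesh"].nodes[s["source_node"]])
    assert err < max_edge
    assert x.total == pytest.approx(s["total"], rel=0.10)


def test_reconstruction_shape_invariant_to_global_gain(crime_setup):
    """Scaling all measured intensities by a common gain leaves the
    normalized source shape unchanged and scales the amplitude."""
    s = crime_setup
    x1 = reconstruct_source(
        s["mesh"], s["coeffs"], s["data"], s["measurement"].weights,
        model=s["model"], measurement=s["measurement"],
    )
    scaled = s["measurement"].copy()
    scaled.intensities = 37.0 * scaled.intensities
    data2 = spectral_derivative(scaled)
    x2 = reconstruct_source(
        s["mesh"], s["coeffs"], data2, scaled.weights,
        model=s["model"], measurement=scaled,
    )
    assert np.allclose(data2.values, s["data"].values, rtol=1e-12)
    assert x2.total == pytest.approx(37.0 * x1.total, rel=1e-6)
    assert np.allclose(
        x2.values / x2.total, x1.values / x1.total, atol=1e-12
    )


def test_shape_only_reconstruction_is_gain_invariant(crime_setup):
    """Without absolute intensities the result is fully invariant to any
    global scaling of the measurement (unit-total shape)."""
    s = crime_setup
    x = reconstruct_source(
        s["mesh"], s["coeffs"], s["data"], s["measurement"].weights,
        model=s["model"],
    )
    assert x.total == pytest.approx(1.0)


def test_zero_data_returns_zero_source(crime_setup):
    s = crime_setup
    zero = SpectralDerivativeData(
        np.zeros_like(s["data"].values) * 0.0,
        s["data"].detector_nodes,
        s["data"].wavelengths,
    )
    zero.values[:] = 0.0
    x = reconstruct_source(s["mesh"], s["coeffs"], zero, model=s["model"])
    assert not x.values.any()
    assert x.converged


def test_polish_misfit_non_increasing(crime_setup):
    """Accepted Gauss-Newton/CG polish steps never increase the misfit."""
    s = crime_setup
    x = reconstruct_source(
        s["mesh"], s["coeffs"], s["data"], s["measurement"].weights,
        model=s["model"], measurement=s["measurement"], n_outer=10,
    )
    trace = np.asarray(x.misfit_trace)
    assert (np.diff(trace) <= 1e-12 * max(trace[0], 1.0)).all()
    assert x.converged


# -- FWHM support / COM / diffuse source -------------------------------------


def test_fwhm_support_rule():
    assert list(fwhm_support(np.array([1.0, 0.6, 0.4]))) == [0, 1]
    assert list(fwhm_support(np.array([2.0, 2.0, 2.0]))) == [0, 1, 2]
    assert list(fwhm_support(np.array([0.0, 3.0, 0.0]))) == [1]
    with pytest.raises(ValueError):
        fwhm_support(np.zeros(4))


def test_center_of_mass_rules(crime_setup):
    mesh = crime_setup["mesh"]
    x = np.zeros(mesh.n_nodes)
    x[7] = 2.5
    assert np.allclose(center_of_mass(mesh, x, [7]), mesh.nodes[7])
    x[11] = 2.5
    assert np.allclose(
        center_of_mass(mesh, x, [7, 11]),
        0.5 * (mesh.nodes[7] + mesh.nodes[11]),
    )
    with pytest.raises(ValueError):
        center_of_mass(mesh, x, [])
    with pytest.raises(ValueError):
        center_of_mass(mesh, np.zeros(mesh.n_nodes), [3, 4])


def test_center_of_mass_symmetric_blob():
    """A symmetric Gaussian blob on the symmetric box mesh has its COM at
    the blob center (brute-force weighted mean is the definition)."""
    from lumitomo.phantom import box_mesh

    mesh = box_mesh((6.0, 6.0, 6.0), 1.0)
    d2 = (mesh.nodes**2).sum(axis=1)
    x = np.exp(-0.5 * d2 / 1.2**2)
    com = center_of_mass(mesh, x, np.arange(mesh.n_nodes))
    assert np.linalg.norm(com) < 1e-12


def test_make_diffuse_source():
    d = make_diffuse_source(6, [2], 5.0)
    assert d.values[2] == 5.0 and d.total == 5.0
    d = make_diffuse_source(6, [0, 1, 2, 3], 1.0)
    assert np.allclose(d.values[:4], 0.25)
    assert d.total == pytest.approx(1.0)
    with pytest.raises(ValueError):
        make_diffuse_source(6, [], 1.0)
    with pytest.raises(ValueError):
        make_diffuse_source(6, [1], 0.0)


def test_source_distribution_validation():
    with pytest.raises(ValueError):
        SourceDistribution(np.array([1.0, -0.1]))
    with pytest.raises(ValueError):
        SourceDistribution(np.array([np.nan, 0.0]))
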