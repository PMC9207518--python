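"""Adjoint property Jacobian, Moore-Penrose update, projection error."""

import numpy as np
import pytest

from lumitomo.fem_forward import assemble_system
from lumitomo.mesh_model import boundary_nodes
from lumitomo.phantom import box_mesh
from lumitomo.property_update import (
    adjoint_jacobian,
    converged,
    moore_penrose_update,
    projection_error,
)
from lumitomo.source_recon import SpectralDerivativeData, SpectralForwardModel
from lumitomo.tissue_optics import (
    ExtinctionTable,
    TissueComposition,
    optical_coefficients,
)

WL = np.array([610.0, 630.0, 650.0])


@pytest.fixture(scope="module")
def setup():
    """<=500-node mesh with a small interior diffuse source."""
    mesh = box_mesh((5.0, 5.0, 5.0), 1.0)  # 216 nodes
    table = ExtinctionTable.default()
    comp = TissueComposition(0.12, 0.70, 0.9, 1.3)
    coeffs = optical_coefficients(comp, table, WL)
    detectors = boundary_nodes(mesh)[::12]
    model = SpectralForwardModel(mesh, coeffs, detectors)
    center = int(
        np.argmin(np.linalg.norm(mesh.nodes, axis=1) + 1e9 * mesh.boundary)
    )
    source = np.zeros(mesh.n_nodes)
    source[center] = 3.0
    ring = np.unique(mesh.elements[(mesh.elements == center).any(axis=1)])
    source[ring] += 0.5
    return dict(mesh=mesh, table=table, comp=comp, coeffs=coeffs, model=model,
                source=source)


def _fd_lnI(mesh, coeffs, detectors, source, mua_nodal, kappa_nodal, k):
    """ln detector intensity for explicit nodal coefficient fields."""
    system = assemble_system(mesh, mua_nodal, kappa_nodal)
    phi = system.solve(source)
    return np.log(phi[detectors])


@pytest.mark.parametrize("block", ["cthb", "scatter_amplitude", "scatter_power"])
def test_adjoint_jacobian_matches_central_finite_differences(setup, block):
    """Adjoint sensitivities against central differences of the forward
    model w.r.t. the homogeneous spectrally constrained parameter: relative
    discrepancy <= 1e-3 on entries above 1e-6 of the maximum."""
    s = setup
    jac = adjoint_jacobian(
        s["model"], s["comp"], s["table"], s["source"], blocks=(block,)
    )
    # column-summed sensitivity = derivative w.r.t. the global parameter
    adjoint_cols = jac.block(block).sum(axis=1)

    eps = {"cthb": 1e-5, "scatter_amplitude": 1e-5, "scatter_power": 1e-5}[block]
    import dataclasses

    rows = []
    for sign in (+1, -1):
        kwargs = {
            "cthb": dict(cthb=s["comp"].cthb + sign * eps),
            "scatter_amplitude": dict(
                scatter_amplitude=s["comp"].scatter_amplitude + sign * eps
            ),
            "scatter_power": dict(
                scatter_power=s["comp"].scatter_power + sign * eps
            ),
        }[block]
        comp_p = dataclasses.replace(s["comp"], **kwargs)
        coeffs_p = optical_coefficients(comp_p, s["table"], WL)
        lnI = np.stack(
            [
                _fd_lnI(
                    s["mesh"], coeffs_p, s["model"].detector_nodes, s["source"],
                    coeffs_p.mua[k], coeffs_p.kappa[k], k,
                )
                for k in range(3)
            ]
        )
        rows.append((lnI[:-1] - lnI[1:]).ravel())
    fd = (rows[0] - rows[1]) / (2 * eps)

    scale = np.abs(fd).max()
    mask = np.abs(fd) > 1e-6 * scale
    rel = np.abs(adjoint_cols[mask] - fd[mask]) / np.abs(fd[mask])
    assert rel.max() <= 1e-3


def test_adjoint_jacobian_nodal_fd_spot_check(setup):
    """Nodal cTHb sensitivities of a single non-differenced ln-intensity row
    against central differences on a few sampled nodes."""
    s = setup
    mesh, comp, table = s["mesh"], s["comp"], s["table"]
    from lumitomo.property_update import lnI_coefficient_sensitivities
    from lumitomo.tissue_optics import d_absorption_d_cthb

    k = 1  # 630 nm
    coeffs = s["coeffs"]
    system = s["model"].systems[k]
    phi = system.solve(s["source"])
    detectors = s["model"].detector_nodes
    intensity = phi[detectors]
    d_mua, d_kappa = lnI_coefficient_sensitivities(
        mesh, phi, s["model"].adjoint_fields[k], intensity
    )
    rng = np.random.default_rng(1)
    nodes = rng.choice(mesh.n_nodes, size=6, replace=False)
    eps = 1e-6
    for node in nodes:
        mua = np.full(mesh.n_nodes, coeffs.mua[k])
        for arr, d_block in ((mua, d_mua),):
            up, dn = arr.copy(), arr.copy()
            up[node] += eps
            dn[node] -= eps
            lo = np.log(assemble_system(mesh, dn, coeffs.kappa[k]).solve(
                s["source"])[detectors])
            hi = np.log(assemble_system(mesh, up, coeffs.kappa[k]).solve(
                s["source"])[detectors])
            fd = (hi - lo) / (2 * eps)
            big = np.abs(fd) > 1e-6 * np.abs(fd).max()
            rel = np.abs(d_block[:, node][big] - fd[big]) / np.abs(fd[big])
            assert rel.max() <= 1e-3


def test_cthb_sensitivities_nonpositive(setup):
    """More absorber never brightens the boundary: every cTHb-block entry of
    a non-differenced ln-intensity row is <= 0 (tiny numerical slack)."""
    s = setup
    from lumitomo.property_update import lnI_coefficient_sensitivities
    from lumitomo.tissue_optics import d_absorption_d_cthb

    for k in range(3):
        phi = s["model"].systems[k].solve(s["source"])
        intensity = phi[s["model"].detector_nodes]
        d_mua, d_kappa = lnI_coefficient_sensitivities(
            s["mesh"], phi, s["model"].adjoint_fields[k], intensity
        )
        kappa = s["coeffs"].kappa[k]
        col = (d_mua + d_kappa * (-3.0 * kappa**2)) * d_absorption_d_cthb(
            s["comp"], s["table"], float(WL[k])
        )
        assert col.max() <= 1e-12 * np.abs(col).max()


def test_jacobian_invariant_to_source_scale(setup):
    s = setup
    j1 = adjoint_jacobian(s["model"], s["comp"], s["table"], s["source"])
    j2 = adjoint_jacobian(s["model"], s["comp"], s["table"], 2.0 * s["source"])
    assert np.allclose(j1.matrix, j2.matrix, rtol=1e-10)
    # modeled log differences also unchanged (log cancels scale)
    assert np.allclose(j1.modeled.values, j2.modeled.values, rtol=1e-10)


def test_jacobian_zero_source_rejected(setup):
    with pytest.raises(ValueError, match="zero source"):
        adjoint_jacobian(
            setup["model"], setup["comp"], setup["table"],
            np.zeros(setup["mesh"].n_nodes),
        )


# -- Moore-Penrose update -----------------------------------------------------


def test_update_identity_system():
    upd = moore_penrose_update(np.eye(2), np.array([3.0, 5.0]), 0.0,
                               blocks=("cthb",), n_nodes=2)
    assert np.allclose(upd.nodal["cthb"], [3.0, 5.0])
    assert upd.d_cthb == pytest.approx(4.0)


def test_update_minimum_norm_solution():
    upd = moore_penrose_update(np.array([[1.0, 1.0]]), np.array([2.0]), 0.0,
                               blocks=("cthb",), n_nodes=2)
    assert np.allclose(upd.nodal["cthb"], [1.0, 1.0])


def test_update_regularized_underdetermined():
    """J = [1, 1], r = [2], lambda = 0.1: J J^T = 2, diag = 2, so
    y = 2 / (2 + 0.2) and dp = [2/2.2, 2/2.2] (dense linear-algebra oracle)."""
    J = np.array([[1.0, 1.0]])
    r = np.array([2.0])
    expected = J.T @ np.linalg.solve(J @ J.T + 0.1 * np.diag(np.diag(J @ J.T)), r)
    upd = moore_penrose_update(J, r, 0.1, blocks=("cthb",), n_nodes=2)
    assert np.allclose(upd.nodal["cthb"], expected)
    assert np.allclose(upd.nodal["cthb"], 2.0 / 2.2)


def test_update_shrinks_with_regularization():
    rng = np.random.default_rng(5)
    J = rng.normal(size=(4, 12))
    r = rng.normal(size=4)
    norms = [
        np.linalg.norm(
            moore_penrose_update(J, r, lam, blocks=("cthb",), n_nodes=12).nodal["cthb"]
        )
        for lam in (0.0, 0.1, 1.0, 10.0, 1e4)
    ]
    assert all(a >= b for a, b in zip(norms, norms[1:]))
    assert norms[-1] < 1e-3 * norms[0]


def test_update_errors():
    with pytest.raises(ValueError):
        moore_penrose_update(np.eye(2), np.array([1.0]), 0.1)
    with pytest.raises(ValueError):
        moore_penrose_update(np.eye(2), np.array([np.nan, 1.0]), 0.1)


# -- projection error / convergence rule --------------------------------------


def _sd(values):
    values = np.asarray(values, dtype=float)
    return SpectralDerivativeData(
        values, np.arange(values.shape[1]), WL[: values.shape[0] + 1]
    )


def test_projection_error_rules():
    meas = _sd([[1.0, 2.0], [3.0, 4.0]])
    assert projection_error(meas, _sd(meas.values.copy())) == 0.0
    zero = _sd(np.zeros((2, 2)))
    assert projection_error(meas, zero) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        projection_error(zero, meas)  # zero measured norm
    with pytest.raises(ValueError):
        projection_error(meas, _sd([[1.0], [2.0]]))


def test_projection_error_invariant_to_reordering():
    rng = np.random.default_rng(2)
    a, b = rng.normal(size=(2, 5)), rng.normal(size=(2, 5))
    perm = rng.permutation(5)
    chi1 = projection_error(_sd(a), _sd(b))
    pa = SpectralDerivativeData(a[:, perm], perm, WL)
    pb = SpectralDerivativeData(b[:, perm], perm, WL)
    assert projection_error(pa, pb) == pytest.approx(chi1)


@pytest.mark.parametrize(
    "history,expected",
    [
        ([0.5, 0.5], True),
        ([0.5, 0.4], False),
        ([0.100, 0.0985], True),  # 1.5% change < 2%
        ([0.0, 0.1], True),  # previous chi zero => converged
    ],
)
def test_convergence_rule(history, expected):
    assert converged(history, tol=0.02) is expected


def test_convergence_needs_two_entries():
    with pytest.raises(ValueError):
        converged([0.5])
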