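"""Spectrally constrained optical-property update via the adjoint method.

Given a fixed diffuse source, the sensitivity of the log boundary intensity
to the nodal absorption and diffusion coefficients is

    d ln I_d / d p_n = -(psi_d^T (dK/dp_n) Phi) / I_d,

with Phi the direct field, psi_d = K^{-1} e_d the adjoint field of detector
d, and dK/dp_n the exactly linear dependence of the FEM matrix on nodal
coefficients (element coefficients are nodal means).  The nodal mu_a and
kappa sensitivities are chained to the spectrally constrained parameters

    cTHb : d mu_a/d cTHb = StO2 eps_HbO2 + (1-StO2) eps_Hb, plus the induced
           kappa change d kappa/d mu_a = -3 kappa^2
    a, b : through mu_s' = a (lambda/1000 nm)^(-b) and kappa only

and rows are differenced across adjacent wavelength pairs to match the
spectral-derivative data (the unknown global source magnitude and the
per-detector gains cancel there, which is what makes a CW property update
well posed at all).  The update solves the underdetermined regularized
normal equations in data space,

    dp = J^T (J J^T + lambda_reg diag(J J^T))^{-1} r,

and each parameter block is then averaged over the model (or a region) to a
scalar step, mirroring a homogeneous-property assumption.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import scipy.linalg

from .mesh_model import Mesh
from .fem_forward import element_geometry
from .source_recon import SpectralDerivativeData, SpectralForwardModel
from .tissue_optics import (
    LAMBDA_REF_NM,
    ExtinctionTable,
    TissueComposition,
    d_absorption_d_cthb,
)

__all__ = [
    "JacobianMatrix",
    "PropertyUpdate",
    "lnI_coefficient_sensitivities",
    "adjoint_jacobian",
    "moore_penrose_update",
    "projection_error",
    "converged",
]


@dataclasses.dataclass
class JacobianMatrix:
    """Sensitivities of spectral-derivative data to spectrally constrained
    parameters, as contiguous nodal blocks (cTHb, then a, then b if enabled)."""

    matrix: np.ndarray  # (n_pairs * d, n_blocks * n)
    blocks: tuple[str, ...]
    n_nodes: int
    modeled: SpectralDerivativeData  # model prediction at the linearization point

    def block(self, name: str) -> np.ndarray:
        i = self.blocks.index(name)
        return self.matrix[:, i * self.n_nodes : (i + 1) * self.n_nodes]


@dataclasses.dataclass
class PropertyUpdate:
    """Scalar parameter steps after spatial averaging (and the nodal fields)."""

    d_cthb: float = 0.0
    d_scatter_amplitude: float = 0.0
    d_scatter_power: float = 0.0
    nodal: dict | None = None


def lnI_coefficient_sensitivities(
    mesh: Mesh, phi: np.ndarray, psi: np.ndarray, intensity: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Adjoint sensitivities of ln(detector intensity) to nodal mu_a and kappa.

    Parameters
    ----------
    phi : (n,) direct field for the source of interest.
    psi : (n, d) adjoint fields (columns = K^{-1} e_d per detector).
    intensity : (d,) detector intensities phi[detectors].

    Returns ``(d_mua, d_kappa)`` of shape (d, n) each.
    """
    if np.any(intensity <= 0):
        raise ValueError("detector intensity must be positive")
    vol, grads = element_geometry(mesh)
    conn = mesh.elements
    n, m = mesh.n_nodes, mesh.n_elements
    d = psi.shape[1]
    phi_e = phi[conn]  # (m, 4)
    gphi = np.einsum("mki,mk->mi", grads, phi_e)  # (m, 3)
    flat = conn.ravel()
    d_mua = np.empty((d, n))
    d_kappa = np.empty((d, n))
    from .fem_forward import MASS_CONSISTENT_FRACTION as _alpha

    sum_phi = phi_e.sum(axis=1)
    for j in range(d):
        psi_e = psi[:, j][conn]
        # psi^T M_e phi with unit coefficient and the blended mass pattern
        mass = vol * (
            (1.0 - _alpha) / 4.0 * (psi_e * phi_e).sum(axis=1)
            + _alpha / 20.0
            * (psi_e.sum(axis=1) * sum_phi + (psi_e * phi_e).sum(axis=1))
        )
        gpsi = np.einsum("mki,mk->mi", grads, psi_e)
        stiff = vol * (gpsi * gphi).sum(axis=1)
        # element coefficient = mean of 4 nodal values => 1/4 to each node
        d_mua[j] = np.bincount(flat, np.repeat(mass / 4.0, 4), minlength=n)
        d_kappa[j] = np.bincount(flat, np.repeat(stiff / 4.0, 4), minlength=n)
    d_mua *= -1.0 / intensity[:, None]
    d_kappa *= -1.0 / intensity[:, None]
    return d_mua, d_kappa


def adjoint_jacobian(
    model: SpectralForwardModel,
    comp: TissueComposition,
    table: ExtinctionTable,
    source: np.ndarray,
    weights=None,
    blocks: tuple[str, ...] = ("cthb",),
) -> JacobianMatrix:
    """Spectral-derivative Jacobian for a fixed (diffuse) source.

    ``blocks`` selects the estimated parameters among "cthb",
    "scatter_amplitude", "scatter_power"; frozen blocks are omitted.
    Also returns the modeled spectral-derivative data at the linearization
    point, computed from the same direct fields.
    """
    source = np.asarray(source, dtype=float)
    if not source.any():
        raise ValueError("zero source: nothing excites the boundary data")
    if weights is None:
        weights = np.ones_like(model.wavelengths)
    weights = np.asarray(weights, dtype=float)
    mesh = model.mesh
    n = mesh.n_nodes
    n_wl = len(model.wavelengths)
    d = model.n_detectors

    per_wl = []  # per-wavelength (d, n_blocks*n) chained sensitivity rows
    log_intensity = np.empty((n_wl, d))
    for k, wl in enumerate(model.wavelengths):
        phi = model.systems[k].solve(source)
        intensity = phi[model.detector_nodes]
        if np.any(intensity <= 0):
            # P1 far fields can dip below zero at marginal detectors; floor
            # them (the chi-based step acceptance guards the update)
            floor = 1e-12 * max(intensity.max(), 1e-300)
            intensity = np.maximum(intensity, floor)
        log_intensity[k] = np.log(weights[k] * intensity)
        d_mua, d_kappa = lnI_coefficient_sensitivities(
            mesh, phi, model.adjoint_fields[k], intensity
        )
        kappa = model.coeffs.kappa[k]
        musp = model.coeffs.musp[k]
        dk_dmu = -3.0 * kappa**2  # d kappa / d (mu_a or mu_s')
        cols = []
        for name in blocks:
            if name == "cthb":
                c = d_absorption_d_cthb(comp, table, float(wl))
                cols.append((d_mua + d_kappa * dk_dmu) * c)
            elif name == "scatter_amplitude":
                dmusp_da = (wl / LAMBDA_REF_NM) ** (-comp.scatter_power)
                cols.append(d_kappa * dk_dmu * dmusp_da)
            elif name == "scatter_power":
                dmusp_db = -np.log(wl / LAMBDA_REF_NM) * musp
                cols.append(d_kappa * dk_dmu * dmusp_db)
            else:
                raise ValueError(f"unknown parameter block {name!r}")
        per_wl.append(np.hstack(cols))

    rows = np.vstack([per_wl[k] - per_wl[k + 1] for k in range(n_wl - 1)])
    modeled = SpectralDerivativeData(
        log_intensity[:-1] - log_intensity[1:],
        model.detector_nodes,
        model.wavelengths.copy(),
    )
    return JacobianMatrix(rows, tuple(blocks), n, modeled)


def moore_penrose_update(
    J: JacobianMatrix | np.ndarray,
    residual: np.ndarray,
    lambda_reg: float = 0.1,
    blocks: tuple[str, ...] | None = None,
    n_nodes: int | None = None,
    region_mask: np.ndarray | None = None,
) -> PropertyUpdate:
    """Regularized minimum-norm update, averaged per parameter block.

    Solves dp = J^T (J J^T + lambda_reg diag(J J^T))^{-1} residual and averages
    each nodal block over the model (or over ``region_mask``) to a scalar.
    """
    if isinstance(J, JacobianMatrix):
        matrix, blocks, n_nodes = J.matrix, J.blocks, J.n_nodes
    else:
        matrix = np.asarray(J, dtype=float)
        if blocks is None or n_nodes is None:
            blocks = ("cthb",)
            n_nodes = matrix.shape[1]
    residual = np.asarray(residual, dtype=float)
    if residual.shape != (matrix.shape[0],):
        raise ValueError("residual length must equal the Jacobian row count")
    if not np.all(np.isfinite(residual)) or not np.all(np.isfinite(matrix)):
        raise ValueError("non-finite residual or Jacobian")
    gram = matrix @ matrix.T
    reg = gram + lambda_reg * np.diag(np.diag(gram))
    try:
        y = scipy.linalg.solve(reg, residual, assume_a="pos")
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"singular regularized system: {exc}") from exc
    nodal = matrix.T @ y

    if region_mask is not None:
        region_mask = np.asarray(region_mask, dtype=bool)
        if region_mask.shape != (n_nodes,) or not region_mask.any():
            raise ValueError("region mask must select at least one node")
    update = PropertyUpdate(nodal={})
    key_map = {
        "cthb": "d_cthb",
        "scatter_amplitude": "d_scatter_amplitude",
        "scatter_power": "d_scatter_power",
    }
    for i, name in enumerate(blocks):
        block = nodal[i * n_nodes : (i + 1) * n_nodes]
        update.nodal[name] = block
        avg = block[region_mask].mean() if region_mask is not None else block.mean()
        setattr(update, key_map[name], float(avg))
    return update


def projection_error(
    measured: SpectralDerivativeData, modeled: SpectralDerivativeData
) -> float:
    """Relative l2 misfit chi = ||d_meas - d_model|| / ||d_meas||."""
    if measured.values.shape != modeled.values.shape or not np.array_equal(
        measured.detector_nodes, modeled.detector_nodes
    ):
        raise ValueError("measured and modeled data structures differ")
    denom = np.linalg.norm(measured.vector)
    if denom == 0:
        raise ValueError("zero measured data norm")
    return float(np.linalg.norm(measured.vector - modeled.vector) / denom)


def converged(chi_history, tol: float = 0.02) -> bool:
    """True when the relative change of the projection error drops below tol."""
    chi = np.asarray(chi_history, dtype=float)
    if chi.size < 2:
        raise ValueError("need at least two projection-error values")
    prev, cur = chi[-2], chi[-1]
    if prev == 0:
        return True
    return bool(abs(cur - prev) / prev < tol)
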