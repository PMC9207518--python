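"""Joint source/optical-property reconstruction loop and evaluation metrics.

Each iteration: (1) reconstruct the nonnegative source with the current
properties; (2) take the FWHM support (all nodes at or above half the
maximum) and its intensity-weighted center of mass; (3) replace the source
by a uniform "diffuse source" on that support; (4) compute the adjoint
property Jacobian for the diffuse source and the regularized Moore-Penrose
step for the spatially constrained (homogeneous) parameters; (5) accept the
largest damped step whose re-reconstructed projection error chi improves on
the current one, probing bracketing property values when the local step
stalls (the depth/absorption ambiguity creates shallow local basins);
(6) record chi -- non-increasing by construction -- and stop when its
relative change falls below the tolerance (default 2%) or at the iteration
cap (default 50).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
from scipy.spatial.distance import pdist

from .mesh_model import Mesh
from .preprocess import SpectralMeasurement
from .property_update import (
    adjoint_jacobian,
    converged as chi_converged,
    moore_penrose_update,
)
from .source_recon import (
    SourceDistribution,
    SpectralForwardModel,
    center_of_mass,
    fwhm_support,
    make_diffuse_source,
    reconstruct_source,
    spectral_derivative,
)
from .tissue_optics import ExtinctionTable, TissueComposition, optical_coefficients

__all__ = [
    "ReconConfig",
    "IterationRecord",
    "JointReconResult",
    "run_joint_reconstruction",
    "localization_error",
    "fwhm_distance",
    "intensity_metrics",
]

logger = logging.getLogger("lumitomo")


@dataclasses.dataclass
class ReconConfig:
    """Tunable parameters of the joint loop (defaults follow the method)."""

    lambda_reg: float = 0.1  # Moore-Penrose regularization
    tolerance: float = 0.02  # relative chi change stopping rule
    max_iterations: int = 50
    update_cthb: bool = True
    update_scatter_amplitude: bool = False
    update_scatter_power: bool = False
    cthb_bounds: tuple[float, float] = (0.001, 1.0)  # mM
    amplitude_bounds: tuple[float, float] = (0.05, 5.0)
    power_bounds: tuple[float, float] = (0.0, 3.0)
    damping_halvings: int = 4
    recon_outer: int = 0
    recon_inner: int = 50
    refractive_index: float = 1.33
    region_label: int | None = None  # average the update within this region only

    def blocks(self) -> tuple[str, ...]:
        names = []
        if self.update_cthb:
            names.append("cthb")
        if self.update_scatter_amplitude:
            names.append("scatter_amplitude")
        if self.update_scatter_power:
            names.append("scatter_power")
        if not names:
            raise ValueError("at least one property block must be updated")
        return tuple(names)


@dataclasses.dataclass
class IterationRecord:
    iteration: int
    source: SourceDistribution
    composition: TissueComposition
    chi: float
    com: np.ndarray
    support_size: int
    step_scale: float


@dataclasses.dataclass
class JointReconResult:
    records: list[IterationRecord]
    final_source: SourceDistribution
    final_composition: TissueComposition
    converged: bool
    iterations: int

    @property
    def chi_trace(self) -> np.ndarray:
        return np.array([r.chi for r in self.records])

    @property
    def final_com(self) -> np.ndarray:
        return self.records[-1].com

    def report(self, mesh: Mesh, truth_com=None) -> dict:
        """JSON-ready summary of the run."""
        total, peak = intensity_metrics(self.final_source)
        out = {
            "cthb_mM": self.final_composition.cthb,
            "scatter_amplitude": self.final_composition.scatter_amplitude,
            "scatter_power": self.final_composition.scatter_power,
            "sto2": self.final_composition.sto2,
            "com_mm": [float(v) for v in self.final_com],
            "fwhm_distance_mm": fwhm_distance(mesh, self.final_source),
            "total_intensity": total,
            "max_intensity": peak,
            "chi_trace": [float(c) for c in self.chi_trace],
            "iterations": self.iterations,
            "converged": self.converged,
        }
        if truth_com is not None:
            out["localization_error_mm"] = localization_error(self, truth_com)
        return out


def _apply_update(comp, update, scale, config) -> TissueComposition:
    cthb, a, b = comp.cthb, comp.scatter_amplitude, comp.scatter_power
    if config.update_cthb:
        cthb = float(np.clip(cthb + scale * update.d_cthb, *config.cthb_bounds))
    if config.update_scatter_amplitude:
        a = float(
            np.clip(a + scale * update.d_scatter_amplitude, *config.amplitude_bounds)
        )
    if config.update_scatter_power:
        b = float(np.clip(b + scale * update.d_scatter_power, *config.power_bounds))
    return dataclasses.replace(comp, cthb=cthb, scatter_amplitude=a, scatter_power=b)


def _dilate_support(mesh: Mesh, support: np.ndarray) -> np.ndarray:
    """Add the one-ring element neighbourhood of the support nodes."""
    mask = np.zeros(mesh.n_nodes, dtype=bool)
    mask[support] = True
    touched = mask[mesh.elements].any(axis=1)
    mask[np.unique(mesh.elements[touched])] = True
    return np.flatnonzero(mask)


def run_joint_reconstruction(
    mesh: Mesh,
    measurement: SpectralMeasurement,
    init: TissueComposition,
    config: ReconConfig | None = None,
    table: ExtinctionTable | None = None,
) -> JointReconResult:
    """Run the full joint loop on a preprocessed measurement.

    ``measurement`` should already be merged, thresholded and
    spectrum-normalized; its detector nodes must be boundary nodes of
    ``mesh``.
    """
    config = config or ReconConfig()
    table = table or ExtinctionTable.default()
    if measurement.detector_nodes.size == 0:
        raise ValueError("empty detector set after preprocessing")
    data = spectral_derivative(measurement)
    weights = measurement.weights
    blocks = config.blocks()
    wavelengths = measurement.wavelengths

    comp = init
    model = SpectralForwardModel(
        mesh,
        optical_coefficients(comp, table, wavelengths),
        data.detector_nodes,
        config.refractive_index,
    )
    region_mask = None
    if config.region_label is not None:
        in_region = np.zeros(mesh.n_nodes, dtype=bool)
        in_region[
            np.unique(mesh.elements[mesh.region == config.region_label])
        ] = True
        region_mask = in_region

    records: list[IterationRecord] = []
    chi_prev: float | None = None
    converged_flag = False
    # reference norm of the stacked data (log differences + the gain-
    # invariant per-wavelength pattern block the reconstruction also fits);
    # chi is the relative misfit of that whole data vector
    from .source_recon import PATTERN_WEIGHT, _match_measurement

    f_ref = float(data.vector @ data.vector)
    measured = _match_measurement(measurement, data.detector_nodes)
    if (measured > 0).all():
        logs_m = np.log(measured)
        pattern = logs_m - logs_m.mean(axis=1, keepdims=True)
        f_ref += PATTERN_WEIGHT * float((pattern * pattern).sum())
    if f_ref <= 0:
        raise ValueError("zero data norm")

    def build_model(composition):
        return SpectralForwardModel(
            mesh,
            optical_coefficients(composition, table, wavelengths),
            data.detector_nodes,
            config.refractive_index,
        )

    def reconstruct(current_model):
        x = reconstruct_source(
            mesh,
            current_model.coeffs,
            data,
            weights,
            model=current_model,
            measurement=measurement,
            n_outer=config.recon_outer,
            n_inner=config.recon_inner,
        )
        # relative misfit of the stacked data vector the reconstruction fits
        chi = float(np.sqrt(x.misfit_trace[-1] / f_ref))
        return x, chi

    x, chi = reconstruct(model)
    if x.max <= 0:
        raise RuntimeError("initial reconstruction is zero")

    for it in range(1, config.max_iterations + 1):
        support = fwhm_support(x)
        if support.size < 3:
            support = _dilate_support(mesh, support)
        com = center_of_mass(mesh, x, support)
        diffuse = make_diffuse_source(mesh.n_nodes, support, x.total)

        jac = adjoint_jacobian(model, comp, table, diffuse.values, weights, blocks)
        residual = data.vector - jac.modeled.vector
        # homogeneous (spatially constrained) update: the derivative of the
        # data w.r.t. a global parameter change is the column sum of the nodal
        # Jacobian over the model (or region), giving a full-size quasi-Newton
        # step for the scalar parameters
        cols = []
        for name in blocks:
            block = jac.block(name)
            cols.append(
                block[:, region_mask].sum(axis=1)
                if region_mask is not None
                else block.sum(axis=1)
            )
        constrained = np.stack(cols, axis=1)
        update = moore_penrose_update(
            constrained, residual, config.lambda_reg, blocks=blocks, n_nodes=1
        )

        # damped acceptance on the *joint* misfit: take the largest step
        # scale whose re-reconstructed projection error improves on the
        # current one; the source and properties are thus always consistent
        accepted = None
        used_scale = 0.0
        scale = 1.0
        for _ in range(config.damping_halvings + 1):
            comp_try = _apply_update(comp, update, scale, config)
            if comp_try == comp:
                break
            model_try = build_model(comp_try)
            x_try, chi_try = reconstruct(model_try)
            if chi_try < chi and x_try.max > 0:
                accepted = (chi_try, comp_try, model_try, x_try)
                used_scale = scale
                break
            scale *= 0.5
        if accepted is None:
            # local step exhausted: probe bracketing property values to
            # escape a shallow basin of the depth/absorption ambiguity
            probe = _escape_probe(build_model, reconstruct, comp, config, chi)
            if probe is not None:
                accepted = probe
                used_scale = float("nan")

        stagnated = accepted is None
        if not stagnated:
            chi_new, comp, model, x = accepted
            support = fwhm_support(x)
            if support.size < 3:
                support = _dilate_support(mesh, support)
            com = center_of_mass(mesh, x, support)
        else:
            chi_new = chi

        small_change = not stagnated and chi_converged(
            [chi, chi_new], config.tolerance
        )
        if small_change:
            # below-tolerance progress still gets one escape attempt before
            # the loop declares convergence
            probe = _escape_probe(build_model, reconstruct, comp, config, chi_new)
            if probe is not None:
                chi_new, comp, model, x = probe
                used_scale = float("nan")
                support = fwhm_support(x)
                if support.size < 3:
                    support = _dilate_support(mesh, support)
                com = center_of_mass(mesh, x, support)
                small_change = False

        records.append(
            IterationRecord(it, x, comp, chi_new, com, int(support.size), used_scale)
        )
        logger.info(
            "iter %2d  chi=%.5f  cTHb=%.4f mM  a=%.3f  b=%.3f  com=(%.2f, %.2f, %.2f)",
            it,
            chi_new,
            comp.cthb,
            comp.scatter_amplitude,
            comp.scatter_power,
            *com,
        )
        if stagnated or small_change:
            converged_flag = True
            break
        chi = chi_new

    return JointReconResult(
        records=records,
        final_source=records[-1].source,
        final_composition=records[-1].composition,
        converged=converged_flag,
        iterations=len(records),
    )


def _escape_probe(build_model, reconstruct, comp, config, chi_reference):
    """Bracketing property probes with full re-reconstruction.

    Returns (chi, comp, model, source) for the best probe if it improves the
    reconstruction misfit by more than the convergence tolerance, else None.
    """
    candidates = []
    if config.update_cthb:
        for factor in (1.5, 1.0 / 1.5, 1.2, 1.0 / 1.2, 1.05, 1.0 / 1.05):
            candidates.append(
                dataclasses.replace(
                    comp,
                    cthb=float(np.clip(comp.cthb * factor, *config.cthb_bounds)),
                )
            )
    if config.update_scatter_amplitude:
        for factor in (1.5, 1.0 / 1.5):
            candidates.append(
                dataclasses.replace(
                    comp,
                    scatter_amplitude=float(
                        np.clip(
                            comp.scatter_amplitude * factor,
                            *config.amplitude_bounds,
                        )
                    ),
                )
            )
    if config.update_scatter_power:
        for step in (0.3, -0.3):
            candidates.append(
                dataclasses.replace(
                    comp,
                    scatter_power=float(
                        np.clip(comp.scatter_power + step, *config.power_bounds)
                    ),
                )
            )
    best = None
    threshold = chi_reference * (1.0 - 0.25 * config.tolerance)
    for cand in candidates:
        model_c = build_model(cand)
        x_c, chi_c = reconstruct(model_c)
        if chi_c < threshold and (best is None or chi_c < best[0]):
            best = (chi_c, cand, model_c, x_c)
    return best


# -- metrics -----------------------------------------------------------------


def localization_error(result: JointReconResult | np.ndarray, truth) -> float:
    """Euclidean distance (mm) between the final COM and the true centroid."""
    com = result.final_com if isinstance(result, JointReconResult) else result
    return float(np.linalg.norm(np.asarray(com, float) - np.asarray(truth, float)))


def fwhm_distance(mesh: Mesh, x) -> float:
    """Largest pairwise distance (mm) among nodes at or above half maximum."""
    support = fwhm_support(x)
    if support.size == 1:
        return 0.0
    return float(pdist(mesh.nodes[support]).max())


def intensity_metrics(x) -> tuple[float, float]:
    """(total, max) reconstructed intensity."""
    values = x.values if isinstance(x, SourceDistribution) else np.asarray(x, float)
    if values.size == 0:
        return 0.0, 0.0
    return float(values.sum()), float(values.max())
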