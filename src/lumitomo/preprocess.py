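"""Multispectral surface measurements and the preprocessing pipeline.

The pipeline mirrors the acquisition workflow: per-projection surface maps
are merged (max of overlap), detectors below 10% of the global maximum are
discarded, intensities are corrected for signal drift over the acquisition
session using an open-field time-resolved curve, and finally each wavelength
column is normalized by the source emission-spectrum weight.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "SpectralMeasurement",
    "threshold_surface_data",
    "merge_projections",
    "normalize_to_spectrum",
    "correct_time_drift",
    "read_measurement_tsv",
    "write_measurement_tsv",
]


@dataclasses.dataclass
class SpectralMeasurement:
    """Per-wavelength intensity at boundary (detector) nodes.

    detector_nodes : (d,) int
        Boundary node indices of the reconstruction mesh.
    wavelengths : (w,) float
        Wavelengths in nm.
    intensities : (d, w) float
        Nonnegative intensities in arbitrary counts.
    weights : (w,) float
        Emission-spectrum weight per wavelength (positive; 1 after
        normalization).
    timestamps : (w,) float, optional
        Acquisition time of each spectral image (s).
    openfield : (t, 2) float, optional
        Open-field (unfiltered) intensity time series: columns (time s,
        intensity), used for drift correction.
    """

    detector_nodes: np.ndarray
    wavelengths: np.ndarray
    intensities: np.ndarray
    weights: np.ndarray | None = None
    timestamps: np.ndarray | None = None
    openfield: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.detector_nodes = np.asarray(self.detector_nodes, dtype=np.int64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.weights is None:
            self.weights = np.ones_like(self.wavelengths)
        self.weights = np.asarray(self.weights, dtype=float)
        d, w = len(self.detector_nodes), len(self.wavelengths)
        if self.intensities.shape != (d, w):
            raise ValueError(
                f"intensity matrix must be ({d}, {w}), got {self.intensities.shape}"
            )
        if self.weights.shape != (w,):
            raise ValueError("one emission weight per wavelength required")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be nonnegative")
        if np.any(self.weights <= 0):
            raise ValueError("emission weights must be positive")
        if self.timestamps is not None:
            self.timestamps = np.asarray(self.timestamps, dtype=float)
            if self.timestamps.shape != (w,):
                raise ValueError("one timestamp per wavelength required")
        if self.openfield is not None:
            self.openfield = np.asarray(self.openfield, dtype=float)
            if self.openfield.ndim != 2 or self.openfield.shape[1] != 2:
                raise ValueError("openfield series must be (t, 2)")

    def copy(self) -> "SpectralMeasurement":
        return SpectralMeasurement(
            self.detector_nodes.copy(),
            self.wavelengths.copy(),
            self.intensities.copy(),
            self.weights.copy(),
            None if self.timestamps is None else self.timestamps.copy(),
            None if self.openfield is None else self.openfield.copy(),
        )


def threshold_surface_data(
    m: SpectralMeasurement, frac: float = 0.10
) -> SpectralMeasurement:
    """Keep detectors whose max across wavelengths exceeds ``frac`` of the
    global maximum over all surface points."""
    if m.intensities.size == 0:
        raise ValueError("empty measurement")
    per_det = m.intensities.max(axis=1)
    keep = per_det > frac * per_det.max()
    if not keep.any():
        raise ValueError("no detectors survive threshold")
    out = m.copy()
    out.detector_nodes = m.detector_nodes[keep]
    out.intensities = m.intensities[keep]
    return out


def merge_projections(
    a: SpectralMeasurement, b: SpectralMeasurement
) -> SpectralMeasurement:
    """Union of detectors; the per-node, per-wavelength maximum on overlap."""
    if not np.array_equal(a.wavelengths, b.wavelengths):
        raise ValueError("projections have different wavelengths")
    if not np.array_equal(a.weights, b.weights):
        raise ValueError("projections have different emission weights")
    nodes = np.union1d(a.detector_nodes, b.detector_nodes)
    vals = np.zeros((len(nodes), len(a.wavelengths)))
    ia = np.searchsorted(nodes, a.detector_nodes)
    ib = np.searchsorted(nodes, b.detector_nodes)
    np.maximum.at(vals, ia, a.intensities)
    np.maximum.at(vals, ib, b.intensities)
    return SpectralMeasurement(nodes, a.wavelengths.copy(), vals, a.weights.copy())


def normalize_to_spectrum(m: SpectralMeasurement) -> SpectralMeasurement:
    """Divide each wavelength column by its emission weight; reset weights to 1."""
    out = m.copy()
    out.intensities = m.intensities / m.weights[None, :]
    out.weights = np.ones_like(m.weights)
    return out


def correct_time_drift(m: SpectralMeasurement) -> SpectralMeasurement:
    """Rescale each spectral image to the open-field level at the first
    acquisition, interpolating the open-field curve at each image timestamp."""
    if m.timestamps is None or m.openfield is None:
        raise ValueError("timestamps and an open-field series are required")
    if len(m.openfield) < 2:
        raise ValueError("open-field series needs at least two points")
    t, level = m.openfield[:, 0], m.openfield[:, 1]
    order = np.argsort(t)
    t, level = t[order], level[order]
    if np.any(m.timestamps < t[0]) or np.any(m.timestamps > t[-1]):
        raise ValueError("image timestamp outside the open-field series range")
    at_images = np.interp(m.timestamps, t, level)
    if np.any(at_images <= 0):
        raise ValueError("open-field level must be positive at image times")
    reference = at_images[int(np.argmin(m.timestamps))]
    out = m.copy()
    out.intensities = m.intensities * (reference / at_images)[None, :]
    return out


# -- TSV I/O ----------------------------------------------------------------


def write_measurement_tsv(path, m: SpectralMeasurement) -> None:
    """Long-format TSV: node_id, wavelength_nm, intensity [, timestamp_s]."""
    d, w = m.intensities.shape
    frame = {
        "node_id": np.repeat(m.detector_nodes, w),
        "wavelength_nm": np.tile(m.wavelengths, d),
        "intensity": m.intensities.ravel(),
    }
    if m.timestamps is not None:
        frame["timestamp_s"] = np.tile(m.timestamps, d)
    pd.DataFrame(frame).to_csv(path, sep="\t", index=False)


def read_measurement_tsv(path, weights=None) -> SpectralMeasurement:
    df = pd.read_csv(Path(path), sep="\t")
    for col in ("node_id", "wavelength_nm", "intensity"):
        if col not in df.columns:
            raise ValueError(f"measurement file lacks column {col!r}")
    wide = df.pivot_table(
        index="node_id", columns="wavelength_nm", values="intensity"
    )
    if wide.isna().any().any():
        raise ValueError("every detector needs a value at every wavelength")
    wavelengths = wide.columns.to_numpy(dtype=float)
    timestamps = None
    if "timestamp_s" in df.columns:
        ts = df.groupby("wavelength_nm")["timestamp_s"].first()
        timestamps = ts.reindex(wide.columns).to_numpy(dtype=float)
    return SpectralMeasurement(
        wide.index.to_numpy(dtype=np.int64),
        wavelengths,
        wide.to_numpy(dtype=float),
        None if weights is None else np.asarray(weights, dtype=float),
        timestamps,
    )
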