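"""Measurement preprocessing: threshold, merge, normalization, drift."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lumitomo.preprocess import (
    SpectralMeasurement,
    correct_time_drift,
    merge_projections,
    normalize_to_spectrum,
    read_measurement_tsv,
    threshold_surface_data,
    write_measurement_tsv,
)

WL = np.array([610.0, 630.0, 650.0])


def meas(nodes, values, weights=None, **kw):
    return SpectralMeasurement(
        np.asarray(nodes), WL.copy(), np.asarray(values, dtype=float), weights, **kw
    )


def test_threshold_keeps_detectors_above_fraction_of_global_max():
    m = meas([1, 2, 3], [[100, 90, 80], [15, 10, 5], [9, 9, 9]])
    out = threshold_surface_data(m, 0.10)
    # per-detector maxima 100, 15, 9: only the first two exceed 10
    assert list(out.detector_nodes) == [1, 2]
    assert np.array_equal(out.intensities, m.intensities[:2])


def test_threshold_zero_fraction_is_identity():
    m = meas([1, 2], [[5, 4, 3], [1, 2, 3]])
    out = threshold_surface_data(m, 0.0)
    assert np.array_equal(out.detector_nodes, m.detector_nodes)


def test_threshold_uniform_data_keeps_everything():
    m = meas([0, 1, 2], np.full((3, 3), 7.0))
    assert threshold_surface_data(m, 0.9).detector_nodes.size == 3


def test_threshold_empty_result_raises():
    m = meas([0], [[0.0, 0.0, 0.0]])
    with pytest.raises(ValueError, match="survive"):
        threshold_surface_data(m, 0.10)


def test_merge_disjoint_is_concatenation():
    a = meas([0, 1], [[1, 1, 1], [2, 2, 2]])
    b = meas([5], [[3, 3, 3]])
    out = merge_projections(a, b)
    assert list(out.detector_nodes) == [0, 1, 5]
    assert out.intensities[2, 0] == 3


def test_merge_overlap_takes_maximum_per_node_per_wavelength():
    a = meas([4], [[3.0, 8.0, 1.0]])
    b = meas([4], [[5.0, 2.0, 1.0]])
    out = merge_projections(a, b)
    assert np.array_equal(out.intensities, [[5.0, 8.0, 1.0]])


def test_merge_idempotent():
    a = meas([0, 7], [[1, 2, 3], [4, 5, 6]])
    out = merge_projections(a, a)
    assert np.array_equal(out.detector_nodes, a.detector_nodes)
    assert np.array_equal(out.intensities, a.intensities)


def test_merge_wavelength_mismatch_raises():
    a = meas([0], [[1, 2, 3]])
    b = SpectralMeasurement([0], [610.0, 620.0, 650.0], [[1, 2, 3]])
    with pytest.raises(ValueError, match="wavelength"):
        merge_projections(a, b)


def test_merge_then_threshold_equals_threshold_on_merged_maximum():
    """The pipeline merges first; thresholding the merged data must equal
    thresholding computed on the merged per-node maxima."""
    rng = np.random.default_rng(3)
    a = meas(np.arange(10), rng.uniform(0, 100, (10, 3)))
    b = meas(np.arange(5, 15), rng.uniform(0, 100, (10, 3)))
    merged = merge_projections(a, b)
    out = threshold_surface_data(merged, 0.10)
    per_det = merged.intensities.max(axis=1)
    keep = merged.detector_nodes[per_det > 0.10 * per_det.max()]
    assert np.array_equal(out.detector_nodes, keep)


def test_normalize_divides_columns_and_resets_weights():
    weights = np.array([1.0, 0.674, 0.389])
    m = meas([0], [[1.0, 0.674, 0.389]], weights)
    out = normalize_to_spectrum(m)
    assert np.allclose(out.intensities, 1.0)
    assert np.allclose(out.weights, 1.0)
    # idempotent once weights are reset
    again = normalize_to_spectrum(out)
    assert np.allclose(again.intensities, out.intensities)


def test_normalize_four_wavelength_cell_spectrum():
    """The measured four-band cell spectrum weighting: the 650 nm column is
    divided by its weight 0.389."""
    wl = np.array([590.0, 610.0, 630.0, 650.0])
    weights = np.array([1.0, 0.916, 0.674, 0.389])
    m = SpectralMeasurement([0], wl, [[2.0, 2.0, 2.0, 2.0]], weights)
    out = normalize_to_spectrum(m)
    assert out.intensities[0, 3] == pytest.approx(2.0 / 0.389)
    assert out.intensities[0, 1] == pytest.approx(2.0 / 0.916)
    assert np.allclose(out.weights, 1.0)


def test_normalize_with_unit_weights_is_identity():
    m = meas([0, 1], [[1, 2, 3], [4, 5, 6]])
    out = normalize_to_spectrum(m)
    assert np.array_equal(out.intensities, m.intensities)


def test_time_drift_constant_series_is_identity():
    m = meas(
        [0],
        [[2.0, 3.0, 4.0]],
        timestamps=np.array([10.0, 20.0, 30.0]),
        openfield=np.array([[0.0, 5.0], [40.0, 5.0]]),
    )
    out = correct_time_drift(m)
    assert np.allclose(out.intensities, m.intensities)


def test_time_drift_linear_decay_scaling():
    """Open field halves linearly over the session; the image taken at the
    midpoint is scaled by 1/0.75 relative to the first acquisition."""
    m = meas(
        [0],
        [[1.0, 1.0, 1.0]],
        timestamps=np.array([0.0, 50.0, 100.0]),
        openfield=np.array([[0.0, 8.0], [100.0, 4.0]]),
    )
    out = correct_time_drift(m)
    assert out.intensities[0, 0] == pytest.approx(1.0)
    assert out.intensities[0, 1] == pytest.approx(1.0 / 0.75)
    assert out.intensities[0, 2] == pytest.approx(2.0)


def test_time_drift_identical_timestamps_identical_factors():
    m = meas(
        [0],
        [[1.0, 2.0, 3.0]],
        timestamps=np.array([30.0, 30.0, 30.0]),
        openfield=np.array([[0.0, 10.0], [60.0, 5.0]]),
    )
    out = correct_time_drift(m)
    factors = out.intensities[0] / m.intensities[0]
    assert np.allclose(factors, factors[0])


def test_time_drift_outside_series_raises():
    m = meas(
        [0],
        [[1.0, 1.0, 1.0]],
        timestamps=np.array([0.0, 50.0, 200.0]),
        openfield=np.array([[0.0, 8.0], [100.0, 4.0]]),
    )
    with pytest.raises(ValueError, match="outside"):
        correct_time_drift(m)


@given(scale=st.floats(0.01, 100.0))
@settings(deadline=None, max_examples=25)
def test_preprocessing_is_scale_covariant(scale):
    vals = np.array([[10.0, 8.0, 5.0], [1.5, 1.2, 1.0], [0.5, 0.4, 0.3]])
    weights = np.array([1.0, 0.893, 0.633])
    base = normalize_to_spectrum(
        threshold_surface_data(meas([0, 1, 2], vals, weights), 0.10)
    )
    scaled = normalize_to_spectrum(
        threshold_surface_data(meas([0, 1, 2], scale * vals, weights.copy()), 0.10)
    )
    assert np.array_equal(base.detector_nodes, scaled.detector_nodes)
    assert np.allclose(scaled.intensities, scale * base.intensities, rtol=1e-12)


def test_tsv_round_trip(tmp_path):
    m = meas(
        [3, 9],
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        timestamps=np.array([0.0, 10.0, 20.0]),
    )
    path = tmp_path / "meas.tsv"
    write_measurement_tsv(path, m)
    back = read_measurement_tsv(path)
    assert np.array_equal(back.detector_nodes, m.detector_nodes)
    assert np.allclose(back.wavelengths, m.wavelengths)
    assert np.allclose(back.intensities, m.intensities)
    assert np.allclose(back.timestamps, m.timestamps)


def test_measurement_validation():
    with pytest.raises(ValueError):
        meas([0], [[-1.0, 1.0, 1.0]])
    with pytest.raises(ValueError):
        meas([0], [[1.0, 1.0, 1.0]], np.array([1.0, 0.0, 1.0]))
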