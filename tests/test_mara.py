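"""Correction chain: stage contracts, locality, descent, end-to-end paths."""

import numpy as np
import pytest
from scipy import ndimage

from fdmar.mara import (MaraParams, MetalMask, compute_trace, default_metal_threshold,
                        denormalize_sinogram, inpaint_trace, normalize_sinogram,
                        run_mara, segment_metal, smooth_boundary, total_variation,
                        tv_reduce, MetalTrace)
from fdmar.phantoms import LABEL_METAL, ScenarioConfig, generate_phantom
from fdmar.projector import (PhysicsModel, Sinogram, default_geometry,
                             forward_project, make_geometry, simulate_measurement,
                             to_line_integrals)
from fdmar.recon import Volume, fbp_reconstruct


def _measured(phantom, geometry, noise="poisson", seed=17):
    physics = PhysicsModel(noise=noise, seed=seed)
    return to_line_integrals(simulate_measurement(phantom, geometry, physics), physics)


# --------------------------------------------------------------------------
# segment_metal
# --------------------------------------------------------------------------

def test_segment_no_metal_gives_empty_mask(nometal_phantom_128, geometry_128):
    vol = fbp_reconstruct(_measured(nometal_phantom_128, geometry_128),
                          geometry_128, "sharp", grid_size=128,
                          voxel_size_mm=nometal_phantom_128.voxel_size_mm)
    mask = segment_metal(vol, default_metal_threshold())
    assert mask.empty and mask.components == 0


def test_segment_threshold_must_exceed_soft_tissue():
    vol = Volume(np.zeros((8, 8)), 1.0)
    with pytest.raises(ValueError, match="soft"):
        segment_metal(vol, 0.001)


def test_segment_multi_clip_retains_all_components():
    """Flood-fill oracle on the label map vs segmentation of a noiseless
    monochromatic reconstruction."""
    ph = generate_phantom(ScenarioConfig(implant_kind="multi_clip", grid_size=192,
                                         noise_seed=21))
    geom = default_geometry("5s", 192, ph.voxel_size_mm)
    vol = fbp_reconstruct(_measured(ph, geom, noise="none"), geom, "sharp",
                          grid_size=192, voxel_size_mm=ph.voxel_size_mm)
    mask = segment_metal(vol, default_metal_threshold())
    _, n_true = ndimage.label(ph.labels == LABEL_METAL, structure=np.ones((3, 3)))
    assert n_true >= 2
    assert mask.components >= 2


def test_segment_recovers_most_metal_on_noiseless_recon():
    ph = generate_phantom(ScenarioConfig(implant_kind="coil", grid_size=192,
                                         noise_seed=3))
    geom = default_geometry("5s", 192, ph.voxel_size_mm)
    physics = PhysicsModel(noise="none").monochromatic()
    m = to_line_integrals(simulate_measurement(ph, geom, physics), physics)
    vol = fbp_reconstruct(m, geom, "sharp", grid_size=192,
                          voxel_size_mm=ph.voxel_size_mm)
    mask = segment_metal(vol, default_metal_threshold())
    true_count = int((ph.labels == LABEL_METAL).sum())
    assert mask.values.sum() >= 0.8 * true_count


# --------------------------------------------------------------------------
# compute_trace
# --------------------------------------------------------------------------

def test_trace_empty_mask_empty_trace(geometry_128):
    mask = MetalMask(np.zeros((128, 128), bool), 0, 0.4)
    trace = compute_trace(mask, geometry_128, 1.2, margin_bins=2)
    assert not trace.values.any()


def test_trace_central_pixel_covers_central_bin_every_view():
    n = 65
    geom = make_geometry("5s", n_bins=n, bin_spacing_mm=1.0)
    values = np.zeros((n, n), bool)
    values[n // 2, n // 2] = True
    trace = compute_trace(MetalMask(values, 1, 0.4), geom, 1.0, margin_bins=1)
    center = n // 2
    assert trace.values[:, center].all()


def test_trace_margin_is_monotone(coil_phantom_128, geometry_128):
    values = coil_phantom_128.labels == LABEL_METAL
    mask = MetalMask(values, 1, 0.4)
    t0 = compute_trace(mask, geometry_128, coil_phantom_128.voxel_size_mm, 0)
    t2 = compute_trace(mask, geometry_128, coil_phantom_128.voxel_size_mm, 2)
    assert np.all(t2.values[t0.values])


# --------------------------------------------------------------------------
# normalize / inpaint / denormalize / smooth
# --------------------------------------------------------------------------

def _random_sino(geom, seed, positive=True):
    rng = np.random.default_rng(seed)
    v = rng.random((geom.n_views, geom.n_bins))
    return Sinogram(v + (0.5 if positive else -0.5), "line_integral", geom)


def test_normalize_identity_when_measured_equals_prior():
    geom = make_geometry("5s", n_bins=33, bin_spacing_mm=1.0)
    s = _random_sino(geom, 0)
    out = normalize_sinogram(s, s, 1e-3)
    assert np.allclose(out.values, 1.0)


def test_normalize_floors_small_priors():
    geom = make_geometry("5s", n_bins=4, bin_spacing_mm=1.0)
    measured = Sinogram(np.full((133, 4), 2.0), "line_integral", geom)
    prior = Sinogram(np.zeros((133, 4)), "line_integral", geom)
    out = normalize_sinogram(measured, prior, 1e-2)
    assert np.allclose(out.values, 200.0)


@pytest.mark.parametrize("seed", range(5))
def test_normalize_denormalize_round_trip_exact(seed):
    """Round trip is the identity everywhere, including sub-epsilon priors."""
    geom = make_geometry("5s", n_bins=40, bin_spacing_mm=1.0)
    rng = np.random.default_rng(seed)
    measured = Sinogram(rng.random((133, 40)) * 5, "line_integral", geom)
    prior_vals = rng.random((133, 40)) * 3
    prior_vals[rng.random((133, 40)) < 0.1] = 0.0  # below-floor entries
    prior = Sinogram(prior_vals, "line_integral", geom)
    eps = 1e-3
    out = denormalize_sinogram(normalize_sinogram(measured, prior, eps), prior, eps)
    assert np.array_equal(out.values, measured.values) or \
        np.allclose(out.values, measured.values, rtol=0, atol=1e-15)


def test_normalize_shape_mismatch():
    geom_a = make_geometry("5s", n_bins=8, bin_spacing_mm=1.0)
    geom_b = make_geometry("5s", n_bins=9, bin_spacing_mm=1.0)
    with pytest.raises(ValueError, match="mismatch"):
        normalize_sinogram(_random_sino(geom_a, 0), _random_sino(geom_b, 0), 1e-3)


def test_inpaint_reproduces_linear_profiles_exactly():
    geom = make_geometry("5s", n_bins=32, bin_spacing_mm=1.0)
    ramp = np.tile(np.arange(32.0) * 0.5 + 1.0, (133, 1))
    trace = np.zeros((133, 32), bool)
    trace[:, 10:20] = True
    out = inpaint_trace(Sinogram(ramp.copy(), "line_integral", geom),
                        MetalTrace(trace, 0))
    assert np.allclose(out.values, ramp, atol=1e-12)


def test_inpaint_leaves_off_trace_bit_identical():
    geom = make_geometry("5s", n_bins=48, bin_spacing_mm=1.0)
    rng = np.random.default_rng(8)
    sino = Sinogram(rng.random((133, 48)), "line_integral", geom)
    trace = rng.random((133, 48)) < 0.2
    out = inpaint_trace(sino, MetalTrace(trace, 0))
    assert np.array_equal(out.values[~trace], sino.values[~trace])
    empty = inpaint_trace(sino, MetalTrace(np.zeros_like(trace), 0))
    assert np.array_equal(empty.values, sino.values)


def test_inpaint_edge_trace_constant_extension():
    geom = make_geometry("5s", n_bins=10, bin_spacing_mm=1.0)
    vals = np.tile(np.arange(10.0), (133, 1))
    trace = np.zeros((133, 10), bool)
    trace[:, :3] = True  # touches the left detector edge
    out = inpaint_trace(Sinogram(vals, "line_integral", geom), MetalTrace(trace, 0))
    assert np.allclose(out.values[:, :3], 3.0)  # nearest interior value


def test_inpaint_fully_covered_view_falls_back(caplog):
    geom = make_geometry("5s", n_bins=6, bin_spacing_mm=1.0)
    vals = np.full((133, 6), 2.0)
    vals[0] = 9.0
    trace = np.zeros((133, 6), bool)
    trace[0] = True  # view 0 fully covered
    import logging

    with caplog.at_level(logging.WARNING, logger="fdmar.mara"):
        out = inpaint_trace(Sinogram(vals, "line_integral", geom), MetalTrace(trace, 0))
    assert np.allclose(out.values[0], 2.0)
    assert any("fully covered" in r.message for r in caplog.records)


def test_smooth_boundary_contracts():
    geom = make_geometry("5s", n_bins=40, bin_spacing_mm=1.0)
    rng = np.random.default_rng(4)
    corrected = Sinogram(rng.random((133, 40)), "line_integral", geom)
    measured = Sinogram(rng.random((133, 40)), "line_integral", geom)
    trace = np.zeros((133, 40), bool)
    trace[:, 18:22] = True
    mt = MetalTrace(trace, 0)
    # band 0: corrected returned unchanged
    out0 = smooth_boundary(corrected, measured, mt, 0)
    assert np.array_equal(out0.values, corrected.values)
    # identical inputs: unchanged
    out_same = smooth_boundary(measured, measured, mt, 3)
    assert np.allclose(out_same.values, measured.values)
    # convex combination bound inside the band
    out = smooth_boundary(corrected, measured, mt, 3)
    lo = np.minimum(corrected.values, measured.values)
    hi = np.maximum(corrected.values, measured.values)
    assert np.all(out.values >= lo - 1e-12) and np.all(out.values <= hi + 1e-12)
    # inside the trace the corrected data is kept
    assert np.array_equal(out.values[trace], corrected.values[trace])


# --------------------------------------------------------------------------
# tv_reduce
# --------------------------------------------------------------------------

def test_tv_zero_iterations_is_identity():
    rng = np.random.default_rng(0)
    vol = Volume(rng.random((32, 32)), 1.0)
    out = tv_reduce(vol, None, 0, 0.1)
    assert np.array_equal(out.values, vol.values)
    with pytest.raises(ValueError, match="step"):
        tv_reduce(vol, None, 1, 0.0)


@pytest.mark.parametrize("seed", range(10))
def test_tv_never_increases_per_iteration(seed):
    rng = np.random.default_rng(seed)
    u = rng.random((24, 24))
    vol = Volume(u, 1.0)
    tv_prev = total_variation(vol.values)
    for _ in range(5):
        vol = tv_reduce(vol, None, 1, 0.1)
        tv_now = total_variation(vol.values)
        assert tv_now <= tv_prev + 1e-12
        tv_prev = tv_now


def test_tv_removes_streaks_from_piecewise_constant_image():
    """Constructed streak fixture: RMSE to the clean image decreases."""
    n = 64
    clean = np.full((n, n), 0.02)
    clean[20:40, 20:40] = 0.05
    yy, xx = np.mgrid[0:n, 0:n]
    streaks = 0.004 * np.sin(0.9 * (xx + 2 * yy))
    vol = Volume(clean + streaks, 1.0)
    out = tv_reduce(vol, None, 10, 0.1)
    rmse_before = np.sqrt(np.mean((vol.values - clean) ** 2))
    rmse_after = np.sqrt(np.mean((out.values - clean) ** 2))
    assert rmse_after < rmse_before


def test_tv_freezes_masked_voxels():
    rng = np.random.default_rng(5)
    u = rng.random((24, 24))
    frozen = np.zeros((24, 24), bool)
    frozen[10:14, 10:14] = True
    mask = MetalMask(frozen, 1, 0.4)
    out = tv_reduce(Volume(u, 1.0), mask, 5, 0.2)
    assert np.array_equal(out.values[frozen], u[frozen])


# --------------------------------------------------------------------------
# run_mara end to end
# --------------------------------------------------------------------------

def test_empty_mask_bypass_corrected_equals_uncorrected(nometal_phantom_128,
                                                        geometry_128):
    measured = _measured(nometal_phantom_128, geometry_128)
    result = run_mara(measured, geometry_128, "sharp",
                      MaraParams(tv_iterations=0), grid_size=128,
                      voxel_size_mm=nometal_phantom_128.voxel_size_mm)
    assert result.mask.empty
    assert result.trace is None
    assert np.array_equal(result.corrected.values, result.uncorrected.values)
    assert result.corrected.provenance == "mara_corrected"


def test_run_mara_requires_line_integrals(coil_phantom_128, geometry_128):
    counts = simulate_measurement(coil_phantom_128, geometry_128, PhysicsModel(seed=1))
    with pytest.raises(TypeError, match="line_integral"):
        run_mara(counts, geometry_128)


def test_off_trace_sinogram_preserved_with_zero_band(coil_phantom_128, geometry_128):
    """The corrected sinogram equals the measured one at every off-trace
    entry when the boundary band is disabled."""
    from fdmar.mara import build_prior_volume

    ph = coil_phantom_128
    measured = _measured(ph, geometry_128)
    params = MaraParams(boundary_band_bins=0, tv_iterations=0)
    uncorrected = fbp_reconstruct(measured, geometry_128, "sharp", grid_size=128,
                                  voxel_size_mm=ph.voxel_size_mm)
    mask = segment_metal(uncorrected, params.resolved_threshold())
    trace = compute_trace(mask, geometry_128, ph.voxel_size_mm,
                          params.trace_margin_bins)
    prior_vol = build_prior_volume(uncorrected, mask, params.prior_dilation_mm)
    prior = forward_project(prior_vol.values, geometry_128, ph.voxel_size_mm)
    corrected = denormalize_sinogram(
        inpaint_trace(normalize_sinogram(measured, prior, params.epsilon), trace),
        prior, params.epsilon)
    corrected = smooth_boundary(corrected, measured, trace, 0)
    off = ~trace.values
    assert np.allclose(corrected.values[off], measured.values[off], rtol=0, atol=1e-14)


def test_run_mara_reduces_artifacts_on_coil_case():
    """Smoke-scale paired check; the full 20-seed study runs in acceptance."""
    from fdmar.studies import run_case

    case = run_case(ScenarioConfig(implant_kind="coil", grid_size=128, noise_seed=12))
    assert case["corrected"].artifact_index < case["uncorrected"].artifact_index


def test_multi_clip_corrected_jointly_in_one_pass():
    ph = generate_phantom(ScenarioConfig(implant_kind="multi_clip", grid_size=192,
                                         noise_seed=21))
    geom = default_geometry("5s", 192, ph.voxel_size_mm)
    measured = _measured(ph, geom)
    result = run_mara(measured, geom, "sharp", MaraParams(),
                      grid_size=192, voxel_size_mm=ph.voxel_size_mm)
    assert result.mask.components >= 2
    # the trace covers the projection of every component, not just the largest
    proj = forward_project(result.mask.values.astype(float), geom, ph.voxel_size_mm)
    assert np.all(result.trace.values[proj.values > 1e-6 * ph.voxel_size_mm])


def test_metal_reinsertion_keeps_implant_visible(coil_phantom_128, geometry_128):
    ph = coil_phantom_128
    measured = _measured(ph, geometry_128)
    result = run_mara(measured, geometry_128, "sharp",
                      MaraParams(tv_iterations=0), grid_size=128,
                      voxel_size_mm=ph.voxel_size_mm)
    m = result.mask.values
    assert np.array_equal(result.corrected.values[m], result.uncorrected.values[m])


def test_stage_errors_carry_stage_name(coil_phantom_128, geometry_128):
    measured = _measured(coil_phantom_128, geometry_128)
    bad = MaraParams(tv_iterations=1, tv_step=-1.0)
    with pytest.raises(RuntimeError, match="tv_reduce"):
        run_mara(measured, geometry_128, "sharp", bad, grid_size=128,
                 voxel_size_mm=coil_phantom_128.voxel_size_mm)


def test_correction_is_nearly_idempotent():
    """Re-running the chain on the corrected, metal-reinserted volume's
    re-projection changes the artifact index by less than 10% (tendency
    guard, not exactness)."""
    from fdmar.evaluation import compute_image_metrics

    ph = generate_phantom(ScenarioConfig(implant_kind="coil", grid_size=128,
                                         noise_seed=3))
    geom = default_geometry("5s", 128, ph.voxel_size_mm)
    measured = _measured(ph, geom, seed=4)
    first = run_mara(measured, geom, "sharp", MaraParams(), grid_size=128,
                     voxel_size_mm=ph.voxel_size_mm)
    ai_first = compute_image_metrics(first.corrected, ph).artifact_index
    reprojected = forward_project(first.corrected.values, geom, ph.voxel_size_mm)
    second = run_mara(reprojected, geom, "sharp", MaraParams(), grid_size=128,
                      voxel_size_mm=ph.voxel_size_mm)
    ai_second = compute_image_metrics(second.corrected, ph).artifact_index
    assert abs(ai_second - ai_first) / ai_first < 0.10
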