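"""Biomarker extraction, vessel FWHM, blood volume and depth-resolved TP."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from frsom import (COHORT_PRESETS, HemodynamicParams, IntensityProfile,
                   LayerBounds, LONG_PROTOCOL, ReconGrid, ReconImage,
                   compute_biomarkers, depth_resolved_tp,
                   hemodynamic_modulation, layer_profile, percent_increment,
                   total_blood_volume, vessel_fwhm)


def _bounds():
    return LayerBounds(d_ep_um=100.0, d_sd_um=200.0, d_max_um=1000.0)


def _frames(values, nx=10, nz=100, dz=10.0):
    """One uniform 2D frame per value (per-layer values via a dict)."""
    grid = ReconGrid(voxel_um=(10.0, 10.0, dz),
                     extent_mm=(nx * 1e-2, 1e-2, nz * dz * 1e-3))
    z = (np.arange(nz) + 0.5) * dz
    frames = []
    for v in values:
        data = np.zeros((nx, 1, nz))
        if isinstance(v, dict):
            for layer, val in v.items():
                lo, hi = _bounds().interval_um(layer)
                data[:, :, (z >= lo) & (z < hi)] = val
        else:
            data[:] = v
        frames.append(ReconImage(data=data, grid=grid))
    return frames


# --------------------------------------------------------------------------
# layer profiles
# --------------------------------------------------------------------------

def test_constant_frames_give_constant_profile():
    frames = _frames([2.0] * 5)
    t = np.arange(5) / 60.0 * 150  # arbitrary increasing times
    profs = layer_profile(frames, _bounds(), LONG_PROTOCOL, times_min=t)
    for layer in ("SD", "RD", "DV"):
        assert np.allclose(profs[layer].intensity, 2.0)


def test_single_frame_change_is_isolated():
    vals = [1.0, 1.0, 3.0, 1.0]
    frames = _frames([{"SD": v, "RD": v} for v in vals])
    t = np.arange(4) * 0.5
    profs = layer_profile(frames, _bounds(), LONG_PROTOCOL, times_min=t)
    assert profs["SD"].intensity[2] == pytest.approx(3.0)
    assert np.allclose(profs["SD"].intensity[[0, 1, 3]], 1.0)


def test_ep_changes_do_not_leak_into_dermal_profiles():
    a = _frames([{"EP": 1.0, "SD": 1.0, "RD": 2.0}])
    b = _frames([{"EP": 9.0, "SD": 1.0, "RD": 2.0}])
    t = np.array([0.0])
    pa = layer_profile(a, _bounds(), LONG_PROTOCOL, times_min=t)
    pb = layer_profile(b, _bounds(), LONG_PROTOCOL, times_min=t)
    for layer in ("SD", "RD", "DV"):
        assert pa[layer].intensity == pytest.approx(pb[layer].intensity)


def test_dv_is_voxel_weighted_mean_of_sd_and_rd():
    frames = _frames([{"SD": 2.0, "RD": 5.0}])
    t = np.array([0.0])
    profs = layer_profile(frames, _bounds(), LONG_PROTOCOL, times_min=t)
    b = _bounds()
    n_sd = (b.interval_um("SD")[1] - b.interval_um("SD")[0])
    n_rd = (b.interval_um("RD")[1] - b.interval_um("RD")[0])
    expected = (2.0 * n_sd + 5.0 * n_rd) / (n_sd + n_rd)
    assert profs["DV"].intensity[0] == pytest.approx(expected)


def test_empty_mask_raises():
    frames = _frames([1.0])
    bad = LayerBounds(d_ep_um=990.0, d_sd_um=5.0, d_max_um=1000.0)
    with pytest.raises(ValueError, match="empty"):
        layer_profile(frames, bad, LONG_PROTOCOL, times_min=np.array([0.0]),
                      layers=("SD",))


# --------------------------------------------------------------------------
# biomarker formulas
# --------------------------------------------------------------------------

def _profile_from_params(mvc, hr, tp, protocol=LONG_PROTOCOL, **kw):
    h = HemodynamicParams(mvc_true=mvc, hr_true=hr, tp_true=tp, **kw)
    t = protocol.times_min()
    return IntensityProfile(t, hemodynamic_modulation(h, protocol, t),
                            "DV", protocol)


def test_biomarkers_printed_group_shape():
    # MVB=1, plateau ~0.66, peak 1.2560 at 8.42 min -> MVC~0.34, HR=20.38%,
    # TP=1.42 min (occlusion transient makes MVIC slightly above the floor)
    prof = _profile_from_params(0.34, 0.2038, 1.42,
                                occlusion_decay_tau=1e-3)
    bm = compute_biomarkers(prof, peak_smooth_s=0, refine_peak_s=0)
    assert bm.mvb == pytest.approx(1.0, abs=1e-9)
    assert bm.mvc == pytest.approx(0.34, rel=0.01)
    assert bm.hr_pct == pytest.approx(20.38, abs=0.05)
    assert bm.tp_min == pytest.approx(1.42, abs=1.0 / 60.0 + 1e-9)


def test_biomarkers_constant_profile():
    t = LONG_PROTOCOL.times_min()
    prof = IntensityProfile(t, np.ones_like(t), "DV", LONG_PROTOCOL)
    bm = compute_biomarkers(prof)
    assert bm.mvc == 0.0
    assert bm.hr_pct == 0.0
    # earliest-tie peak: within one frame interval of the release
    assert 0.0 <= bm.tp_min <= 1.0 / 60.0 + 1e-9


def test_biomarkers_require_post_release_samples():
    t = np.linspace(0, 6.5, 100)
    prof = IntensityProfile(t, np.ones_like(t), "DV", LONG_PROTOCOL)
    with pytest.raises(ValueError, match="release"):
        compute_biomarkers(prof)


def test_noise_free_recovery_matches_generator_truth():
    prof = _profile_from_params(0.30, 0.15, 1.30, occlusion_decay_tau=1e-3,
                                recovery_tau=1.0)
    bm = compute_biomarkers(prof)
    assert bm.mvc == pytest.approx(0.30, rel=0.01)
    assert bm.hr_pct == pytest.approx(15.0, rel=0.01)
    assert bm.tp_min == pytest.approx(1.30, abs=1.0 / 60.0 + 0.04)


def test_identities_hold_exactly_on_random_profiles():
    rng = np.random.default_rng(0)
    t = LONG_PROTOCOL.times_min()[::5]
    for _ in range(1000):
        y = rng.gamma(2.0, 1.0, t.size)
        bm = compute_biomarkers(IntensityProfile(t, y, "DV", LONG_PROTOCOL))
        assert bm.mvc == bm.mvb - bm.mvic
        assert bm.hr_pct == 100.0 * (bm.piv - bm.mvb) / bm.piv
        assert bm.tp_min == bm.t_piv_min - LONG_PROTOCOL.t_release_min
        assert bm.tp_min >= 0.0


@settings(deadline=None, max_examples=30, derandomize=True)
@given(c=st.floats(1e-3, 1e3))
def test_hr_and_tp_scale_invariant(c):
    prof = _profile_from_params(0.4, 0.2, 1.6)
    noisy = prof.scaled(1.0)
    noisy.intensity += np.random.default_rng(1).normal(0, 0.02,
                                                       prof.t_min.size)
    a = compute_biomarkers(noisy)
    b = compute_biomarkers(noisy.scaled(c))
    assert b.hr_pct == pytest.approx(a.hr_pct, rel=1e-9, abs=1e-9)
    assert b.tp_min == pytest.approx(a.tp_min, abs=1e-9)
    assert b.mvc == pytest.approx(c * a.mvc, rel=1e-9)


# --------------------------------------------------------------------------
# vessel FWHM
# --------------------------------------------------------------------------

def _image_from_row(row, voxel=(5.0, 5.0)):
    data = np.tile(row, (5, 1)).T  # rows along lateral axis
    data = np.asarray([row] * 5)
    return (np.asarray(data), voxel)


def test_fwhm_gaussian_closed_form():
    sigma = 30.0  # um
    step = 5.0
    x = (np.arange(200) - 100) * step
    row = np.exp(-0.5 * (x / sigma) ** 2)
    img = (np.tile(row, (5, 1)), (step, step))
    w = vessel_fwhm(img, (2, 100), direction="depth")
    assert w == pytest.approx(2.3548 * sigma, rel=0.02)


def test_fwhm_top_hat():
    step = 5.0
    row = np.zeros(120)
    row[40:60] = 1.0  # 100 um wide
    img = (np.tile(row, (5, 1)), (step, step))
    w = vessel_fwhm(img, (2, 50), direction="depth")
    assert w == pytest.approx(100.0, abs=step)


def test_fwhm_cylinder_with_psf_matches_convolution_oracle():
    # vessel cross-section = circle chord profile; imaging blurs with an
    # ~18 um FWHM Gaussian point-spread function
    r, step = 30.0, 2.0
    psf_sigma = 18.0 / 2.3548
    x = (np.arange(-150, 151)) * step
    chord = np.where(np.abs(x) < r, np.sqrt(np.clip(r ** 2 - x ** 2, 0, None)),
                     0.0)
    psf = np.exp(-0.5 * (x / psf_sigma) ** 2)
    blurred = np.convolve(chord, psf, mode="same")
    # oracle FWHM by dense linear interpolation of the blurred profile
    xx = np.linspace(x[0], x[-1], 60001)
    yy = np.interp(xx, x, blurred)
    above = yy >= yy.max() / 2.0
    oracle = xx[above][-1] - xx[above][0]
    img = (np.tile(blurred, (5, 1)), (step, step))
    w = vessel_fwhm(img, (2, 150), direction="depth", window_um=320.0)
    assert w == pytest.approx(oracle, rel=0.05)


def test_fwhm_flags_missing_crossing_as_nan():
    row = np.linspace(1.0, 2.0, 80)  # monotone ramp: no symmetric peak
    img = (np.tile(row, (5, 1)), (5.0, 5.0))
    assert np.isnan(vessel_fwhm(img, (2, 79), direction="depth",
                                window_um=50.0))


# --------------------------------------------------------------------------
# percent increment
# --------------------------------------------------------------------------

@pytest.mark.parametrize("b,p,expected", [(27.0, 33.0, 22.0),
                                          (50.0, 60.0, 20.0),
                                          (40.0, 40.0, 0.0)])
def test_percent_increment_reporting(b, p, expected):
    assert percent_increment(b, p, rounded=True) == expected


def test_percent_increment_unrounded_and_errors():
    assert percent_increment(58.0, 69.0) == pytest.approx(18.9655, abs=1e-3)
    with pytest.raises(ValueError):
        percent_increment(0.0, 10.0)


# --------------------------------------------------------------------------
# total blood volume
# --------------------------------------------------------------------------

def test_blood_volume_counts_super_threshold_voxels():
    grid = ReconGrid(voxel_um=(10.0, 10.0, 10.0), extent_mm=(0.2, 0.01, 1.0))
    data = np.zeros(grid.shape)
    data[3:7, 0, 20:25] = 1.0  # 20 voxels in the SD interval
    img = ReconImage(data=data, grid=grid)
    v = total_blood_volume(img, _bounds())
    assert v["SD"] == pytest.approx(20 * 1000.0)
    assert v["RD"] == 0.0
    assert v["DV"] == v["SD"] + v["RD"]


def test_blood_volume_empty_volume_is_zero():
    grid = ReconGrid(voxel_um=(10.0, 10.0, 10.0), extent_mm=(0.2, 0.01, 1.0))
    img = ReconImage(data=np.zeros(grid.shape), grid=grid)
    v = total_blood_volume(img, _bounds())
    assert v["DV"] == 0.0


def test_blood_volume_scale_equivariant():
    rng = np.random.default_rng(0)
    grid = ReconGrid(voxel_um=(10.0, 10.0, 10.0), extent_mm=(0.2, 0.01, 1.0))
    data = 0.05 * rng.random(grid.shape)
    data[5:9, 0, 30:40] = 1.0
    a = total_blood_volume(ReconImage(data=data, grid=grid), _bounds())
    b = total_blood_volume(ReconImage(data=17.0 * data, grid=grid), _bounds())
    assert a == b


def test_blood_volume_empty_mask_raises():
    grid = ReconGrid(voxel_um=(10.0, 10.0, 10.0), extent_mm=(0.2, 0.01, 0.05))
    img = ReconImage(data=np.ones(grid.shape), grid=grid)
    bad = LayerBounds(d_ep_um=200.0, d_sd_um=100.0, d_max_um=400.0)
    with pytest.raises(ValueError, match="dermal"):
        total_blood_volume(img, bad)


# --------------------------------------------------------------------------
# depth-resolved time-to-peak
# --------------------------------------------------------------------------

def _modulated_frames(tp_offsets_s, protocol):
    """Uniform-dermis frames where each depth half has its own peak time."""
    t = protocol.times_min()
    nz, dz = 100, 10.0
    grid = ReconGrid(voxel_um=(10.0, 10.0, dz), extent_mm=(0.1, 0.01, 1.0))
    z = (np.arange(nz) + 0.5) * dz
    b = _bounds()
    mid = (b.d_ep_um + b.d_max_um) / 2.0
    sup = (z >= b.d_ep_um) & (z < mid)
    deep = (z >= mid) & (z < b.d_max_um)
    frames = np.zeros((t.size, 10, 1, nz))
    for mask, off in ((sup, tp_offsets_s[0]), (deep, tp_offsets_s[1])):
        h = HemodynamicParams(mvc_true=0.4, hr_true=0.2, tp_true=1.5,
                              depth_tp_offset_s=off)
        frames[:, :, :, mask] = hemodynamic_modulation(
            h, protocol, t)[:, None, None, None]
    return frames, grid


def test_depth_tp_uniform_offsets_agree():
    frames, grid = _modulated_frames((0.0, 0.0), LONG_PROTOCOL)
    table = depth_resolved_tp(frames, _bounds(), 450.0, LONG_PROTOCOL,
                              grid=grid)
    assert np.ptp(table["tp_min"]) <= 1.0 / 60.0 + 1e-9


def test_depth_tp_detects_deep_lead():
    frames, grid = _modulated_frames((0.0, -15.0), LONG_PROTOCOL)
    table = depth_resolved_tp(frames, _bounds(), 450.0, LONG_PROTOCOL,
                              grid=grid)
    diff_s = (table["tp_min"].iloc[0] - table["tp_min"].iloc[-1]) * 60.0
    assert diff_s == pytest.approx(15.0, abs=1.0 + 1e-9)


def test_depth_tp_single_bin_equals_layer_tp():
    frames, grid = _modulated_frames((0.0, 0.0), LONG_PROTOCOL)
    b = _bounds()
    table = depth_resolved_tp(frames, b, b.d_max_um - b.d_ep_um,
                              LONG_PROTOCOL, grid=grid)
    assert len(table) == 1
    profs = layer_profile(frames, b, LONG_PROTOCOL, layers=("DV",), grid=grid)
    bm = compute_biomarkers(profs["DV"])
    assert table["tp_min"].iloc[0] == pytest.approx(bm.tp_min, abs=1e-9)


def test_depth_tp_oversized_bin_raises():
    frames, grid = _modulated_frames((0.0, 0.0), LONG_PROTOCOL)
    with pytest.raises(ValueError, match="bin"):
        depth_resolved_tp(frames, _bounds(), 2000.0, LONG_PROTOCOL, grid=grid)
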