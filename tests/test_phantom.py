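"""Phantom generator: lesion census, mask algebra, motion ground truth."""

import numpy as np
import pytest

from aoangio import (InfeasiblePhantomError, MotionModel, PhantomSpec,
                     generate_phantom, invert_warp, render_frames,
                     render_structural)
from scipy import ndimage


def test_empty_spec_yields_empty_phantom():
    spec = PhantomSpec(n_vessels=0, n_loops=0, n_s_inflections=0,
                       n_dilations=0, n_microaneurysms=0, seed=1)
    ph = generate_phantom(spec)
    assert ph.segments == []
    assert not ph.vessel_mask.any()
    assert not ph.perfused_mask.any()
    assert not ph.ghost_mask.any()


def test_zero_ghost_fraction_makes_all_vessels_perfused():
    ph = generate_phantom(PhantomSpec(ghost_fraction=0.0, seed=2))
    assert np.array_equal(ph.perfused_mask, ph.vessel_mask)
    assert not ph.ghost_mask.any()


def test_full_ghost_fraction_leaves_structure_without_flow():
    ph = generate_phantom(PhantomSpec(ghost_fraction=1.0, seed=2))
    assert not ph.perfused_mask.any()
    assert ph.vessel_mask.any()
    structural = render_structural(ph)
    assert structural.std() > 0  # structure remains visible


def test_requested_lesion_counts_are_realized():
    ph = generate_phantom(PhantomSpec(seed=1, n_microaneurysms=3, n_loops=2))
    tags = [s.lesion_tag for s in ph.segments]
    assert tags.count("microaneurysm") == 3
    assert tags.count("loop") == 2
    assert tags.count("s_inflection") == 1


@pytest.mark.parametrize("seed", range(20))
def test_mask_partition_over_seeds(seed):
    ph = generate_phantom(PhantomSpec(seed=seed))
    assert np.array_equal(ph.perfused_mask | ph.ghost_mask, ph.vessel_mask)
    assert not (ph.perfused_mask & ph.ghost_mask).any()


def test_ghost_fraction_realized_in_segment_flags():
    ph = generate_phantom(PhantomSpec(seed=6))
    n = len(ph.segments)
    n_ghost = sum(1 for s in ph.segments if not s.perfused)
    assert n_ghost == round(0.2 * n)


def test_centerlines_stay_inside_field():
    ph = generate_phantom(PhantomSpec(seed=9))
    w_um, h_um = ph.spec.field_um
    for s in ph.segments:
        assert (s.centerline[:, 0] >= 0).all()
        assert (s.centerline[:, 0] <= w_um).all()
        assert (s.centerline[:, 1] >= 0).all()
        assert (s.centerline[:, 1] <= h_um).all()


def test_infeasible_field_raises():
    with pytest.raises(InfeasiblePhantomError):
        generate_phantom(PhantomSpec(field_width_px=16, field_height_px=16,
                                     seed=0))


def test_invalid_spec_rejected():
    with pytest.raises(ValueError):
        generate_phantom(PhantomSpec(ghost_fraction=1.5))
    with pytest.raises(ValueError):
        generate_phantom(PhantomSpec(caliber_range_um=(8.0, 4.0)))


def test_seed_determinism_bit_identical():
    a = generate_phantom(PhantomSpec(seed=12))
    b = generate_phantom(PhantomSpec(seed=12))
    assert np.array_equal(a.vessel_mask, b.vessel_mask)
    fa = render_frames(a, 4, MotionModel(seed=3), 0.02, True, seed=4)
    fb = render_frames(b, 4, MotionModel(seed=3), 0.02, True, seed=4)
    assert np.array_equal(fa.frames, fb.frames)
    assert np.array_equal(fa.true_warps, fb.true_warps)


def test_static_scene_renders_identical_frames(default_phantom):
    seq = render_frames(default_phantom, 5, MotionModel(0.0, 0.0, seed=0),
                        noise_sd=0.0, flow_on=False, seed=0)
    for n in range(1, 5):
        assert np.array_equal(seq.frames[n], seq.frames[0])


def test_frame_count_convention(default_phantom):
    seq = render_frames(default_phantom, 12, MotionModel(seed=1), 0.0, True,
                        seed=1)
    assert seq.n_frames == 12


def test_negative_noise_rejected(default_phantom):
    with pytest.raises(ValueError):
        render_frames(default_phantom, 2, MotionModel(seed=0), -0.1, True,
                      seed=0)


def test_flow_variance_confined_to_perfused_lumen(default_phantom,
                                                  still_flow_frames):
    var = still_flow_frames.frames.var(axis=0)
    perf = default_phantom.perfused_mask
    ghost = default_phantom.ghost_mask
    assert var[perf].min() > 0
    assert np.allclose(var[ghost], 0.0)
    assert var[perf].mean() > var[ghost].mean()


@pytest.mark.parametrize("seed", range(10))
def test_flow_contrast_ratio_at_least_threefold(seed):
    """Temporal sd over perfused lumen >= 3x over ghost lumen (no motion,
    default noise), Monte-Carlo over seeds."""
    ph = generate_phantom(PhantomSpec(seed=seed))
    seq = render_frames(ph, 12, MotionModel(0.0, 0.0, seed=seed), 0.02, True,
                        seed=seed + 100)
    sd = seq.frames.std(axis=0)
    assert sd[ph.perfused_mask].mean() >= 3.0 * sd[ph.ghost_mask].mean()


def test_recorded_warps_recover_reference_frame(default_phantom):
    """Warping frame n by the inverse of its recorded warp recovers the
    static scene to within 2% of the dynamic range (interior)."""
    seq = render_frames(default_phantom, 4,
                        MotionModel(jitter_amplitude_um=4.5,
                                    deformation_amplitude_um=3.0, seed=21),
                        noise_sd=0.0, flow_on=False, seed=22)
    ref = render_frames(default_phantom, 1, MotionModel(0.0, 0.0, seed=0),
                        0.0, False, seed=0).frames[0]
    h, w = seq.shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    span = np.ptp(ref)
    for n in range(4):
        v = invert_warp(seq.true_warps[n].astype(float))
        rec = ndimage.map_coordinates(seq.frames[n],
                                      [yy + v[..., 0], xx + v[..., 1]],
                                      order=3, mode="nearest")
        interior = (slice(8, -8), slice(8, -8))
        mae = np.abs(rec[interior] - ref[interior]).mean()
        assert mae < 0.02 * span


def test_structural_contrast_ordering(default_phantom, structural):
    bg = ~default_phantom.vessel_mask
    mean_bg = structural[bg].mean()
    mean_ghost = structural[default_phantom.ghost_mask].mean()
    mean_perf = structural[default_phantom.perfused_mask].mean()
    assert mean_ghost > mean_bg
    assert mean_perf >= mean_ghost


def test_structural_of_empty_phantom_is_flat_background():
    spec = PhantomSpec(n_vessels=0, n_loops=0, n_s_inflections=0,
                       n_dilations=0, n_microaneurysms=0,
                       texture_amplitude=0.0, seed=0)
    img = render_structural(generate_phantom(spec))
    assert np.allclose(img, spec.background_level)
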