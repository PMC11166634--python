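"""Registration: similarity cost, transform resampling, groupwise recovery."""

import numpy as np
import pytest

from aoangio import (BsplineTransform, MotionModel, PhantomSpec,
                     RegistrationConfig, apply_transform,
                     control_point_spacing_px, generate_phantom,
                     register_groupwise, render_frames, similarity_cost,
                     warp_recovery_error)
from aoangio.phantom import FrameSequence


# ---------------------------------------------------------------------------
# similarity cost

def test_cost_of_identical_images_is_minus_one():
    rng = np.random.default_rng(0)
    a = rng.random((32, 32))
    assert similarity_cost(a, a) == pytest.approx(-1.0)


def test_cost_invariant_to_offset_and_gain():
    rng = np.random.default_rng(1)
    a = rng.random((32, 32))
    assert similarity_cost(a, a + 3.7) == pytest.approx(-1.0)
    assert similarity_cost(a, 2.5 * a + 1.0) == pytest.approx(-1.0)


def test_cost_of_independent_noise_is_near_zero():
    rng = np.random.default_rng(2)
    a = rng.random((64, 64))
    b = rng.random((64, 64))
    cost = similarity_cost(a, b)
    assert abs(cost) < 0.1
    # cross-check against the direct Pearson correlation
    r = np.corrcoef(a.ravel(), b.ravel())[0, 1]
    assert cost == pytest.approx(-r, abs=1e-12)


def test_cost_of_constant_image_is_zero_with_warning():
    with pytest.warns(UserWarning):
        c = similarity_cost(np.ones((8, 8)), np.random.default_rng(0)
                            .random((8, 8)))
    assert c == 0.0


# ---------------------------------------------------------------------------
# transforms

def test_spacing_conversion():
    assert control_point_spacing_px(48.0, 1.5) == 32
    assert control_point_spacing_px(48.0, 10.0) == 5
    assert control_point_spacing_px(3.0, 1.5) == 4  # floor at 4 px


def test_identity_transform_is_exact():
    rng = np.random.default_rng(3)
    img = rng.random((48, 48))
    t = BsplineTransform.identity((48, 48), 48.0, 1.5)
    out, valid = apply_transform(img, t)
    assert np.array_equal(out, img)
    assert valid.all()


def test_integer_translation_matches_array_roll():
    rng = np.random.default_rng(4)
    img = rng.random((48, 48))
    t = BsplineTransform.identity((48, 48), 48.0, 1.5)
    t.grid_dx_um += 3 * 1.5  # +3 px in x: output(y,x) = input(y, x+3)
    out, valid = apply_transform(img, t, order=1)
    expected = np.roll(img, -3, axis=1)
    interior = (slice(2, -2), slice(2, 44))
    assert np.allclose(out[interior], expected[interior], atol=1e-9)
    assert not valid[:, -2:].any()  # samples past the right edge flagged


def test_warp_roundtrip_recovers_image():
    rng = np.random.default_rng(5)
    img = np.cumsum(rng.random((64, 64)), axis=0) / 30.0
    t = BsplineTransform.identity((64, 64), 48.0, 1.5)
    t.grid_dx_um += rng.uniform(-2, 2, t.grid_dx_um.shape) * 1.5
    t.grid_dy_um += rng.uniform(-2, 2, t.grid_dy_um.shape) * 1.5
    warped, _ = apply_transform(img, t)
    # numerical inverse on the dense field
    from aoangio import invert_warp
    uy, ux = t.dense_field()
    v = invert_warp(np.stack([uy, ux], axis=-1))
    inv = BsplineTransform.identity((64, 64), 48.0, 1.5)
    # apply the dense inverse directly (not a lattice fit) via map_coordinates
    from scipy import ndimage
    yy, xx = np.mgrid[0:64, 0:64].astype(float)
    back = ndimage.map_coordinates(warped, [yy + v[..., 0], xx + v[..., 1]],
                                   order=3, mode="nearest")
    interior = (slice(6, -6), slice(6, -6))
    span = np.ptp(img)
    assert np.abs(back - img)[interior].mean() < 0.01 * span


def test_transform_domain_mismatch_rejected():
    t = BsplineTransform.identity((32, 32), 48.0, 1.5)
    with pytest.raises(ValueError):
        apply_transform(np.zeros((16, 16)), t)


# ---------------------------------------------------------------------------
# groupwise registration

def test_identical_frames_give_near_identity_transforms(default_phantom):
    base = render_frames(default_phantom, 1, MotionModel(0.0, 0.0, seed=0),
                         0.0, False, seed=0).frames[0]
    seq = FrameSequence(frames=np.repeat(base[None], 4, axis=0),
                        pixel_pitch_um=1.5)
    res = register_groupwise(seq, RegistrationConfig(sampler_seed=0))
    for t in res.transforms:
        assert t.max_displacement_px() < 0.25
    assert np.allclose(res.registered.frames[:, res.validity_mask],
                       seq.frames[:, res.validity_mask], atol=1e-6)


def test_constant_frames_warn_and_return_identity():
    seq = FrameSequence(frames=np.ones((3, 32, 32)), pixel_pitch_um=1.5)
    with pytest.warns(UserWarning):
        res = register_groupwise(seq)
    for t in res.transforms:
        assert t.max_displacement_px() == 0.0


def test_single_frame_rejected():
    seq = FrameSequence(frames=np.zeros((1, 32, 32)) + 1.0,
                        pixel_pitch_um=1.5)
    with pytest.raises(ValueError):
        register_groupwise(seq)


def test_known_rigid_jitter_recovered():
    ph = generate_phantom(PhantomSpec(seed=31))
    seq = render_frames(ph, 8, MotionModel(jitter_amplitude_um=7.5,
                                           deformation_amplitude_um=0.0,
                                           seed=32),
                        noise_sd=0.0, flow_on=False, seed=33)
    res = register_groupwise(seq, RegistrationConfig(sampler_seed=34))
    assert warp_recovery_error(res, seq) < 0.5


def test_smooth_warp_improves_pairwise_correlation():
    ph = generate_phantom(PhantomSpec(seed=41))
    seq = render_frames(ph, 6, MotionModel(jitter_amplitude_um=0.0,
                                           deformation_amplitude_um=4.5,
                                           seed=42),
                        noise_sd=0.0, flow_on=False, seed=43)
    res = register_groupwise(seq, RegistrationConfig(sampler_seed=44))
    v = res.validity_mask
    improved = total = 0
    from aoangio import similarity_cost
    for i in range(6):
        for j in range(i + 1, 6):
            before = similarity_cost(seq.frames[i], seq.frames[j], v)
            after = similarity_cost(res.registered.frames[i],
                                    res.registered.frames[j], v)
            improved += after <= before + 1e-9
            total += 1
    assert improved >= 0.9 * total


def test_cost_trace_non_increasing(registration_result):
    trace = registration_result.cost_trace
    assert all(b <= a + 1e-6 for a, b in zip(trace, trace[1:]))


def test_registration_deterministic_for_fixed_sampler_seed(moving_frames):
    cfg = RegistrationConfig(sampler_seed=77, n_outer_iterations=1,
                             n_resolutions=3, iterations_per_level=16)
    r1 = register_groupwise(moving_frames, cfg)
    r2 = register_groupwise(moving_frames, cfg)
    for a, b in zip(r1.transforms, r2.transforms):
        assert np.array_equal(a.grid_dx_um, b.grid_dx_um)
        assert np.array_equal(a.grid_dy_um, b.grid_dy_um)


def test_static_noisy_stack_not_overfit(default_phantom):
    """Registering a motion-free noisy stack must not invent motion."""
    seq = render_frames(default_phantom, 8, MotionModel(0.0, 0.0, seed=51),
                        noise_sd=0.02, flow_on=False, seed=52)
    res = register_groupwise(seq, RegistrationConfig(sampler_seed=53))
    for t in res.transforms:
        assert t.max_displacement_px() < 1.0
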