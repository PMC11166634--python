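"""Vessel segmentation, perfusion classification, composite rendering."""

import numpy as np
import pytest
from scipy import ndimage

from aoangio import (FusionConfig, PerfusionImage, classify_perfusion,
                     composite_render, ghost_confusion, segment_vessels)


def _uniform_perfusion(shape, value, vessel_mask=None):
    """D = value on vessels (everywhere if no mask), 0 on background."""
    d = np.zeros(shape)
    if vessel_mask is None:
        d += float(value)
    else:
        d[vessel_mask] = float(value)
    return PerfusionImage(decorrelation=d,
                          mean_image=np.ones(shape),
                          noise_mask=np.ones(shape, dtype=bool),
                          threshold_value=0.0, n_pairs_used=1)


def test_constant_image_yields_no_segments():
    seg = segment_vessels(np.full((64, 64), 0.4))
    assert seg.segments == []
    assert not seg.vessel_mask.any()


def test_segmentation_dice_against_ground_truth(default_phantom,
                                                segmentation):
    inter = (segmentation.vessel_mask & default_phantom.vessel_mask).sum()
    dice = 2.0 * inter / (segmentation.vessel_mask.sum()
                          + default_phantom.vessel_mask.sum())
    assert dice >= 0.7


def test_skeleton_recall_of_true_centerlines(default_phantom, segmentation):
    """>= 90% of true centerline pixels lie within 2 px of the skeleton."""
    spec = default_phantom.spec
    h, w = default_phantom.shape
    dist = ndimage.distance_transform_edt(~segmentation.skeleton)
    total = hits = 0
    for s in default_phantom.segments:
        p = np.round(s.centerline[:, ::-1] / spec.pixel_pitch_um).astype(int)
        p = p[(p[:, 0] >= 0) & (p[:, 0] < h) & (p[:, 1] >= 0) & (p[:, 1] < w)]
        d = dist[p[:, 0], p[:, 1]]
        total += len(d)
        hits += int((d <= 2).sum())
    assert hits / total >= 0.9


def test_segments_partition_skeleton(segmentation):
    seen = np.zeros_like(segmentation.skeleton)
    for s in segmentation.segments:
        m = np.zeros_like(seen)
        m[s.pixels[:, 0], s.pixels[:, 1]] = True
        assert not (seen & m).any()  # disjoint
        assert (m <= segmentation.vessel_mask).all()  # skeleton in mask
        seen |= m
    assert np.array_equal(seen, segmentation.skeleton)


def test_full_decorrelation_labels_all_perfused(segmentation):
    perf = _uniform_perfusion(segmentation.vessel_mask.shape, 1.0,
                              segmentation.vessel_mask)
    labels = classify_perfusion(segmentation, perf)
    assert labels.n_non_perfused == 0
    assert all(l.flow_fraction == 1.0 for l in labels.labels)


def test_zero_decorrelation_labels_all_non_perfused(segmentation):
    perf = _uniform_perfusion(segmentation.vessel_mask.shape, 0.0)
    labels = classify_perfusion(segmentation, perf)
    assert labels.n_perfused == 0
    assert all(l.flow_fraction == 0.0 for l in labels.labels)


def test_status_reproduces_flow_fraction_rule(segmentation, perfusion):
    cfg = FusionConfig(perfused_fraction=0.5)
    labels = classify_perfusion(segmentation, perfusion, cfg)
    for l in labels.labels:
        assert l.status == ("perfused" if l.flow_fraction >= 0.5
                            else "non_perfused")


def test_geometry_mismatch_rejected(segmentation):
    perf = _uniform_perfusion((10, 10), 1.0)
    with pytest.raises(ValueError):
        classify_perfusion(segmentation, perf)


def test_monotone_in_flow_threshold(segmentation, perfusion):
    prev = None
    for thr in (0.0, 0.02, 0.1, 0.5, 1.0):
        labels = classify_perfusion(segmentation, perfusion,
                                    FusionConfig(flow_threshold=thr))
        fracs = np.array([l.flow_fraction for l in labels.labels])
        if prev is not None:
            assert np.all(fracs <= prev + 1e-12)
        prev = fracs


def test_monotone_in_perfused_fraction(segmentation, perfusion):
    prev = None
    for pf in (0.0, 0.25, 0.5, 0.75, 1.0):
        labels = classify_perfusion(segmentation, perfusion,
                                    FusionConfig(perfused_fraction=pf))
        if prev is not None:
            assert labels.n_perfused <= prev
        prev = labels.n_perfused


def test_composite_tints(structural, segmentation):
    shape = segmentation.vessel_mask.shape
    all_flow = classify_perfusion(segmentation,
                                  _uniform_perfusion(
                                      shape, 1.0, segmentation.vessel_mask))
    rgb = composite_render(structural, segmentation, all_flow)
    # magenta tint: red and blue dominate green somewhere on vessels
    tinted = (rgb[..., 0] > rgb[..., 1]) & (rgb[..., 2] > rgb[..., 1])
    assert tinted.any()
    assert (tinted <= segmentation.vessel_mask).all()

    no_flow = classify_perfusion(segmentation,
                                 _uniform_perfusion(shape, 0.0))
    rgb2 = composite_render(structural, segmentation, no_flow)
    assert not ((rgb2[..., 0] > rgb2[..., 1] + 1e-9)
                & (rgb2[..., 2] > rgb2[..., 1] + 1e-9)).any()


def test_composite_of_empty_segmentation_is_replicated_grayscale(structural):
    seg = segment_vessels(np.full_like(structural, 0.3))
    labels = classify_perfusion(seg, _uniform_perfusion(structural.shape,
                                                        0.5))
    rgb = composite_render(structural, seg, labels)
    span = np.ptp(structural)
    gray = (structural - structural.min()) / span
    for c in range(3):
        assert np.array_equal(rgb[..., c], gray)


def test_ghost_confusion_counts(segmentation, perfusion, default_phantom):
    labels = classify_perfusion(segmentation, perfusion)
    conf = ghost_confusion(segmentation, labels,
                           default_phantom.perfused_mask,
                           default_phantom.ghost_mask)
    total = conf["tp"] + conf["fp"] + conf["tn"] + conf["fn"] \
        + conf["unmatched"]
    assert total == len(segmentation.segments)
    assert conf["tp"] + conf["fn"] > 0  # the fixture contains ghosts
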