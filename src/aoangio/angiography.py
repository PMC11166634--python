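"""Motion-contrast AO-SLO angiography.

From a registered frame sequence I_1..I_N the per-pixel pairwise
decorrelation

    D(x, y) = 1 - I1*I2 / (0.5*I1^2 + 0.5*I2^2)

is computed for every frame pair in the chosen pair set, averaged into
the perfusion image, and masked: pixels whose value in the mean image
I(x, y) = (1/N) * sum_n I_n falls below an intensity threshold are set
to zero, removing decorrelation produced by noise in dark regions
rather than by flow.  D is bounded in [0, 1] for nonnegative inputs
(equality with 1 only where one frame is zero and the other is not) and
is invariant to a common positive rescaling of the frames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

from .phantom import FrameSequence

__all__ = [
    "AngiographyConfig",
    "PerfusionImage",
    "pairwise_decorrelation",
    "mean_image",
    "perfusion_map",
]


@dataclass(frozen=True)
class AngiographyConfig:
    """Pairing and noise-masking policy for the perfusion map.

    ``pair_policy``: "consecutive" averages the N-1 temporally adjacent
    pairs (the usual motion-contrast construction); "all_pairs" averages
    all N(N-1)/2 pairs.  ``threshold_policy``: "quantile" (threshold at
    the ``threshold_q`` quantile of the mean image, scale-free),
    "otsu", or "absolute" (use ``threshold_value``).
    """

    pair_policy: str = "consecutive"
    threshold_policy: str = "quantile"
    threshold_q: float = 0.10
    threshold_value: float = 0.0
    restrict_to_validity: bool = True

    def validate(self) -> None:
        if self.pair_policy not in ("consecutive", "all_pairs"):
            raise ValueError("pair_policy must be consecutive or all_pairs")
        if self.threshold_policy not in ("quantile", "otsu", "absolute"):
            raise ValueError("unknown threshold_policy")
        if self.threshold_policy == "quantile" and not (
                0.0 < self.threshold_q < 1.0):
            raise ValueError("threshold_q must lie in (0, 1)")
        if self.threshold_policy == "absolute" and self.threshold_value < 0:
            raise ValueError("absolute threshold must be nonnegative")


@dataclass
class PerfusionImage:
    decorrelation: np.ndarray
    mean_image: np.ndarray
    noise_mask: np.ndarray
    threshold_value: float
    n_pairs_used: int

    def __post_init__(self) -> None:
        d = self.decorrelation
        if np.any(d < 0) or np.any(d > 1):
            raise ValueError("decorrelation must lie in [0, 1]")
        if np.any(self.mean_image < 0):
            raise ValueError("mean image must be nonnegative")


def pairwise_decorrelation(i1: np.ndarray, i2: np.ndarray) -> np.ndarray:
    """Per-pixel decorrelation between two nonnegative frames.

    Pixels where both frames are zero carry no signal and return 0 by
    convention (absence of signal is not evidence of flow).
    """
    i1 = np.asarray(i1, dtype=float)
    i2 = np.asarray(i2, dtype=float)
    if i1.shape != i2.shape:
        raise ValueError("frames must share a shape")
    if np.any(i1 < 0):
        raise ValueError("negative intensities in i1")
    if np.any(i2 < 0):
        raise ValueError("negative intensities in i2")
    denom = 0.5 * i1 * i1 + 0.5 * i2 * i2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 - (i1 * i2) / denom
    d[denom == 0] = 0.0
    return np.clip(d, 0.0, 1.0)


def mean_image(frames: FrameSequence) -> np.ndarray:
    """Arithmetic per-pixel mean over all frames."""
    if frames.n_frames < 1:
        raise ValueError("empty frame sequence")
    return frames.frames.mean(axis=0)


def _pair_indices(n: int, policy: str) -> list[tuple[int, int]]:
    if policy == "consecutive":
        return [(i, i + 1) for i in range(n - 1)]
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


def perfusion_map(frames: FrameSequence,
                  config: Optional[AngiographyConfig] = None
                  ) -> PerfusionImage:
    """Averaged pairwise decorrelation with intensity-threshold masking.

    The threshold statistic is computed within the registration validity
    mask when the sequence carries one (and ``restrict_to_validity``);
    outside it D is set to zero as well, since averages are undefined
    there.
    """
    if config is None:
        config = AngiographyConfig()
    config.validate()
    if frames.n_frames < 2:
        raise ValueError("perfusion map needs at least 2 frames")
    stack = frames.frames
    pairs = _pair_indices(frames.n_frames, config.pair_policy)
    d = np.zeros(frames.shape, dtype=float)
    for i, j in pairs:
        d += pairwise_decorrelation(stack[i], stack[j])
    d /= len(pairs)

    mean_img = mean_image(frames)
    validity = None
    if config.restrict_to_validity and frames.validity_mask is not None:
        validity = frames.validity_mask.astype(bool)

    domain = validity if validity is not None else np.ones(frames.shape,
                                                           dtype=bool)
    vals = mean_img[domain]
    if not np.any(vals > 0):
        warnings.warn("all-zero frame stack: perfusion map is identically 0")
        thr = 0.0
    elif config.threshold_policy == "quantile":
        thr = float(np.quantile(vals, config.threshold_q))
    elif config.threshold_policy == "otsu":
        thr = float(threshold_otsu(vals))
    else:
        thr = float(config.threshold_value)

    noise_mask = (mean_img >= thr) & domain
    d[~noise_mask] = 0.0
    return PerfusionImage(decorrelation=d, mean_image=mean_img,
                          noise_mask=noise_mask, threshold_value=thr,
                          n_pairs_used=len(pairs))
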