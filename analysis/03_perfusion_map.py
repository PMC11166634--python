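#!/usr/bin/env python
"""Compute a perfusion image end to end and test its contrast ordering.

Runs simulate -> register -> angiography for one seed and reports the
mean decorrelation inside perfused lumens, ghost lumens, and background:
motion contrast should rank them in exactly that order.
"""

import json
from pathlib import Path

from aoangio import (MotionModel, PhantomSpec, RegistrationConfig,
                     generate_phantom, perfusion_map, register_groupwise,
                     render_frames)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    phantom = generate_phantom(PhantomSpec(seed=3))
    frames = render_frames(phantom, 12, MotionModel(seed=1012), 0.02, True,
                           seed=2006)
    result = register_groupwise(frames, RegistrationConfig(sampler_seed=3004))
    pm = perfusion_map(result.registered)
    background = ~phantom.vessel_mask & pm.noise_mask
    summary = {
        "n_frames": frames.n_frames,
        "n_pairs_used": pm.n_pairs_used,
        "noise_threshold": round(float(pm.threshold_value), 4),
        "mean_D_perfused": round(
            float(pm.decorrelation[phantom.perfused_mask].mean()), 4),
        "mean_D_ghost": round(
            float(pm.decorrelation[phantom.ghost_mask].mean()), 4),
        "mean_D_background": round(
            float(pm.decorrelation[background].mean()), 4),
    }
    with open(OUT / "perfusion_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    print(json.dumps(summary, indent=2))
    ratio = summary["mean_D_perfused"] / max(summary["mean_D_ghost"], 1e-9)
    print(f"perfused lumens decorrelate {ratio:.1f}x more than ghost "
          f"lumens; ghost D sits at the noise floor "
          f"(background {summary['mean_D_background']})")


if __name__ == "__main__":
    main()
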