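#!/usr/bin/env python
"""Segment the simulated video into 100-point midlines and compute posture
outputs: the bending kymograph (CSV + PNG), the eleven 3-point angles, the
dorso-ventral ratio of the 2nd angle, body length/centroid traces, and an
eigenworm basis fitted to the recording.  Reads results/simulation/, writes
results/posture/."""

from pathlib import Path

import numpy as np
import pandas as pd

from undulalab import io as uio
from undulalab import posture
from undulalab.segmentation import segment_video

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "results" / "simulation"
STACKS = ROOT / "scratch" / "simulation"
OUT = ROOT / "results" / "posture"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    video_tif = STACKS / "video.tif"
    if not video_tif.exists():
        raise SystemExit("run analysis/01_simulate_locomotion.py first")
    frames = uio.load_stack(video_tif)
    params = uio.load_params(SIM / "params.json")
    midlines = segment_video(frames, fps=params.fps)
    n_ok = sum(m.valid for m in midlines)
    print(f"segmented {n_ok}/{len(midlines)} frames successfully")

    uio.midlines_to_frame(midlines).to_csv(OUT / "midlines.csv", index=False)
    uio.midline_qc_frame(midlines).to_csv(OUT / "midline_qc.csv", index=False)

    kymo = posture.two_point_kymograph(midlines, vulva_side="dorsal_up")
    pd.DataFrame(kymo).to_csv(OUT / "kymograph.csv", index=False)
    uio.save_kymograph_png(OUT / "kymograph.png", kymo, params.fps)

    angles = posture.three_point_series(midlines, vulva_side="dorsal_up")
    pd.DataFrame(angles, columns=[f"angle_{i}" for i in range(1, 12)]).to_csv(
        OUT / "three_point_angles.csv", index=False)
    ratio = posture.dorsoventral_ratio(angles[:, 1])
    print(f"dorsal/ventral ratio of the 2nd 3-point angle: {ratio:.2f} "
          "(> 1: dorsal bias, as configured)")

    dd = posture.differential_bending(angles, fps=params.fps,
                                      protocol={"dark": (0.0, 8.0),
                                                "light": (8.0, 14.0)})
    print(f"differential bending light-dark: anterior {dd.anterior:+.3f}, "
          f"posterior {dd.posterior:+.3f} deg/frame")

    metrics = posture.body_metrics(midlines, mm_per_px=0.005, fps=params.fps)
    metrics.to_csv(OUT / "body_metrics.csv", index=False)
    basis = posture.fit_eigenworms(kymo[~np.isnan(kymo).any(axis=1)], k=4)
    pd.DataFrame(basis.components).to_csv(OUT / "eigenworms.csv", index=False)
    print("eigenworm explained variance:",
          np.round(basis.explained_variance, 3))


if __name__ == "__main__":
    main()
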