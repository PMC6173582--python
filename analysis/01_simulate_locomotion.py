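#!/usr/bin/env python
"""Generate the baseline crawling dataset: a worm undulating at 0.5 Hz with an
optogenetic-style perturbation epoch (deeper bends, dorsal bias, slowing,
contraction) in the middle of the recording.  Writes the rendered video and
ground-truth tables under results/simulation/."""

from pathlib import Path

from undulalab import io as uio
from undulalab import synthetic as syn

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "simulation"
STACKS = ROOT / "scratch" / "simulation"     # large binary output


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    STACKS.mkdir(parents=True, exist_ok=True)
    epoch = syn.PerturbationEpoch(t_start=8.0, t_end=14.0, amplitude=1.5,
                                  bias=1.0, speed=0.5, length=0.93)
    params = syn.LocomotionParams(duration_s=20.0, fps=25.0, wave_freq_hz=0.5,
                                  wave_amplitude_rad=0.3, dorsal_bias_rad=0.3,
                                  speed_mm_s=0.1, perturbation_epochs=(epoch,),
                                  seed=0)
    truth = syn.generate_locomotion(params)
    video = syn.render_worm_video(truth, syn.RenderParams(noise_sd=3.0, seed=0),
                                  protocol={"dark": (0.0, 8.0),
                                            "light": (8.0, 14.0)})
    uio.save_stack(STACKS / "video.tif", video.frames)
    uio.truth_track_frame(truth).to_csv(OUT / "truth_track.csv", index=False)
    uio.truth_midline_frame(truth).to_csv(OUT / "truth_midline.csv", index=False)
    uio.save_params(OUT / "params.json", params)
    print(f"wrote {truth.n_frames} frames at {params.fps} fps to {OUT}")
    print("perturbation epoch 8-14 s: amplitude x1.5, speed x0.5, length x0.93")


if __name__ == "__main__":
    main()
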