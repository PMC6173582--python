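#!/usr/bin/env python
"""Track-level quality control of the simulated recording: speed from the
centroid trace, the 1.25 mm/s and 25%-length filters, the 15% exclusion rule,
and before/during-illumination window statistics.  Reads
results/simulation/truth_track.csv, writes results/track_qc/."""

import json
from pathlib import Path

import pandas as pd

from undulalab.track_qc import filter_track, window_stats

SIM = Path(__file__).resolve().parents[1] / "results" / "simulation"
OUT = Path(__file__).resolve().parents[1] / "results" / "track_qc"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    track = pd.read_csv(SIM / "truth_track.csv")
    filtered, report = filter_track(track)
    filtered.to_csv(OUT / "track_filtered.csv", index=False)
    (OUT / "qc_report.json").write_text(json.dumps({
        "n_frames": report.n_frames, "n_discarded": report.n_discarded,
        "discard_fraction": report.discard_fraction,
        "video_excluded": report.video_excluded}, indent=2))
    print(f"discarded {report.n_discarded}/{report.n_frames} frames; "
          f"excluded: {report.video_excluded}")

    stats = window_stats(filtered["time_s"].to_numpy(),
                         filtered["speed_mm_s"].to_numpy(),
                         {"before_light": (3.0, 8.0),
                          "during_light": (8.0, 13.0)},
                         valid=filtered["valid"].to_numpy())
    stats.to_csv(OUT / "speed_windows.csv", index=False)
    print(stats.to_string(index=False))
    print("(the perturbation epoch halves the crawl speed)")


if __name__ == "__main__":
    main()
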