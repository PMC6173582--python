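#!/usr/bin/env python
"""Dual-neuron tracking and event-wise cross-correlation: AS6/AS7 spots are
tracked through a stage-tracked movie, activity is read out with the
18 px-radius ROI + 5 px donut background, the AS6-vulva-AS7 bending angle is
measured, and per-bending-event cross-correlograms are aggregated.  The
generator's 2 s AS6 activity lead is the recovery target.  Writes
results/neuron_correlation/."""

import json
from pathlib import Path

from undulalab import io as uio
from undulalab.scenarios import neuron_correlation_scenario

OUT = Path(__file__).resolve().parents[1] / "results" / "neuron_correlation"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    r = neuron_correlation_scenario(seed=0, activity_lead_s=2.0)
    print(f"tracked {len(r.events)} bending events "
          f"(dropped {r.events.n_dropped} short ones)")
    summary = {}
    for name, cset in (("as6_vs_vulva_angle", r.as6_vs_angle),
                       ("as7_vs_vulva_angle", r.as7_vs_angle),
                       ("as6_vs_as7", r.as6_vs_as7)):
        uio.correlogram_frame(cset).to_csv(OUT / f"correlogram_{name}.csv",
                                           index=False)
        summary[name] = {"peak_value": cset.peak_value,
                         "peak_lag_s": cset.peak_lag_s,
                         "n_events": cset.n_events}
        print(f"{name}: peak {cset.peak_value:+.3f} at "
              f"{cset.peak_lag_s:+.1f} s over {cset.n_events} events")
    (OUT / "peak_summary.json").write_text(json.dumps(summary, indent=2))
    print("configured AS6 activity lead was +2.0 s; AS7 coincides (0 s)")


if __name__ == "__main__":
    main()
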