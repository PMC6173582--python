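#!/usr/bin/env python
"""Synaptic-output budget of the AS motor neurons from the transcribed
connectome counts: per-target fractions and whole-number percents.  Writes
results/connectome/."""

from pathlib import Path

from undulalab.connectome import load_synapse_table, synapse_fractions

OUT = Path(__file__).resolve().parents[1] / "results" / "connectome"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = load_synapse_table()
    out = synapse_fractions(table, "AS")
    out.to_csv(OUT / "as_output_fractions.csv", index=False)
    print(out.to_string(index=False))
    total = int(out["count"].sum())
    print(f"\nAS neurons: {total} documented chemical synapses; "
          "dorsal muscle and inhibitory VD neurons take near-equal shares — "
          "the anatomical basis of their dorsal-biasing, ventrally "
          "disinhibiting output.")


if __name__ == "__main__":
    main()
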