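"""Synaptic-output fractions from a transcribed synapse-count table.

The bundled table transcribes connectome counts for the ventral-nerve-cord
motor circuit: notably the AS motor neurons' 144 documented chemical synapses,
of which 68 target dorsal body-wall muscle and 66 target the inhibitory
(GABAergic, ventrally innervating) VD motor neurons — the anatomical
asymmetry that makes AS neurons dorsal-biased.  Counts whose targets are not
itemized in the source are entered under ``unassigned`` so per-source totals
match the documented denominators.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = ["load_synapse_table", "synapse_fractions", "round_half_up"]


def round_half_up(x) -> np.ndarray | int:
    """Round to nearest integer with exact halves going up (47.5 -> 48)."""
    out = np.floor(np.asarray(x, dtype=float) + 0.5).astype(int)
    return out if out.ndim else int(out)


def load_synapse_table(path: str | None = None) -> pd.DataFrame:
    """Load a (source, target, count[, kind]) synapse table; default bundled."""
    if path is None:
        with resources.files("undulalab.data").joinpath(
                "synapse_counts.csv").open() as fh:
            table = pd.read_csv(fh)
    else:
        table = pd.read_csv(path)
    if not {"source", "target", "count"}.issubset(table.columns):
        raise InputError("synapse table needs source,target,count columns")
    if (table["count"] < 0).any():
        raise InputError("synapse counts must be non-negative")
    if "kind" not in table.columns:
        table["kind"] = "chemical"
    dup = table.duplicated(["source", "target", "kind"])
    if dup.any():
        raise InputError("duplicate (source, target) rows in synapse table")
    return table


def synapse_fractions(table: pd.DataFrame, source: str,
                      kind: str = "chemical") -> pd.DataFrame:
    """Per-target output count, fraction and whole-number percent of a source.

    Fractions are count over the source's total outgoing count; percents are
    half-up rounded to the nearest whole number.
    """
    sub = table[(table["source"] == source) & (table["kind"] == kind)]
    if sub.empty:
        raise InputError(f"unknown source '{source}'")
    total = int(sub["count"].sum())
    if total == 0:
        raise InputError(f"source '{source}' has zero outgoing synapses")
    out = sub[["target", "count"]].copy().reset_index(drop=True)
    out["fraction"] = out["count"] / total
    out["percent"] = round_half_up(100.0 * out["fraction"])
    return out
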