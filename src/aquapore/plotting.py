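"""Minimal matplotlib views of traces and group permeabilities."""

from __future__ import annotations

from typing import Iterable, Sequence

import matplotlib.pyplot as plt
import numpy as np

from .swelling import PermeabilityEstimate, SwellingTrace

__all__ = ["plot_traces", "plot_group_permeabilities"]


def plot_traces(traces: Iterable[SwellingTrace], ax=None):
    """Relative volume against time, one line per oocyte, colored by group."""
    if ax is None:
        _, ax = plt.subplots()
    colors = {"expressing": "tab:blue", "control": "tab:gray"}
    seen = set()
    for tr in traces:
        label = tr.group if tr.group not in seen else None
        seen.add(tr.group)
        ax.plot(tr.times, tr.rel_volume, color=colors.get(tr.group, "tab:green"),
                alpha=0.6, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("relative volume V/V0")
    ax.legend()
    return ax


def plot_group_permeabilities(
    groups: dict[str, Sequence[PermeabilityEstimate]], ax=None
):
    """Mean ± SEM bar per group of permeability estimates."""
    if ax is None:
        _, ax = plt.subplots()
    names = list(groups)
    means = [np.mean([e.value for e in groups[n]]) for n in names]
    sems = [
        np.std([e.value for e in groups[n]], ddof=1) / np.sqrt(len(groups[n]))
        for n in names
    ]
    ax.bar(names, means, yerr=sems, capsize=4, color="tab:blue", alpha=0.8)
    kind = {e.kind for n in names for e in groups[n]}
    ax.set_ylabel(f"{'/'.join(sorted(kind))} (cm/s)")
    return ax
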