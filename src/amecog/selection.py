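"""Selection of speech-responsive electrode sites.

A site counts as active in a task when a bootstrap t-test finds its
high-gamma responses sampled during stimulus/production windows larger
than responses sampled during pre-stimulus silence (p < 0.01 by default).
Sites active during both listening and speaking are the intersection set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ElectrodeTable, EventTable, HighGammaSeries, REGIONS, TASKS
from .errors import WindowingError
from .stats import bootstrap_ttest

__all__ = ["SiteSelection", "select_sites", "summarize_by_region"]


@dataclass
class SiteSelection:
    """Per-electrode task p-values and activity flags."""

    table: pd.DataFrame  # columns: id, p_listen, p_speak, active_listen, ...

    def active(self, which: str) -> list[str]:
        return list(self.table.loc[self.table[f"active_{which}"], "id"])


def _window_samples(hg, events, window, rng, samples_per_trial):
    """One (or more) random high-gamma samples per trial from ``window``."""
    fs = hg.fs_out
    n = hg.values.shape[1]
    cols = []
    for onset in events.df["onset_s"]:
        a = int(round((onset + window[0]) * fs))
        b = int(round((onset + window[1]) * fs))
        if a < 0 or b > n or b <= a:
            raise WindowingError(f"window {window} around {onset} s is out of range")
        cols.append(rng.integers(a, b, size=samples_per_trial))
    idx = np.concatenate(cols)
    return hg.values[:, idx]  # (channels, trials * samples_per_trial)


def select_sites(
    hg: HighGammaSeries,
    events: EventTable,
    alpha: float = 0.01,
    stim_window: tuple[float, float] = (0.0, 0.5),
    base_window: tuple[float, float] = (-0.5, 0.0),
    samples_per_trial: int = 1,
    n_boot: int = 2000,
    seed: int | None = 0,
) -> SiteSelection:
    """Flag electrodes responsive during listening, speaking, and both.

    For each electrode and task, responses randomly sampled over time
    inside the post-onset window are compared with samples from the
    pre-stimulus silent window by a one-sided bootstrap t-test; a site is
    active at p < ``alpha``. ``active_both`` is the intersection of the two
    task flags.
    """
    rng = np.random.default_rng(seed)
    pvals = {}
    for task in TASKS:
        ev = events.for_task(task)
        if len(ev) == 0:
            pvals[task] = np.full(hg.n_channels, np.nan)
            continue
        stim = _window_samples(hg, ev, stim_window, rng, samples_per_trial)
        base = _window_samples(hg, ev, base_window, rng, samples_per_trial)
        p = np.empty(hg.n_channels)
        for c in range(hg.n_channels):
            if np.isnan(hg.values[c]).any():
                p[c] = np.nan  # rejected channel
                continue
            p[c] = bootstrap_ttest(
                stim[c], base[c], n_boot=n_boot,
                seed=rng.integers(2**31), alternative="greater",
            )
        pvals[task] = p

    def _flag(p):
        if alpha >= 1.0:  # degenerate threshold: every testable site is active
            return np.isfinite(p)
        return p < alpha

    listen = _flag(pvals["listen"])
    speak = _flag(pvals["speak"])
    table = pd.DataFrame(
        {
            "id": list(hg.channel_ids),
            "p_listen": pvals["listen"],
            "p_speak": pvals["speak"],
            "active_listen": listen,
            "active_speak": speak,
            "active_both": listen & speak,
        }
    )
    return SiteSelection(table=table)


def summarize_by_region(sel: SiteSelection, electrodes: ElectrodeTable) -> pd.DataFrame:
    """Counts of active sites per region x {listen, speak, both}."""
    merged = sel.table.merge(
        electrodes.df[["id", "region"]], on="id", how="inner"
    )
    out = []
    for region in REGIONS:
        sub = merged[merged["region"] == region]
        if len(sub) == 0:
            continue
        out.append(
            {
                "region": region,
                "n_sites": len(sub),
                "listen": int(sub["active_listen"].sum()),
                "speak": int(sub["active_speak"].sum()),
                "both": int(sub["active_both"].sum()),
            }
        )
    return pd.DataFrame(out, columns=["region", "n_sites", "listen", "speak", "both"])
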