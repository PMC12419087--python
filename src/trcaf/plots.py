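"""Optional figures; every plot draws only from objects the tables persist."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .atac import SECallResult
from .survival import KMCurve

__all__ = ["plot_km", "plot_elbow"]


def _step_xy(km: KMCurve):
    xs, ys = [0.0], [1.0]
    for t, s in zip(km.event_times, km.survival):
        xs += [t, t]
        ys += [ys[-1], s]
    return xs, ys


def plot_km(km_high: KMCurve, km_low: KMCurve, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    for km, label in ((km_high, "signature high"), (km_low, "signature low")):
        xs, ys = _step_xy(km)
        ax.plot(xs, ys, label=label)
    ax.set_xlabel("time")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_elbow(result: SECallResult, path) -> None:
    fig, ax = plt.subplots(figsize=(4, 3))
    t = result.table
    for label, color in (("TE", "tab:gray"), ("SE", "tab:red")):
        sub = t[t["label"] == label]
        ax.scatter(sub["x"], sub["y"], s=12, c=color, label=label)
    if result.inflection is not None:
        ax.axhline(result.inflection[1], ls="--", lw=0.8, c="k")
    ax.set_xlabel("scaled gene rank")
    ax.set_ylabel("scaled qualifying-peak count")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
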