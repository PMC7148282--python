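"""Figures mirroring the protocol's standard visual outputs.

- histogram of each participant's best cross-correlation;
- Bland-Altman plots with the a-priori boundary (green) and the empirical
  limits of agreement (red);
- per-device task line plots (thin participant lines, red mean +- SE);
- difference plots with the zero axis (black) and +- reference-effect
  boundaries (green).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def signal_histogram(results, path: Path) -> None:
    rs = [r.best_r for r in results.signal.per_participant]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(rs, bins=np.linspace(-1, 1, 21), color="steelblue", edgecolor="k")
    ax.axvline(results.signal.threshold, color="red", ls="--",
               label=f"criterion {results.signal.threshold:.2f}")
    ax.set_xlabel("best cross-correlation")
    ax.set_ylabel("participants")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def bland_altman_plot(entry, path: Path) -> None:
    res, boundary = entry["result"], entry["boundary"]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.scatter(res.pairs["mean"], res.pairs["diff"], s=18, color="k")
    for y, c, lbl in (
        (boundary.boundary, "green", "a-priori boundary"),
        (-boundary.boundary, "green", None),
        (res.loa_high, "red", "limits of agreement"),
        (res.loa_low, "red", None),
        (res.mean_diff, "gray", "mean difference"),
    ):
        ax.axhline(y, color=c, ls="--", lw=1, label=lbl)
    ax.set_xlabel(f"mean of devices ({res.parameter.value})")
    ax.set_ylabel("wearable - reference")
    ax.set_title(
        f"{res.parameter.value}: {res.pct_within_boundary:.0f}% within boundary"
    )
    ax.legend(frameon=False, fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def task_lines(summaries: dict, channel: str, device: str, path: Path,
               yscale: str | None = None) -> None:
    """Thin per-participant lines with the cohort mean +- SE in red."""
    tasks = list(summaries)
    participants: set[str] = set()
    for t in tasks:
        participants |= set(summaries[t][device].per_participant)
    fig, ax = plt.subplots(figsize=(max(5, 0.4 * len(tasks)), 3.5))
    xs = np.arange(len(tasks))
    for pid in sorted(participants):
        ys = [summaries[t][device].per_participant.get(pid, np.nan) for t in tasks]
        ax.plot(xs, ys, color="lightblue", lw=0.7, alpha=0.7)
    means = [summaries[t][device].mean for t in tasks]
    ses = [summaries[t][device].se for t in tasks]
    ok = [i for i, m in enumerate(means) if m is not None]
    ax.errorbar(
        [xs[i] for i in ok],
        [means[i] for i in ok],
        yerr=[ses[i] or 0 for i in ok],
        color="red", lw=1.5, capsize=2,
    )
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs, tasks, rotation=60, fontsize=6)
    ax.set_ylabel(f"{channel} ({device})")
    if yscale:
        ax.set_yscale(yscale)
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def difference_lines(comparisons: dict, channel: str, path: Path) -> None:
    tasks = list(comparisons)
    fig, ax = plt.subplots(figsize=(max(5, 0.4 * len(tasks)), 3.5))
    xs = np.arange(len(tasks))
    participants: set[str] = set()
    for t in tasks:
        participants |= set(comparisons[t].diffs)
    for pid in sorted(participants):
        ys = [comparisons[t].diffs.get(pid, np.nan) for t in tasks]
        ax.plot(xs, ys, color="lightblue", lw=0.7, alpha=0.7)
    ok = [i for i, t in enumerate(tasks) if comparisons[t].diff_mean is not None]
    ax.errorbar(
        [xs[i] for i in ok],
        [comparisons[tasks[i]].diff_mean for i in ok],
        yerr=[comparisons[tasks[i]].diff_se or 0 for i in ok],
        color="red", lw=1.5, capsize=2,
    )
    refs = [comparisons[t].ref_effect for t in tasks]
    ax.plot(xs, refs, color="green", ls="--", lw=1)
    ax.plot(xs, [-r for r in refs], color="green", ls="--", lw=1)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_xticks(xs, tasks, rotation=60, fontsize=6)
    ax.set_ylabel(f"wearable - reference ({channel})")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)


def render_all(results, out: Path) -> list[Path]:
    written: list[Path] = []
    if results.signal is not None:
        p = out / "signal_histogram.png"
        signal_histogram(results, p)
        written.append(p)
    for name, entry in results.parameters.items():
        p = out / f"bland_altman_{name}.png"
        bland_altman_plot(entry, p)
        written.append(p)
    for channel, summaries in results.event_summaries.items():
        if not summaries:
            continue
        yscale = None
        for device in ("rd", "wd"):
            p = out / f"tasks_{channel}_{device}.png"
            task_lines(summaries, channel, device, p, yscale=yscale)
            written.append(p)
        comps = results.event_comparisons.get(channel, {})
        if comps:
            p = out / f"differences_{channel}.png"
            difference_lines(comps, channel, p)
            written.append(p)
    return written
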