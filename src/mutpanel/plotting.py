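"""Optional static plots (KM and ROC) to SVG/PNG.

matplotlib is an optional dependency (the ``plot`` extra); it is imported
lazily so the rest of the package works without it.
"""

from __future__ import annotations

from typing import Sequence

from .survival_eval import RocResult, km_estimate


def plot_km(
    groups: dict[str, tuple[Sequence[float], Sequence[int]]],
    out_path: str,
    title: str = "Kaplan-Meier",
) -> None:
    """Step-plot one KM curve per group (label -> (times, events))."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, (times, events) in groups.items():
        curve = km_estimate(times, events)
        xs = [0.0, *curve.times]
        ys = [1.0, *curve.survival_prob]
        ax.step(xs, ys, where="post", label=f"{label} (median {curve.median_display})")
    ax.set_xlabel("months")
    ax.set_ylabel("survival probability")
    ax.set_ylim(0, 1.02)
    ax.legend(frameon=False)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)


def plot_roc(roc: RocResult, out_path: str, title: str = "ROC") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.plot(1 - roc.specificity, roc.sensitivity, drawstyle="steps-post")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_title(f"{title} (AUC = {roc.auc:.2f})")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
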