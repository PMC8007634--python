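"""Optional figures: per-subject psychometric curves in the three-law layout."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.special import expit

from .kinematics import MotionLaw
from .psychometrics import fit_psychometric

LAW_COLORS = {
    MotionLaw.CONST_TANGENTIAL.value: "tab:blue",
    MotionLaw.CONST_VERTICAL.value: "tab:orange",
    MotionLaw.GRAVITATIONAL.value: "tab:red",
}


def plot_psychometric_curves(trials, path: str | Path, max_subjects: int = 16):
    """Grid of per-subject psychometric functions, one curve per law."""
    sub = trials[trials["condition_id"].isin(range(1, 8))]
    subjects = sorted(sub["subject_id"].unique())[:max_subjects]
    ncol = 5
    nrow = int(np.ceil(len(subjects) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3 * ncol, 2.4 * nrow),
                             sharex=True, sharey=True, squeeze=False)
    grid = np.linspace(0.65, 1.35, 200)
    for ax, sid in zip(axes.ravel(), subjects):
        for law_val, grp in sub[sub["subject_id"] == sid].groupby("law"):
            color = LAW_COLORS[law_val]
            props = grp.groupby("D_comp")["comparison_longer"].mean()
            ax.plot(props.index, props.values, "o", ms=3, color=color)
            f = fit_psychometric(grp)
            if f.converged:
                ax.plot(grid, expit(f.eta0 + f.eta1 * grid), color=color, lw=1)
        ax.axvline(1.0, color="gray", lw=0.6)
        ax.set_title(str(sid), fontsize=8)
    for ax in axes.ravel()[len(subjects):]:
        ax.axis("off")
    fig.supxlabel("comparison duration (s)")
    fig.supylabel("P(comparison judged longer)")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
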