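"""Stage-by-group line plots of the hypnotic-depth measures."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .stages import STAGE_LABELS

MEASURE_LABELS = {
    "bis": "BIS (surrogate)",
    "alpha_power": "Alpha Power (uV$^2$)",
    "lzc": "LZc",
    "pe": "PE",
    "total_power": "Total Power (uV$^2$)",
    "sef95": "SEF95 (Hz)",
}


def ci95_halfwidth(values) -> float:
    """Half-width of the t-based 95% confidence interval of the mean."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        return np.nan
    return float(sps.t.ppf(0.975, n - 1) * v.std(ddof=1) / np.sqrt(n))


def stage_line_plot(stage_table, measures, out_path=None):
    """One panel per measure: group means across stages with 95% CI bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    measures = [m for m in measures if m in set(stage_table["measure"])]
    if not measures:
        raise ValueError("no requested measure present in the stage table")
    ncol = 2 if len(measures) > 1 else 1
    nrow = int(np.ceil(len(measures) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(5.0 * ncol, 3.4 * nrow),
                             squeeze=False)
    xs = np.arange(len(STAGE_LABELS))
    for ax, measure in zip(axes.ravel(), measures):
        sub = stage_table[stage_table["measure"] == measure]
        for group, marker in (("young", "o"), ("elderly", "s")):
            means, errs = [], []
            for stage in STAGE_LABELS:
                vals = sub.loc[(sub["age_group"] == group)
                               & (sub["stage"] == stage), "value"]
                means.append(vals.mean())
                errs.append(ci95_halfwidth(vals))
            ax.errorbar(xs, means, yerr=errs, marker=marker, capsize=3,
                        label=group)
        ax.set_xticks(xs, STAGE_LABELS, rotation=30)
        ax.set_ylabel(MEASURE_LABELS.get(measure, measure))
        ax.legend(frameon=False, fontsize=8)
    for ax in axes.ravel()[len(measures):]:
        ax.axis("off")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
    return fig
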