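"""Optional Bland-Altman scatter plot (mean vs difference with LoA lines)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

from .agreement import AgreementResult, PairedSeries, bland_altman

__all__ = ["bland_altman_plot"]


def bland_altman_plot(
    pairs: PairedSeries,
    path: str | Path,
    result: AgreementResult | None = None,
    title: str | None = None,
) -> AgreementResult:
    """Save a Bland-Altman plot for ``pairs`` and return the statistics.

    The x-axis is the pair mean, the y-axis the exam1 - exam2 difference;
    the bold line marks the mean difference and the dashed lines the 95%
    limits of agreement.
    """
    if result is None:
        result = bland_altman(pairs)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(pairs.means, pairs.differences, s=18, alpha=0.7, edgecolor="none")
    ax.axhline(result.mean_diff, color="k", lw=2)
    for limit in (result.loa_lower, result.loa_upper):
        ax.axhline(limit, color="k", lw=1, ls="--")
    ax.set_xlabel("mean of the two exams (dB)")
    ax.set_ylabel("exam 1 − exam 2 (dB)")
    ax.set_title(title or f"Bland–Altman, {pairs.level} (n={result.n})")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return result
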