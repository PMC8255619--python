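"""Export helpers: fit diagnostics JSON, histogram CSVs and fit plots."""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .persi import BimodalFit, IntensityHistogram, bimodal_model


def write_fit_diagnostics(diagnostics: dict[str, dict], path: str | os.PathLike) -> None:
    """Per-subject fit parameters, residuals and reference sizes as JSON."""
    with open(path, "w") as fh:
        json.dump(diagnostics, fh, indent=2, sort_keys=True)


def histogram_fit_frame(hist: IntensityHistogram, fit: BimodalFit) -> pd.DataFrame:
    """Bin centers, observed counts and the two fitted components as columns."""
    x = hist.centers
    low = bimodal_model(x, (fit.amp_low, fit.mu_low, fit.sigma_low, 0.0, fit.mu_high, 1.0))
    high = bimodal_model(x, (0.0, fit.mu_low, 1.0, fit.amp_high, fit.mu_high, fit.sigma_high))
    total = np.asarray(low) + np.asarray(high)
    return pd.DataFrame(
        {
            "intensity": x,
            "count": hist.counts,
            "fit_low": low,
            "fit_high": high,
            "fit_total": total,
        }
    )


def plot_histogram_fit(
    hist: IntensityHistogram,
    fit: BimodalFit,
    path: str | os.PathLike,
    title: str | None = None,
) -> None:
    """White-matter histogram with the two fitted peaks and their sum.

    Lower-peak (reference) component shaded separately from the higher
    (contaminated) component; the dotted line is the bimodal sum.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = histogram_fit_frame(hist, fit)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(
        frame["intensity"],
        frame["count"],
        width=hist.bin_width,
        color="0.85",
        edgecolor="none",
        label="WM voxels",
    )
    ax.fill_between(frame["intensity"], frame["fit_low"], alpha=0.4, label="lower peak (reference)")
    if not fit.unimodal_fallback:
        ax.fill_between(
            frame["intensity"], frame["fit_high"], alpha=0.4, label="higher peak (spill-in)"
        )
    ax.plot(frame["intensity"], frame["fit_total"], "k:", label="bimodal sum")
    ax.set_xlabel("intensity (image units)")
    ax.set_ylabel("voxel count")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
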