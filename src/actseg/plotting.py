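"""Minimal profile plotting with optional experimental-curve overlay."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .analysis import RadialProfile

__all__ = ["plot_profile"]


def plot_profile(
    profile: RadialProfile,
    overlay: str | Path | np.ndarray | None = None,
    label: str | None = None,
    ax=None,
):
    """Plot a radial profile with error bars.

    ``overlay`` may be a two-column (R, value) text file or array — e.g. a
    digitized experimental curve — drawn as open symbols for visual
    comparison (no fitting is performed).
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(
        profile.centers, profile.value, yerr=profile.stderr,
        fmt="o-", ms=3, capsize=2, label=label or profile.kind,
    )
    if overlay is not None:
        data = np.loadtxt(overlay) if isinstance(overlay, (str, Path)) else np.asarray(overlay)
        ax.plot(data[:, 0], data[:, 1], "o", mfc="none", label="overlay")
    ax.set_xlabel("R (effective radial coordinate)")
    ax.set_ylabel(profile.kind)
    ax.legend()
    return ax
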