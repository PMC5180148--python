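"""Basic FI-vs-time figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg", force=False)

import matplotlib.pyplot as plt  # noqa: E402


def plot_fi(results, ax=None, show_data: bool = False):
    """Plot the FI series; with ``show_data`` the raw variables go on top."""
    if show_data and ax is None:
        fig, (ax_data, ax) = plt.subplots(
            2, 1, sharex=False, figsize=(8, 6),
            gridspec_kw={"height_ratios": [1, 1.4]})
        ts = results.model.data
        for j, name in enumerate(ts.variable_names):
            ax_data.plot(ts.time_labels, ts.values[:, j], lw=0.8, label=name)
        if ts.n_variables <= 6:
            ax_data.legend(fontsize=8)
        ax_data.set_ylabel("variables")
    elif ax is None:
        fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(results.time_labels, results.fi, marker=".", color="C3")
    ax.set_xlabel("time (window end)")
    ax.set_ylabel("Fisher information")
    ax.set_ylim(0, 8.4)
    ax.axhline(8, ls=":", color="grey", lw=0.8)
    return ax
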