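"""Spreading-curve plots, with optional overlay of digitized experimental
curves (plain CSV with columns t, r in SI units; overlay only — the package
never fits to such data)."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_spreading(curve, overlay_csv=None, ax=None, label="simulation"):
    """Double-logarithmic contact radius vs time, the standard spreading
    representation.  Returns the matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = np.asarray(curve.times)
    r = np.asarray(curve.contact_radii)
    keep = (t > 0) & (r > 0)
    ax.loglog(t[keep], r[keep] * 1e6, label=label)
    if curve.exponent is not None and curve.fit_window is not None:
        r_final = r[-1]
        lo, hi = (w * r_final for w in curve.fit_window)
        m = keep & (r >= lo) & (r <= hi)
        if m.any():
            t0 = t[m][0]
            ax.loglog(t[m], r[m][0] * 1e6 * (t[m] / t0) ** curve.exponent,
                      "--", label=f"fit: slope {curve.exponent:.2f}")
    if overlay_csv is not None:
        exp = pd.read_csv(overlay_csv)
        tcol, rcol = exp.columns[:2]
        ax.loglog(exp[tcol], exp[rcol] * 1e6, "o", mfc="none",
                  label="experiment")
    ax.set_xlabel("t (s)")
    ax.set_ylabel(r"$r_c$ (µm)")
    ax.legend()
    return ax
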