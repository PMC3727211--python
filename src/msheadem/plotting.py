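"""Small matplotlib helpers for the results objects."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_convergence", "plot_profile", "plot_sar_slice",
           "plot_registration_rmse"]


def _ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt

        _, ax = plt.subplots()
    return ax


def plot_convergence(log, ax=None):
    """Per-period energy-change convergence curve (dB)."""
    ax = _ax(ax)
    ax.plot(log.periods, log.delta_db, marker="o")
    ax.set_xlabel("period")
    ax.set_ylabel("energy change (dB)")
    ax.axhline(-40.0, color="k", ls="--", lw=0.8)
    return ax


def plot_registration_rmse(result, ax=None):
    """Per-level RMSE of a hierarchical registration."""
    ax = _ax(ax)
    ax.plot(result.schedule_mm, result.rmse_mm, marker="s")
    ax.set_xscale("log")
    ax.invert_xaxis()
    ax.set_xlabel("control spacing (mm)")
    ax.set_ylabel("RMSE (mm)")
    return ax


def plot_profile(z_mm, values, ax=None, label=None):
    """|E| along a line (e.g. an electrode profile)."""
    ax = _ax(ax)
    ax.plot(z_mm, values, label=label)
    ax.set_xlabel("position (mm)")
    ax.set_ylabel("|E| (V/m)")
    if label:
        ax.legend()
    return ax


def plot_sar_slice(sar_map, axis: int = 1, index: int | None = None, ax=None,
                   db_floor: float = -30.0):
    """One slice of the raw SAR map in dB relative to its peak."""
    ax = _ax(ax)
    raw = sar_map.raw
    if index is None:
        index = int(np.argmax(raw.max(axis=tuple(a for a in range(3) if a != axis))))
    sl = [slice(None)] * 3
    sl[axis] = index
    img = raw[tuple(sl)]
    peak = img.max()
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(np.where(img > 0, img / max(peak, 1e-300), np.nan))
    m = ax.imshow(db.T, origin="lower", vmin=db_floor, vmax=0.0, cmap="inferno")
    ax.figure.colorbar(m, ax=ax, label="SAR (dB rel. peak)")
    return ax
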