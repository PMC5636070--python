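"""Quick-look plots for recordings, segmentations and stride parameters."""

from __future__ import annotations

import numpy as np

from .io import ImuRecording


def plot_recording(rec: ImuRecording, segments=None, events=None, ax=None):
    """Plot the sagittal gyroscope with optional segment/event overlays.

    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    ax.plot(rec.t, rec.gyr[:, 2], lw=0.8, label="gyr_z (sagittal)")
    if segments:
        for seg in segments:
            color = {"straight": "tab:green", "initiation": "tab:orange", "turning": "tab:red"}[seg.label]
            ax.axvspan(rec.t[seg.start], rec.t[seg.end - 1], alpha=0.15, color=color)
    if events:
        for ev in events:
            ax.axvline(ev.heel_strike_time, color="k", lw=0.6, ls="--")
            ax.axvline(ev.toe_off_time, color="gray", lw=0.6, ls=":")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("angular rate [°/s]")
    ax.legend(loc="upper right", fontsize=8)
    return ax


def plot_stride_trajectory(traj, fs: float, ax=None):
    """Plot the reconstructed sagittal sensor path of one stride."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.plot(traj.position[:, 0], 100 * traj.position[:, 1], lw=1.2)
    ax.set_xlabel("anterior displacement [m]")
    ax.set_ylabel("sensor height [cm]")
    ax.set_title(f"stride length {traj.stride_length:.2f} m, clearance {100*traj.clearance:.1f} cm")
    return ax
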