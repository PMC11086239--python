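"""Three-dimensional phase-trajectory rendering of an extracted FECG.

Each sample is embedded as (cos phi, sin phi, amplitude) where the beat
phase phi advances linearly from 0 to 2*pi between consecutive R-peaks.
A well-extracted signal traces a tight limit ring around the unit circle
that oscillates vertically through each P-QRS-T complex; projecting the
trajectory onto the z axis returns the signal exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

__all__ = ["PhaseTrajectory", "phase_embed", "render_trajectory"]


@dataclass
class PhaseTrajectory:
    points: np.ndarray  # (n, 3): (cos phi, sin phi, amplitude)
    phi: np.ndarray     # unwrapped beat phase, one cycle per RR interval

    def __len__(self) -> int:
        return len(self.points)

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]


def phase_embed(signal: np.ndarray, r_peaks: np.ndarray) -> PhaseTrajectory:
    """Embed a signal on the unit cylinder using R-peaks as phase anchors.

    phi interpolates linearly between consecutive peaks (0 at each peak,
    advancing 2*pi per RR interval) and extends with the edge RR interval
    before the first and after the last peak.
    """
    signal = np.asarray(signal, dtype=np.float64).ravel()
    r_peaks = np.asarray(r_peaks, dtype=np.float64)
    if r_peaks.size < 2:
        raise ValueError("need at least two R-peaks to define a phase")
    if np.any(np.diff(r_peaks) <= 0):
        raise ValueError("R-peaks must be strictly increasing")
    idx = np.arange(len(signal), dtype=np.float64)
    cycles = np.interp(idx, r_peaks, np.arange(len(r_peaks), dtype=np.float64))
    head = idx < r_peaks[0]
    cycles[head] = (idx[head] - r_peaks[0]) / (r_peaks[1] - r_peaks[0])
    tail = idx > r_peaks[-1]
    cycles[tail] = (len(r_peaks) - 1) \
        + (idx[tail] - r_peaks[-1]) / (r_peaks[-1] - r_peaks[-2])
    phi = 2.0 * np.pi * cycles
    points = np.column_stack([np.cos(phi), np.sin(phi), signal])
    return PhaseTrajectory(points=points, phi=phi)


def render_trajectory(traj: PhaseTrajectory, out_path: str | Path,
                      dpi: int = 120) -> Path:
    """Write a 3-D line plot of the trajectory plus the unit circle."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(111, projection="3d")
    theta = np.linspace(0, 2 * np.pi, 361)
    ax.plot(np.cos(theta), np.sin(theta), np.zeros_like(theta),
            color="red", lw=1.0, label="unit circle")
    p = traj.points
    ax.plot(p[:, 0], p[:, 1], p[:, 2], color="blue", lw=0.6, label="trajectory")
    ax.set_xlabel("cos $\\varphi$")
    ax.set_ylabel("sin $\\varphi$")
    ax.set_zlabel("amplitude")
    ax.legend(loc="upper right")
    # fixed metadata keeps PNG output byte-reproducible across runs
    kwargs = {"metadata": {"Software": "fecgx"}} if out_path.suffix == ".png" else {}
    fig.savefig(out_path, dpi=dpi, **kwargs)
    plt.close(fig)
    return out_path
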