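"""Trajectory observables: inactive-core detection, core-size statistics,
bound fraction, radius of gyration and steady-state detection.

Core detection operationalizes what the snapshots show as dense inactive
domains: single-linkage connected components over the inactive (B) beads
with adjacency distance ``cluster_cutoff`` (default 1.5 a, the attractive
first-neighbor shell), discarding components below ``min_core_size``.
Absolute core counts depend on this rule; trends with bonding strength do
not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

from .engine.config import TYPE_A, TYPE_B, SimulationConfig
from .engine.state import SystemState, Trajectory, TrajectoryFrame

DEFAULT_CLUSTER_CUTOFF = 1.5
DEFAULT_MIN_CORE_SIZE = 10
DESK_MIN_CORE_SIZE = 5
DEFAULT_STEADY_FRACTION = 0.25


@dataclass
class Core:
    size: int
    center: np.ndarray
    members: np.ndarray  # global bead indices


@dataclass
class CoreStats:
    """Cores detected in one frame, largest first (ties by first member)."""

    frame_index: int
    cores: list = field(default_factory=list)

    @property
    def n_cores(self) -> int:
        return len(self.cores)

    @property
    def sizes(self) -> np.ndarray:
        return np.array([c.size for c in self.cores], dtype=int)


@dataclass
class ObservableSeries:
    """Per-frame observables plus the detected steady-state window."""

    steps: np.ndarray
    n_cores: np.ndarray
    Omega: np.ndarray
    Rg: np.ndarray
    mean_energy: np.ndarray
    steady_window: tuple | None = None


def detect_cores(
    frame: TrajectoryFrame,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
) -> CoreStats:
    """Single-linkage clustering of the inactive beads of one frame."""
    if cluster_cutoff <= 0:
        raise ValueError("cluster_cutoff must be positive")
    b_idx = np.nonzero(frame.types == TYPE_B)[0]
    stats = CoreStats(frame_index=frame.step)
    if len(b_idx) == 0:
        return stats
    pos = frame.positions[b_idx]
    tree = cKDTree(pos)
    pairs = tree.query_pairs(cluster_cutoff, output_type="ndarray")
    n = len(b_idx)
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    n_comp, labels = sparse.csgraph.connected_components(adj, directed=False)
    cores = []
    for c in range(n_comp):
        members = b_idx[labels == c]
        if len(members) < min_core_size:
            continue
        center = frame.positions[members].mean(axis=0)
        cores.append(Core(size=len(members), center=center, members=members))
    cores.sort(key=lambda c: (-c.size, int(c.members[0])))
    stats.cores = cores
    return stats


def core_count_series(
    trajectory: Trajectory,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
    steady_fraction: float = DEFAULT_STEADY_FRACTION,
) -> pd.DataFrame:
    """Per-frame core counts; the ``steady`` column flags the final
    ``steady_fraction`` of frames used for steady-state statistics."""
    if len(trajectory) == 0:
        raise ValueError("trajectory has no frames")
    counts = [
        detect_cores(f, cluster_cutoff, min_core_size).n_cores
        for f in trajectory
    ]
    df = pd.DataFrame({"step": trajectory.steps, "n_cores": counts})
    df["steady"] = _steady_mask(len(df), steady_fraction)
    df.attrs["steady_mean"] = float(df.loc[df["steady"], "n_cores"].mean())
    df.attrs["steady_median"] = float(
        df.loc[df["steady"], "n_cores"].median()
    )
    return df


def _steady_mask(n: int, fraction: float) -> np.ndarray:
    start = int(np.ceil(n * (1.0 - fraction)))
    mask = np.zeros(n, dtype=bool)
    mask[min(start, n - 1):] = True
    return mask


def core_size_distribution(
    trajectory: Trajectory,
    window: tuple | None = None,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
) -> pd.Series:
    """Normalized histogram of core sizes (beads) over a frame window.

    ``window`` is an (start, end) frame-index slice; by default the final
    quarter of the trajectory.  The returned Series is indexed by size and
    sums to 1; its ``.attrs`` carry mean and variance.
    """
    n = len(trajectory)
    if window is None:
        start = int(np.ceil(n * (1.0 - DEFAULT_STEADY_FRACTION)))
        window = (min(start, n - 1), n)
    lo, hi = window
    if not 0 <= lo < hi <= n:
        raise ValueError(f"empty or invalid window {window} for {n} frames")
    sizes: list[int] = []
    for i in range(lo, hi):
        sizes.extend(detect_cores(trajectory[i], cluster_cutoff, min_core_size).sizes)
    if not sizes:
        hist = pd.Series(dtype=float)
        hist.attrs.update(mean=np.nan, var=np.nan, n_cores=0)
        return hist
    values, counts = np.unique(np.array(sizes), return_counts=True)
    hist = pd.Series(counts / counts.sum(), index=values, name="probability")
    hist.attrs.update(
        mean=float(np.mean(sizes)), var=float(np.var(sizes)), n_cores=len(sizes)
    )
    return hist


def measure_bound_fraction(frame, config: SimulationConfig) -> float:
    """Omega = (number of dynamic bonds) / (number of active beads)."""
    partner, types = frame.partner, frame.types  # frame or SystemState
    n_active = int(np.count_nonzero(types == TYPE_A))
    if n_active == 0:
        return 0.0
    n_bonds = int(np.count_nonzero(partner >= 0)) // 2
    return n_bonds / n_active


def radius_of_gyration(frame, subset: np.ndarray | None = None) -> float:
    """Root-mean-square distance of the selected beads from their centroid."""
    pos = frame.positions if hasattr(frame, "positions") else np.asarray(frame)
    if subset is not None:
        pos = pos[subset]
    if len(pos) == 0:
        raise ValueError("empty bead subset")
    com = pos.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((pos - com) ** 2, axis=1))))


def steady_state_window(
    series: pd.DataFrame,
    slope_tolerance: float = 0.05,
    window_fraction: float = DEFAULT_STEADY_FRACTION,
    signals: tuple = ("U_total", "Rg"),
) -> tuple | None:
    """Earliest window of fixed fractional length over which the linear
    -fit relative drift of every signal stays below ``slope_tolerance``.

    Drift is measured as |fitted change across the window| / |window
    mean|.  Returns (start, end) row indices, or None when no window
    qualifies ("steady state not reached").
    """
    n = len(series)
    w = max(2, int(round(n * window_fraction)))
    if n < w:
        raise ValueError("series shorter than the window")
    x = np.arange(w, dtype=float)
    for start in range(0, n - w + 1):
        ok = True
        for col in signals:
            y = np.asarray(series[col].iloc[start : start + w], dtype=float)
            slope = np.polyfit(x, y, 1)[0]
            scale = max(abs(float(np.mean(y))), 1e-12)
            if abs(slope) * (w - 1) / scale > slope_tolerance:
                ok = False
                break
        if ok:
            return (start, start + w)
    return None


def observables(
    result,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    min_core_size: int = DEFAULT_MIN_CORE_SIZE,
    slope_tolerance: float = 0.05,
) -> ObservableSeries:
    """Frame-resolved observables of a :class:`SimulationResult`."""
    traj = result.trajectory
    n_active = int(np.count_nonzero(traj.types == TYPE_A))
    n_cores = np.array(
        [
            detect_cores(f, cluster_cutoff, min_core_size).n_cores
            for f in traj
        ]
    )
    omega = np.array(
        [
            (np.count_nonzero(f.partner >= 0) // 2) / max(n_active, 1)
            for f in traj
        ]
    )
    rg = np.array(
        [radius_of_gyration(f, np.arange(traj.n_chain)) for f in traj]
    )
    energy = np.interp(
        traj.steps, result.series["step"], result.series["U_total"]
    )
    window = None
    if len(result.series) >= 4:
        window = steady_state_window(result.series, slope_tolerance)
    return ObservableSeries(
        steps=traj.steps,
        n_cores=n_cores,
        Omega=omega,
        Rg=rg,
        mean_energy=energy,
        steady_window=window,
    )
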