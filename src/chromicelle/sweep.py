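"""Bonding-strength sweep driver: runs the simulator over a grid of
dynamic-bond stiffnesses K and seeds and summarizes the steady-state
observables (core count, core size, bound fraction) per run."""

from __future__ import annotations

import copy
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import (
    DEFAULT_CLUSTER_CUTOFF,
    DESK_MIN_CORE_SIZE,
    core_size_distribution,
    observables,
)
from .engine import run_simulation
from .engine.config import SimulationConfig


def sweep_K(
    base_config: SimulationConfig,
    K_values,
    seeds,
    cluster_cutoff: float = DEFAULT_CLUSTER_CUTOFF,
    min_core_size: int = DESK_MIN_CORE_SIZE,
    steady_fraction: float = 0.25,
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> pd.DataFrame:
    """One row per (K, seed): steady-state core count (median over the
    final ``steady_fraction`` of frames), mean core size, and mean bound
    fraction.  A failed run is recorded (``error`` column) and the sweep
    continues.  Deterministic for fixed seeds.
    """
    rows = []
    for K in K_values:
        for seed in seeds:
            config = copy.deepcopy(base_config)
            config.K = float(K)
            config.seed = int(seed)
            row = {"K": float(K), "seed": int(seed), "error": ""}
            try:
                result = run_simulation(config)
                obs = observables(
                    result,
                    cluster_cutoff=cluster_cutoff,
                    min_core_size=min_core_size,
                )
                n = len(obs.steps)
                lo = min(int(np.ceil(n * (1.0 - steady_fraction))), n - 1)
                sizes = core_size_distribution(
                    result.trajectory,
                    window=(lo, n),
                    cluster_cutoff=cluster_cutoff,
                    min_core_size=min_core_size,
                )
                row.update(
                    n_cores=float(np.median(obs.n_cores[lo:])),
                    n_cores_mean=float(np.mean(obs.n_cores[lo:])),
                    core_size_mean=float(sizes.attrs["mean"]),
                    core_size_var=float(sizes.attrs["var"]),
                    Omega=float(np.mean(obs.Omega[lo:])),
                    Rg=float(np.mean(obs.Rg[lo:])),
                )
                if out_dir is not None:
                    from .io import write_trajectory

                    out = Path(out_dir)
                    out.mkdir(parents=True, exist_ok=True)
                    write_trajectory(
                        result.trajectory,
                        out / f"traj_K{K}_seed{seed}.dump",
                    )
            except Exception as exc:  # keep sweeping past single failures
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            if progress:
                print(f"sweep_K: K={K} seed={seed} done: {rows[-1]}")
    df = pd.DataFrame(rows)
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(out_dir) / "sweep_summary.csv", index=False)
    return df


def summarize_sweep(df: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a sweep table over seeds: median/sd per K."""
    ok = df[df["error"] == ""] if "error" in df else df
    return (
        ok.groupby("K")
        .agg(
            n_cores_median=("n_cores", "median"),
            n_cores_sd=("n_cores", "std"),
            core_size_median=("core_size_mean", "median"),
            Omega_median=("Omega", "median"),
            Omega_sd=("Omega", "std"),
            n_runs=("seed", "count"),
        )
        .reset_index()
    )
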