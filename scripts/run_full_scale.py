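#!/usr/bin/env python
"""Cluster profile: the published-scale chromatin micelle simulation.

Runs the ``paper_full`` preset — 500 blocks of 100 active + 100 inactive
beads (100,000 chromatin beads), 50,000 protein beads, confinement radius
108 a, 10^7 Langevin steps — at a chosen bonding strength, with periodic
checkpoints so the job can be resumed.  At this scale the steady-state
number of inactive cores saturates around one hundred for strong binding.

This is a multi-day single-core job (or a queue of jobs, one per K and
seed); it is deliberately not part of the test suite.  Desk-scale
validation lives in the tests and in scripts/acceptance.py.

Usage:
    python scripts/run_full_scale.py --k 10 --seed 1 --out runs/full_K10_s1
    python scripts/run_full_scale.py --restart runs/full_K10_s1/checkpoint.json
"""

from __future__ import annotations

import argparse
from pathlib import Path

import numpy as np

from chromicelle.analysis import (
    DEFAULT_CLUSTER_CUTOFF,
    DEFAULT_MIN_CORE_SIZE,
    observables,
)
from chromicelle.engine import load_checkpoint, run_simulation
from chromicelle.fixtures import preset
from chromicelle.io import write_manifest, write_trajectory


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--k", type=float, default=10.0, help="bond stiffness")
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("runs/full"))
    parser.add_argument("--steps", type=int, default=None,
                        help="override the 10^7-step default")
    parser.add_argument("--restart", type=Path, default=None,
                        help="checkpoint file to resume from")
    args = parser.parse_args()

    state = None
    if args.restart is not None:
        config, state = load_checkpoint(args.restart)
        out = args.restart.parent
    else:
        config = preset("paper_full")
        config.K = args.k
        config.seed = args.seed
        out = args.out
    if args.steps is not None:
        config.n_steps = args.steps

    out.mkdir(parents=True, exist_ok=True)
    result = run_simulation(
        config,
        state=state,
        checkpoint_path=out / "checkpoint.json",
        checkpoint_every=100_000,
    )
    result.series.to_csv(out / "series.csv", index=False)
    write_trajectory(result.trajectory, out / "trajectory.dump")

    obs = observables(
        result,
        cluster_cutoff=DEFAULT_CLUSTER_CUTOFF,
        min_core_size=DEFAULT_MIN_CORE_SIZE,
    )
    q = max(len(obs.steps) // 4, 1)
    summary = {
        "K": config.K,
        "seed": config.seed,
        "steady_n_cores_median": float(np.median(obs.n_cores[-q:])),
        "steady_Omega_mean": float(np.mean(obs.Omega[-q:])),
        "steady_Rg_mean": float(np.mean(obs.Rg[-q:])),
    }
    (out / "summary.json").write_text(__import__("json").dumps(summary, indent=2))
    write_manifest(out, config, config.seed, end_step=result.state.step)
    print(summary)


if __name__ == "__main__":
    main()
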