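# chromicelle

Core-shell chromatin microphase separation regulated by protein binding:
an analytical mean-field theory and a coarse-grained Brownian dynamics
simulator, for polymer physicists and quantitative chromatin biologists
studying how transcription machinery reshapes genome organization.

## The model

Chromatin is treated as a multiblock copolymer of alternating active (A,
euchromatin-like) and inactive (B, heterochromatin-like) blocks, both
self-attractive, confined with a solution of protein complexes (RNA Pol
II, transcription factors) that bind reversibly to active monomers only.
The B blocks condense into dense cores; the A blocks form brush-like
shells.  Binding is summarized by the parameter

    eta = e^(1+eps) * phi_bulk,        Omega = eta / (1 + eta),

(`eps` the binding energy in k_BT, `phi_bulk` the bulk protein volume
fraction, `Omega` the bound fraction) and renormalizes the shell's
second and third virial coefficients,

    v_eta = v + (1+2eta)^2/(1+eta)^2,   w_eta = (1+2eta)^3/(1+eta)^3,

driving the active brush from poor through theta (at
`eta* = (sqrt(-v)-1)/(2-sqrt(-v))`) to good solvent.  Balancing brush
osmotic pressure against interfacial tension yields the interfacial area
per block `sigma`, brush height `lambda_A`, core thickness `lambda_B`
and, for spherical micelles, the blocks per core `m` in each regime
(e.g. `sigma ~ v_eta^{2/5} N_A^{3/5}/alpha^{3/5}` in good solvent, with
`m ~ N_B^2` throughout).  Stronger binding always swells the brush and
makes cores smaller and more numerous — the theory's central, testable
statement.

The companion simulator integrates the same system explicitly: a
bead-spring copolymer plus protein beads in a confining sphere,
truncated Lennard-Jones interactions (`eps_BB = 0.5 > eps_AA = 0.3`),
and valence-1 harmonic bonds of stiffness `K` that form within `1.5 a`
and break beyond `2.5 a`, integrated with a Langevin thermostat.  Core
counts, core-size distributions and the bound fraction `Omega(K)` are
measured from trajectories by single-linkage clustering of the inactive
beads.

## Worked example

```python
from chromicelle.meanfield import (
    MeanFieldParams, theta_point, full_equilibrium,
    binding_parameter, classify_regime,
)

print(f"theta point for v=-2: eta* = {theta_point(-2.0):.4f}")
for eps in (0, 2, 4):
    p = MeanFieldParams(N_A=100, N_B=100, v=-2.0, eps=eps, phi_bulk=0.01)
    eq = full_equilibrium(p)
    regime = classify_regime(p.v, binding_parameter(p.eps, p.phi_bulk)).label.value
    print(f"eps={eps}:  Omega={eq.Omega:.4f}  sigma={eq.sigma:.3f}  "
          f"lambda_A={eq.lambda_A:.3f}  lambda_B={eq.lambda_B:.3f}  ({regime} solvent)")
```

prints

```
theta point for v=-2: eta* = 0.7071
eps=0:  Omega=0.0015  sigma=5.116  lambda_A=13.058  lambda_B=9.774  (poor solvent)
eps=2:  Omega=0.0126  sigma=5.234  lambda_A=13.209  lambda_B=9.553  (poor solvent)
eps=4:  Omega=0.4346  sigma=11.360  lambda_A=19.459  lambda_B=4.401  (good solvent)
```

Reading this: at binding energy 4 k_BT the bound fraction jumps to 0.43,
the effective solvent turns good, the interfacial area per block more
than doubles (5.1 -> 11.4 a^2), the active brush swells (13.1 -> 19.5 a)
and the inactive core thins (9.8 -> 4.4 a) — protein binding to the
*active* blocks restructures the *inactive* cores.  All four equilibrium
conditions are satisfied to a residual below 1e-10.

The same experiment in the simulator, from a shell:

```bash
chromicelle sweep-k --k 0,2,5,10 --seeds 0,1,2 --out runs/sweep
chromicelle analyze sweep-summary --sweep-csv runs/sweep/sweep_summary.csv \
    --out runs/sweep/aggregate.csv
```

which at desk scale (20 blocks of 20+20 beads, 400 protein beads)
reproduces the theory's trends: the median steady-state core count rises
from ~5 at `K=0` to ~16 at `K=10` while the mean core size drops from
~80 to ~25 beads, and `Omega(K)` follows a sigmoid that saturates near 1
for `K >= 4`.  `chromicelle --help` lists the remaining commands
(`meanfield solve|sweep`, `simulate`, `analyze`, `fixtures`).

The published-scale system (100,000 chromatin beads, 50,000 proteins,
10^7 steps, where the core count saturates around one hundred) is a
cluster job: `scripts/run_full_scale.py`.

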