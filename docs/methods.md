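# Methods

`chromicelle` models the spatial organization of chromatin as microphase
separation of a multiblock copolymer whose solvent quality is regulated
by the reversible binding of protein complexes (RNA polymerase II,
transcription factors) to the transcriptionally active blocks.  It has
two pillars: an analytical mean-field theory of the core-shell structure
(`chromicelle.meanfield`) and a coarse-grained Langevin-dynamics
simulator with valence-1 dynamic bonds (`chromicelle.engine`), plus the
trajectory analysis connecting the two (`chromicelle.analysis`).

All quantities are reduced: lengths in monomer/bead diameters `a`,
energies in `k_B T`, times in the Langevin unit `tau`, mass `m = 1`.

## Mean-field theory

### Model

Chromatin is a chain of `n` repeats of an active block (A, `N_A`
monomers) followed by an inactive block (B, `N_B` monomers).  Both block
types are self-attractive (poor solvent); the B-B attraction is the
stronger, so in the strong-segregation limit the B blocks condense into
a dense core of fixed volume fraction `phi_B` while the A blocks form a
brush-like shell of extension `lambda_A` and volume fraction `phi_A`,
anchored at an interface with area `sigma` per block and dimensionless
tension `alpha = gamma a^2 / k_B T`.  A reservoir of protein complexes
(volume fraction `phi_bulk`, binding energy `eps` per complex on an
active monomer) exchanges particles with the shell.

The shell free energy per block is

    f = 2 alpha sigma
      + 2 lambda_A sigma [phi_fc ln phi_fc + psi ln psi]
      + N_A [Omega ln Omega + (1-Omega) ln(1-Omega) - eps Omega]
      + 3 lambda_A^2 / N_A + v N_A phi_A (1-Omega)^2 / 2,

with `psi = 1 - phi_fc - phi_A (1+Omega)` the solvent fraction (a bound
complex occupies one lattice site beside its monomer), `phi_fc` the free
-complex fraction, `Omega` the bound fraction, and `v < 0` the bare
second virial coefficient of the active monomers.  Monomer conservation
fixes `phi_A = N_A / (2 lambda_A sigma)` and the core half-thickness
`lambda_B = N_B / (2 phi_B sigma)`.

### Binding renormalizes the solvent quality

In the dilute limit the binding equilibrium gives `Omega = eta/(1+eta)`
with the binding parameter `eta = e^(1+eps) phi_bulk`.  Because each
bound complex adds one site of excluded volume, the pressure balance of
the shell carries effective virial coefficients

    v_eta = v + (1+2 eta)^2/(1+eta)^2,    w_eta = (1+2 eta)^3/(1+eta)^3,

both nondecreasing in `eta` with ranges `[v+1, v+4]` and `[1, 8]`.  The
shell therefore crosses from poor (`v_eta < 0`) through theta to good
(`v_eta > 0`) solvent as binding strengthens; the theta point has the
closed form `eta* = (sqrt(-v) - 1)/(2 - sqrt(-v))`, which exists for
`v` in `(-4, -1]`.  Regime classification uses the sign of the exact
`v_eta` with a tolerance band (default `theta_tolerance = 0.05`) rather
than scaling-level threshold formulas, which are mutually inconsistent
at order one.

### Scaling solutions and prefactor convention

In each regime the dominant balance of

    -3/(2 sigma^2 phi_A) + (v_eta/2) phi_A^2 + (w_eta/3) phi_A^3 = 0

together with the interfacial-area condition yields power laws for
`sigma`, `phi_A`, `lambda_A`, `lambda_B` and, mapping the layer onto
spherical micelles via `(4 pi/3) r^3 phi_B = N_B m`, for the number of
blocks per core `m`.  Every `~` relation is evaluated with numerical
prefactor exactly 1; this convention is recorded in
`LayerSolution.convention`.  Absolute values therefore carry an O(1)
ambiguity, but the exponents — `sigma ~ N_A^{3/5}` (good), `N_A^{1/2}`
(theta), `N_A^{1/3}` (poor); `lambda_A ~ N_A^{4/5}, N_A^{3/4},
N_A^{2/3}`; `m ~ N_B^2` always — are convention-independent, and the
conservation identities hold exactly by construction.  Note that the
good-solvent core thickness follows from conservation as
`lambda_B^e ~ N_B alpha^{3/5} / (N_A^{3/5} v_eta^{2/5} phi_B)`; the
`N_A^{-3/5}` exponent is the one consistent with `m^e ~ N_A^{-9/5}`.

### Full equilibrium solver

`full_equilibrium` solves the four coupled conditions — equality of the
free- and bound-complex chemical potentials, equality with the reservoir
chemical potential `ln phi_bulk`, osmotic-pressure balance
`Pi_shell = Pi_bulk = phi_bulk`, and the interfacial-area condition
`dF/dS + 2 Pi_shell L_A = 0` — with all derivatives taken analytically
from the free energy above.  (The area condition in fact reduces
analytically to `2 alpha = 6 lambda_A^2/(sigma N_A)`; the solver
evaluates the full derivative expressions, so this cancellation is
computed rather than assumed.)  Unknowns are transformed (logits of
compositions, logs of lengths) to keep iterates feasible; infeasible
excursions are repelled by a smooth penalty, never clamped.  The root
find is scipy's modified-Powell method from a scaling-solution initial
guess, with up to eight deterministic jittered restarts.  Convergence
means the term-scaled residual max-norm is below 1e-10; a failed solve
reports `converged=False` with its residuals.

Two consequences worth knowing.  First, the exact binding equilibrium is
`Omega/(1-Omega) = eta psi exp(v phi_A (1-Omega))`, so the dilute-limit
isotherm `Omega = eta/(1+eta)` (including its factor e) is recovered
only as `phi_A -> 0`; at `phi_A ~ 0.3` the bound fraction is several
-fold below the isotherm.  Second, with binding disabled the same solver
reduces to a bare-brush solve, which the enabled solver must match when
`eps -> -infinity` — this is tested to 1e-6.

## Brownian dynamics

### Model

A bead-spring chain of `n_blocks x (N_A + N_B)` beads (pattern A-block,
B-block, repeated) plus `N_p` free protein beads, all of diameter `a`,
confined to a sphere of radius `R_c = (N/(8 phi))^{1/3}` set by the
chromatin volume fraction `phi`.  Potentials:

* chain springs `k_spring (r - a)^2` with `k_spring = 100`;
* truncated (not shifted) Lennard-Jones pair potentials with strengths
  `eps_AA = eps_AB = 0.3`, `eps_BB = 0.5`, `eps_AP = 0.4` (cutoff
  `2.5 a`) and purely repulsive `eps_PP = eps_BP = 1` (cutoff
  `2^{1/6} a`): protein beads neither self-associate nor enter the
  inactive cores;
* a repulsive LJ wall acting on the gap `R_c - |r|`;
* valence-1 harmonic dynamic bonds between active and protein beads:
  formed with probability 1 when an unbonded pair comes within
  `r_bond = 1.5 a`, energy `K (r - r0)^2` with `r0 = a`, broken (and the
  potential zeroed) beyond `r_break = 2.5 a`.  `K` in `[0, 10]` is the
  control parameter; `K = 0` disables the bond machinery entirely.
  The bond-formation energy offset is zero: formation is unconditional
  within the capture radius and breaking purely distance-triggered, so
  an offset would never affect the dynamics.

Bond sweeps run every `bond_update_interval = 10` steps: breaking first,
then formation over all free candidate pairs sorted by distance (ties by
bead index), so the update is deterministic and the nearest pairs win.

Pair exclusions: chain-bonded neighbors and actively bonded A-P pairs do
not interact through the LJ potential (standard 1-2 exclusion).  A
dynamic bond stretched beyond `r_break` is defunct — no bond energy, LJ
restored — until the next sweep removes it.  Because a bonded pair has
no LJ core repulsion, its length fluctuates around `r0` with variance
`1/(2K)`; excursions below `0.5 a` are handled by the singularity guard
(separations clamped at `0.5 a` in the pair force/energy laws).  For
non-bonded pairs the guard also increments a counter, since there it
signals a pathological state.  Below the guard radius the capped force
is no longer the exact gradient of the (flat) clamped potential; valid
states never reach it.

### Integration

BAOAB velocity-Verlet Langevin with `dt = 0.01 tau`, `T = 1`, damping
time 10 tau (`gamma = 0.1`), which reproduces the Einstein diffusivity
`D = k_B T damping / m = 10 a^2/tau` (verified to 5% via the MSD slope).
Gaussian kicks are drawn in single precision from one `numpy` PCG64
generator in fixed-size blocks of 2000 steps; the generator state is
part of the checkpoint, and neighbor-list rebuilds are forced at block
boundaries so a restarted run is bit-identical to an uninterrupted one.
A per-step displacement above `0.5 a` aborts with an instability error.

For the integrator validation on an isolated harmonic dimer the
`dimer_test` preset uses `dt = 0.005` (so `omega dt = 0.1` for the
stiff `k = 100` bond, keeping the configurational discretization bias
far below statistical resolution) and damping `0.5 tau` (fast sample
decorrelation); bond lengths sampled every `2 tau` are compared to
`P(r) ~ r^2 exp(-k (r-1)^2)` by a Kolmogorov-Smirnov test.

### Neighbor search

Cell-list-built Verlet pair lists with list cutoff `max cutoff + skin`
(default skin `0.8 a`, chosen by profiling; any skin gives identical
physics and this is enforced by brute-force oracle tests).  The list is
rebuilt when the two largest displacements since the last build sum to
more than the skin — the sharp sufficient condition for no pair to close
an unseen gap.  Chain bonds are excluded at build time; dynamically
bonded pairs are instead LJ-corrected in the bond loop, which is
algebraically identical to exclusion but keeps the list valid across
bond updates.  Energies and forces from this path agree with an O(N^2)
double loop to 1e-10 and with central finite differences to 1e-6.

## Trajectory analysis

* **Core detection** — single-linkage connected components over the
  inactive beads with adjacency cutoff `1.5 a` (the attractive
  first-neighbor shell), discarding components below `min_core_size`
  (10 beads at published scale, 5 at desk scale where whole blocks are
  only 20 beads).  The absolute core count depends on this rule, which
  is why trends in `K`, not absolute counts, are the robust observable;
  the rule and its parameters are recorded in all outputs.  Core centers
  are member centroids (the geometry is a bounded sphere; no periodic
  images).
* **Bound fraction** — `Omega = bonds / (n_blocks N_A)`.
* **Radius of gyration** — RMS distance of the chromatin beads from
  their centroid; with energy, the steady-state diagnostic.
* **Steady-state window** — earliest window of fixed fractional length
  (default 25%) over which the linear-fit relative drift of total energy
  and Rg both stay below a tolerance (default 5%); summary statistics
  default to the final quarter of frames.

## Synthetic data and what the tests show

The `fixtures` module generates everything the tests consume: initial
configurations (chain grown as a constrained random walk with a `0.9 a`
overlap floor, proteins placed uniformly, then ~2000 sweeps of
displacement-capped steepest descent, leaving chain bonds within 5% of
rest length), and planted-cluster frames with exact ground truth for the
core detector.  The `desk_small` preset is the published-scale system
shrunk 125-fold (20 blocks of 20+20 beads, 400 protein beads) while
preserving every dimensionless ratio the theory identifies as relevant:
volume fraction 0.01, one protein per active bead, `N_A = N_B`, the same
interaction matrix, bonding radii and integrator settings.

What desk-scale agreement does and does not show: the qualitative
regulation mechanism — more and smaller cores, sigmoidal `Omega(K)`
saturating near 1 for `K >~ 4` — transfers cleanly, and is what the
tests assert.  Absolute core counts do not transfer (a 20-block chain
can form at most 20 single-block cores, versus the ~100-core saturation
of the 500-block system), and none of this validates the model against
real chromatin, where block sizes are heterogeneous, binding is
non-equilibrium, and the nucleoplasm is not an implicit solvent.

Problem sizes used by the shipped test suite were chosen so the whole
suite runs on one core in well under half an hour: the bonding-strength
sweep runs `K in {0, 2, 5, 10}` with three seeds for 1.5x10^5 steps
(this system reaches its steady state by ~10^5 steps: `Omega`
plateaus within 5x10^4 steps and the core count by 10^5), while
`scripts/acceptance.py` runs the full 5x10^5-step protocol.  The
published-scale 150,000-particle, 10^7-step run is packaged as
`scripts/run_full_scale.py`, a multi-day single-core job.

## Known limitations

* The mean-field prefactor-1 convention makes absolute lengths O(1)
  -accurate only; exponents and trends are the quantitative content.
* The theory assumes a dilute shell; scaling solutions with
  `phi_A >= 1` are returned with an explicit outside-validity flag, not
  clamped.
* The brush treatment excludes the star-polymer/mushroom regime of very
  long active blocks and lateral phase separation within the brush.
* The simulator has no hydrodynamic interactions and a rigid spherical
  wall; LJ truncation is unshifted, so absolute energies contain the
  usual truncation discontinuity at the cutoff.
* Whether the A-P LJ attraction should persist while a dynamic bond is
  active is not determined by the model definition; this implementation
  excludes it (1-2 exclusion) and the choice is a known sensitivity.
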