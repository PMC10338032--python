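"""Brownian dynamics engine: potentials, forces, dynamic bonds,
integrator statistics and determinism."""

import math

import numpy as np
import pytest

from chromicelle.engine import (
    ConfinementError,
    InstabilityError,
    SimulationConfig,
    chain_stretch_energy,
    compute_forces,
    confinement_energy,
    confinement_radius,
    integrate_step,
    load_checkpoint,
    pair_energy,
    run_simulation,
    save_checkpoint,
    total_energy,
    update_dynamic_bonds,
)
from chromicelle.engine.config import TYPE_A, TYPE_B, TYPE_P
from chromicelle.fixtures import generate_initial_configuration, preset

from conftest import boltzmann_bond_length_ks, make_state, random_mixed_state

WCA = 2.0 ** (1.0 / 6.0)


class TestConfinementRadius:
    def test_published_scale(self):
        r = confinement_radius(100_000, 0.01)
        assert r == pytest.approx(107.72, abs=0.005)
        assert round(r) == 108

    def test_algebraic_identity(self):
        with pytest.warns(UserWarning):
            assert confinement_radius(8, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_desk_scale(self):
        assert confinement_radius(800, 0.01) == pytest.approx(
            10_000.0 ** (1.0 / 3.0), rel=1e-12
        )

    def test_rejects_unphysical_volume_fraction(self):
        with pytest.raises(ValueError):
            confinement_radius(100, 1.5)
        with pytest.raises(ValueError):
            confinement_radius(100, 0.0)
        with pytest.warns(UserWarning):  # beyond close packing: formal only
            confinement_radius(100, 0.8)


class TestPairEnergy:
    def test_minimum_depth(self):
        cfg = SimulationConfig()
        assert pair_energy(WCA, "B", "B", cfg) == pytest.approx(-0.5, rel=1e-12)

    def test_zero_beyond_cutoff(self):
        cfg = SimulationConfig()
        for pair in (("A", "A"), ("A", "B"), ("A", "P")):
            assert pair_energy(2.6, *pair, cfg) == 0.0

    def test_repulsive_only_pairs_truncate_at_wca(self):
        cfg = SimulationConfig()
        assert pair_energy(1.2, "P", "P", cfg) == 0.0
        assert pair_energy(1.0, "P", "P", cfg) == pytest.approx(0.0, abs=1e-12)
        assert pair_energy(0.95, "B", "P", cfg) > 0.0

    def test_direct_evaluation(self):
        cfg = SimulationConfig()
        expected = 4 * 0.3 * (1.2**-12 - 1.2**-6)
        assert pair_energy(1.2, "A", "A", cfg) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(-0.26729, abs=1e-5)


class TestStretchAndConfinement:
    def _chain(self, bond_lengths, R_c=30.0):
        xs = np.concatenate([[0.0], np.cumsum(bond_lengths)])
        pos = np.stack([xs, np.zeros_like(xs), np.zeros_like(xs)], axis=1)
        types = np.array([TYPE_A] * len(pos), np.int8)
        cfg = SimulationConfig(
            n_blocks=1, N_A=len(pos) - 1, N_B=1, N_p=0, R_c=R_c
        )
        # use an all-A chain of matching length for the geometry
        state = make_state(pos, types, len(pos))
        return state, cfg

    def test_zero_at_rest_length(self):
        state, cfg = self._chain([1.0, 1.0, 1.0])
        assert chain_stretch_energy(state, cfg) == 0.0

    def test_single_stretched_bond(self):
        state, cfg = self._chain([1.1])
        assert chain_stretch_energy(state, cfg) == pytest.approx(1.0, rel=1e-9)

    def test_two_strained_bonds_add(self):
        state, cfg = self._chain([0.9, 1.2])
        assert chain_stretch_energy(state, cfg) == pytest.approx(5.0, rel=1e-9)

    def test_confinement_zero_away_from_wall(self):
        state, cfg = self._chain([1.0], R_c=21.5)
        assert confinement_energy(state, cfg) == 0.0

    def test_confinement_zero_at_truncation_gap(self):
        cfg = SimulationConfig(n_blocks=1, N_A=1, N_B=1, N_p=0, R_c=10.0)
        for gap in (WCA, 1.0):
            pos = [[10.0 - gap, 0, 0], [0, 0, 0]]
            state = make_state(pos, [TYPE_A, TYPE_B], 2)
            assert confinement_energy(state, cfg) == pytest.approx(
                0.0, abs=1e-12
            )

    def test_bead_outside_sphere_is_integrity_error(self):
        cfg = SimulationConfig(n_blocks=1, N_A=1, N_B=1, N_p=0, R_c=5.0)
        state = make_state([[5.5, 0, 0], [0, 0, 0]], [TYPE_A, TYPE_B], 2)
        with pytest.raises(ValueError):
            confinement_energy(state, cfg)


def _two_bead_config(**kw):
    defaults = dict(n_blocks=1, N_A=1, N_B=1, N_p=1, R_c=30.0, K=5.0)
    defaults.update(kw)
    return SimulationConfig(**defaults)


class TestDynamicBonds:
    def _state(self, sep, partner=None):
        cfg = _two_bead_config()
        pos = [[0, 0, 0], [0, 1.0, 0], [sep, 0, 0]]  # A, B, P
        state = make_state(pos, [TYPE_A, TYPE_B, TYPE_P], 2, partner=partner)
        return state, cfg

    def test_bond_forms_inside_capture_radius(self):
        state, cfg = self._state(1.2)
        update_dynamic_bonds(state, cfg)
        assert state.partner[0] == 2 and state.partner[2] == 0

    def test_no_bond_outside_capture_radius(self):
        state, cfg = self._state(1.8)
        update_dynamic_bonds(state, cfg)
        assert state.n_bonds == 0

    def test_bond_breaks_beyond_rupture_radius(self):
        state, cfg = self._state(2.6, partner=[2, -1, 0])
        update_dynamic_bonds(state, cfg)
        assert state.n_bonds == 0

    def test_bond_survives_between_radii(self):
        state, cfg = self._state(2.0, partner=[2, -1, 0])
        update_dynamic_bonds(state, cfg)
        assert state.partner[0] == 2

    def test_valence_saturation_blocks_second_bond(self):
        cfg = SimulationConfig(n_blocks=1, N_A=2, N_B=1, N_p=1, R_c=30.0, K=5.0)
        # two active beads within reach of one protein; nearest wins
        pos = [[0, 0, 0], [2.5, 0, 0], [0, 5.0, 0], [1.2, 0, 0]]
        state = make_state(
            pos, [TYPE_A, TYPE_A, TYPE_B, TYPE_P], 3
        )
        update_dynamic_bonds(state, cfg)
        assert state.partner[3] == 0  # nearer active bead (1.2 < 1.3)
        assert state.partner[1] == -1

    def test_protein_saturated_elsewhere_forms_no_new_bond(self):
        cfg = SimulationConfig(n_blocks=1, N_A=2, N_B=1, N_p=1, R_c=30.0, K=5.0)
        pos = [[0, 0, 0], [2.0, 0, 0], [5.0, 5.0, 0], [1.2, 0, 0]]
        state = make_state(
            pos,
            [TYPE_A, TYPE_A, TYPE_B, TYPE_P],
            3,
            partner=[-1, 3, -1, 1],  # protein already bound to bead 1
        )
        update_dynamic_bonds(state, cfg)
        assert state.partner[0] == -1
        assert state.partner[3] == 1


class TestForces:
    def test_zero_pair_force_at_lj_minimum(self):
        cfg = _two_bead_config(N_p=1)
        # chain dimer at rest; the protein sits at the A-P LJ minimum and
        # beyond the B-P repulsive cutoff: every force vanishes
        pos = [[0, 0, 0], [0, 1.0, 0], [WCA, 0, 0]]
        state = make_state(pos, [TYPE_A, TYPE_B, TYPE_P], 2)
        f = compute_forces(state, cfg)
        assert np.abs(f).max() < 1e-10

    def test_zero_bond_force_at_rest_length(self):
        cfg = _two_bead_config()
        pos = [[0, 0, 0], [0, 1.0, 0], [1.0, 0, 0]]
        state = make_state(
            pos, [TYPE_A, TYPE_B, TYPE_P], 2, partner=[2, -1, 0]
        )
        f = compute_forces(state, cfg)
        # bond at r0 and LJ excluded for the bonded pair: no net force
        assert np.abs(f).max() < 1e-10

    def test_forces_match_finite_differences(self):
        state, cfg = random_mixed_state(n_chain=40, n_protein=12, bond_some=True)
        assert state.n_bonds > 0
        f = compute_forces(state, cfg)
        rng = np.random.default_rng(1)
        h = 2e-6
        fmax = np.abs(f).max()
        for b in rng.choice(state.n_total, 12, replace=False):
            for k in range(3):
                orig = state.positions[b, k]
                state.positions[b, k] = orig + h
                up = total_energy(state, cfg).U_total
                state.positions[b, k] = orig - h
                dn = total_energy(state, cfg).U_total
                state.positions[b, k] = orig
                fd = -(up - dn) / (2 * h)
                assert fd == pytest.approx(f[b, k], abs=2e-6 * max(fmax, 1.0))


class TestTotalEnergy:
    @staticmethod
    def _brute_force(state, cfg):
        """Plain-python double loop, no neighbor list (independent oracle)."""
        eps, cut = cfg.pair_tables()
        pos, types = state.positions, state.types
        n = len(pos)
        u_lj = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                r = math.dist(pos[i], pos[j])
                if j - i == 1 and j < state.n_chain:
                    continue
                if state.partner[i] == j and r < cfg.r_break:
                    continue
                if r >= cut[types[i], types[j]]:
                    continue
                rr = max(r, 0.5)
                u_lj += (
                    4.0
                    * eps[types[i], types[j]]
                    * ((1.0 / rr) ** 12 - (1.0 / rr) ** 6)
                )
        u_spring = 0.0
        for i in range(state.n_chain - 1):
            r = math.dist(pos[i], pos[i + 1])
            u_spring += cfg.k_spring * (r - 1.0) ** 2
        u_bond = 0.0
        for i in range(n):
            j = state.partner[i]
            if j > i:
                r = math.dist(pos[i], pos[j])
                if r < cfg.r_break:
                    u_bond += cfg.K * (r - cfg.r0) ** 2
        u_conf = 0.0
        for i in range(n):
            gap = cfg.R_c - math.sqrt(sum(c * c for c in pos[i]))
            if gap < WCA:
                u_conf += 4.0 * ((1.0 / gap) ** 12 - (1.0 / gap) ** 6)
        return u_spring, u_lj, u_conf, u_bond

    def test_matches_brute_force_oracle(self):
        state, cfg = random_mixed_state(
            n_chain=80, n_protein=40, seed=5, bond_some=True
        )
        us, ulj, uc, ub = self._brute_force(state, cfg)
        rep = total_energy(state, cfg)
        assert rep.U_stretch == pytest.approx(us, abs=1e-10)
        assert rep.U_LJ == pytest.approx(ulj, abs=1e-10)
        assert rep.U_confine == pytest.approx(uc, abs=1e-10)
        assert rep.U_bond == pytest.approx(ub, abs=1e-10)
        assert rep.U_total == pytest.approx(us + ulj + uc + ub, abs=1e-10)

    def test_neighbor_list_path_matches_reference(self):
        from chromicelle.engine.dynamics import _Workspace

        state, cfg = random_mixed_state(
            n_chain=60, n_protein=30, seed=9, bond_some=True
        )
        ws = _Workspace(state, cfg)
        us, ulj, uc, ub = ws.energies(state)
        rep = total_energy(state, cfg)
        assert us == pytest.approx(rep.U_stretch, abs=1e-10)
        assert ulj == pytest.approx(rep.U_LJ, abs=1e-10)
        assert uc == pytest.approx(rep.U_confine, abs=1e-10)
        assert ub == pytest.approx(rep.U_bond, abs=1e-10)

    def test_centered_chain_dimer_has_zero_energy(self):
        cfg = SimulationConfig(n_blocks=1, N_A=1, N_B=1, N_p=0, R_c=30.0)
        state = make_state([[0, 0, 0], [0, 1.0, 0]], [TYPE_A, TYPE_B], 2)
        rep = total_energy(state, cfg)
        assert rep.U_stretch == rep.U_confine == rep.U_bond == 0.0
        assert rep.U_LJ == 0.0  # the only pair is the excluded chain bond
        assert rep.U_total == 0.0

    def test_straight_chain_energy_is_next_neighbor_lj_tails(self):
        cfg = SimulationConfig(n_blocks=1, N_A=2, N_B=2, N_p=0, R_c=30.0)
        pos = [[i * 1.0 - 1.5, 0, 0] for i in range(4)]
        # chain pairs (i, i+1) excluded; (0,2) and (1,3) at distance 2.0
        # are inside the 2.5 cutoff, (0,3) at 3.0 is beyond it
        state = make_state(pos, [TYPE_A, TYPE_A, TYPE_B, TYPE_B], 4)
        rep = total_energy(state, cfg)
        assert rep.U_stretch == 0.0
        assert rep.U_confine == 0.0
        assert rep.U_bond == 0.0
        assert rep.U_LJ == pytest.approx(
            pair_energy(2.0, "A", "B", cfg) * 2, abs=1e-14
        )


class TestIntegrator:
    def test_frozen_system_stays_put(self):
        cfg = _two_bead_config(temperature=0.0, N_p=0)
        # chain dimer at rest bond length: zero force, zero temperature
        state = make_state([[0, 0, 0], [0, 1.0, 0]], [TYPE_A, TYPE_B], 2)
        before = state.positions.copy()
        integrate_step(state, cfg, n_steps=100)
        assert np.array_equal(state.positions, before)

    def test_determinism_same_seed_same_trajectory(self):
        cfg = preset("desk_small")
        cfg.n_steps = 4000
        cfg.seed = 3
        r1 = run_simulation(cfg)
        cfg2 = preset("desk_small")
        cfg2.n_steps = 4000
        cfg2.seed = 3
        r2 = run_simulation(cfg2)
        assert np.array_equal(r1.state.positions, r2.state.positions)
        assert r1.series.equals(r2.series)
        assert np.array_equal(
            r1.trajectory.partners, r2.trajectory.partners
        )

    def test_restart_reproduces_uninterrupted_run(self, tmp_path):
        cfg = preset("desk_small")
        cfg.n_steps = 8000
        cfg.seed = 5
        full = run_simulation(cfg)

        cfg_a = preset("desk_small")
        cfg_a.n_steps = 4000
        cfg_a.seed = 5
        ck = tmp_path / "ck.json"
        run_simulation(cfg_a, checkpoint_path=ck)
        config_b, state_b = load_checkpoint(ck)
        assert state_b.step == 4000
        config_b.n_steps = 8000
        resumed = run_simulation(config_b, state=state_b)
        assert np.array_equal(full.state.positions, resumed.state.positions)
        assert np.array_equal(full.state.velocities, resumed.state.velocities)
        assert np.array_equal(full.state.partner, resumed.state.partner)

    def test_instability_raises(self):
        cfg = _two_bead_config(N_p=0, dt=1.0)
        pos = [[0, 0, 0], [3.0, 0, 0]]  # grossly overstretched spring
        state = make_state(pos, [TYPE_A, TYPE_B], 2)
        with pytest.raises(InstabilityError):
            integrate_step(state, cfg, n_steps=5)

    def test_free_bead_diffusion_einstein_relation(self, diffusion_msd_slope):
        # non-interacting beads: long-time MSD slope = 6 k_B T damping / m
        assert diffusion_msd_slope == pytest.approx(60.0, rel=0.05)

    def test_harmonic_dimer_samples_boltzmann_bond_lengths(
        self, dimer_bond_length_samples
    ):
        r, k_spring = dimer_bond_length_samples
        assert len(r) >= 99_000
        assert boltzmann_bond_length_ks(r, k_spring).pvalue > 0.01


class TestChainStatistics:
    def test_repulsive_chain_approaches_self_avoiding_walk_scaling(self):
        # with every attraction off (purely repulsive WCA pairs, K = 0)
        # the chain is a self-avoiding walk: Rg ~ N^nu with nu ~ 0.59.
        # Loose sanity band that excludes collapsed (1/3) and rod (1)
        # statistics.
        lengths = [16, 32, 64]
        rgs = []
        for n in lengths:
            cfg = SimulationConfig(
                n_blocks=1,
                N_A=n // 2,
                N_B=n - n // 2,
                N_p=0,
                R_c=200.0,
                eps_matrix={k: 1.0 for k in ("AA", "AB", "BB", "AP", "BP", "PP")},
                repulsive_only=("AA", "AB", "BB", "AP", "BP", "PP"),
                K=0.0,
                n_steps=60_000,
                dump_interval=2000,
                log_interval=30_000,
                seed=n,
            )
            res = run_simulation(cfg)
            frames = res.trajectory.positions[8:]  # discard equilibration
            rg = [
                float(
                    np.sqrt(
                        np.mean(
                            np.sum((f - f.mean(axis=0)) ** 2, axis=1)
                        )
                    )
                )
                for f in frames
            ]
            rgs.append(np.mean(rg))
        slope = np.polyfit(np.log(lengths), np.log(rgs), 1)[0]
        assert 0.5 < slope < 0.75


class TestRunInvariants:
    def test_valence_and_confinement_hold_after_bonded_run(self, short_desk_run):
        res = short_desk_run
        res.state.validate(res.config)
        assert res.state.n_bonds > 0
        for partners in res.trajectory.partners:
            bonded = np.nonzero(partners >= 0)[0]
            assert np.all(partners[partners[bonded]] == bonded)

    def test_no_binding_when_K_zero(self):
        cfg = preset("desk_small")
        cfg.K = 0.0
        cfg.n_steps = 4000
        cfg.seed = 2
        res = run_simulation(cfg)
        assert (res.series["n_bonds"] == 0).all()
        assert (res.series["U_bond"] == 0.0).all()

    def test_bond_count_grows_toward_plateau(self, short_desk_run):
        nb = short_desk_run.series["n_bonds"].to_numpy()
        # rises from zero and does not collapse back
        assert nb[0] == 0
        assert nb[-1] > 0.5 * nb.max()
        first_half = nb[: len(nb) // 2].mean()
        second_half = nb[len(nb) // 2 :].mean()
        assert second_half > first_half
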