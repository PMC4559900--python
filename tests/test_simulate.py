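"""Langevin engine: force correctness, integrator physics, stage protocol."""

import numpy as np
import pytest

from coevdock.sbm import SBMParams, SBMTopology, Stage, build_topology, default_schedule
from coevdock.simulate import (SimulationError, SimulationState, compute_forces,
                               langevin_step, restraint_energy, run_annealing,
                               run_stage)
from coevdock.structure import build_initial_pose

from conftest import restraints_from_pairs


def free_particles(n):
    """Topology with no interaction terms at all."""
    empty = np.zeros((0, 2))
    return SBMTopology(
        n_particles=n, chain_index=np.zeros(n, dtype=int),
        bonds=np.zeros((0, 4)), angles=np.zeros((0, 5)),
        dihedrals=np.zeros((0, 6)), intra_contacts=np.zeros((0, 5)),
        dca_contacts=np.zeros((0, 5)), repulsion_pairs=np.zeros((0, 2), int),
        sigma_ex=4.0, epsilon=1.0)


def single_bond(k=200.0, r0=3.8):
    top = free_particles(2)
    top.bonds = np.array([[0, 1, r0, k]])
    return top


class TestForces:
    def test_hooke_force_on_stretched_bond(self):
        top = single_bond()
        delta = 0.3
        x = np.array([[0.0, 0, 0], [3.8 + delta, 0, 0]])
        forces, e = compute_forces(x, top)
        assert forces[0, 0] == pytest.approx(200.0 * delta, rel=1e-10)
        assert e["bonds"] == pytest.approx(0.5 * 200.0 * delta ** 2)

    def test_all_terms_match_finite_differences(self, toy_dimer, toy_topology):
        toy_topology.set_stage(default_schedule().stages[2])
        rng = np.random.default_rng(4)
        x = toy_dimer.native.ca + rng.normal(0, 0.4, toy_dimer.native.ca.shape)
        forces, _ = compute_forces(x, toy_topology)
        h = 1e-6
        for p in rng.choice(toy_topology.n_particles, 8, replace=False):
            for dim in range(3):
                xp, xm = x.copy(), x.copy()
                xp[p, dim] += h
                xm[p, dim] -= h
                _, ep = compute_forces(xp, toy_topology)
                _, em = compute_forces(xm, toy_topology)
                fd = -(ep["total"] - em["total"]) / (2 * h)
                assert fd == pytest.approx(forces[p, dim], rel=1e-5, abs=1e-5)

    def test_energy_decomposition_sums_to_total(self, toy_dimer, toy_topology):
        _, e = compute_forces(toy_dimer.native.ca, toy_topology)
        parts = sum(v for k, v in e.items() if k != "total")
        assert parts == pytest.approx(e["total"], rel=1e-9)

    def test_near_zero_force_at_native_minimum(self, toy_dimer, toy_topology):
        # bonded terms take native values, so the native pose is a minimum
        # of everything but the (soft) contact and repulsion terms
        forces, _ = compute_forces(toy_dimer.native.ca, toy_topology)
        interior = forces[2:18]
        assert np.abs(interior).max() < 2.0

    def test_overlapping_particles_error(self):
        top = free_particles(2)
        top.repulsion_pairs = np.array([[0, 1]])
        x = np.array([[0.0, 0, 0], [1e-8, 0, 0]])
        with pytest.raises(SimulationError, match="overlap"):
            compute_forces(x, top)


class TestIntegrator:
    def test_nve_energy_conservation(self, toy_dimer, toy_topology):
        # gamma = 0 reduces BAOAB to velocity Verlet; drift over 1e5 steps
        # at dt = 0.002 tau stays below 0.1% of the well depth (eps = 1)
        toy_topology.set_stage(default_schedule().stages[-1])
        state = SimulationState.from_structure(toy_dimer.native,
                                               temperature=0.2, seed=0)
        def total_energy():
            _, e = compute_forces(state.x, toy_topology)
            return e["total"] + 0.5 * np.sum(state.v ** 2)
        from coevdock.simulate import _Compiled, _integrate_chunk
        compiled = _Compiled(toy_topology)
        series = []
        for _ in range(100):
            _integrate_chunk(state, toy_topology, dt=0.002, gamma=0.0, T=0.0,
                             n_steps=1000, compiled=compiled)
            series.append(total_energy())
        # secular drift: linear trend over the full run (the symplectic
        # scheme oscillates around a shadow energy but must not drift)
        slope = np.polyfit(np.arange(len(series)), series, 1)[0]
        assert abs(slope * len(series)) < 1e-3  # 0.1% of the unit well depth
        # and the oscillation itself stays small
        assert np.ptp(series) < 5e-3

    def test_equipartition_of_free_particles(self):
        top = free_particles(200)
        rng = np.random.default_rng(1)
        state = SimulationState(x=rng.normal(0, 10, (200, 3)),
                                v=np.zeros((200, 3)),
                                rng=np.random.default_rng(2))
        from coevdock.simulate import _Compiled, _integrate_chunk
        compiled = _Compiled(top)
        T = 0.5
        # relax, then average kinetic energy per degree of freedom
        _integrate_chunk(state, top, dt=0.0005, gamma=1.0, T=T,
                         n_steps=20000, compiled=compiled)
        acc = []
        for _ in range(40):
            _integrate_chunk(state, top, dt=0.0005, gamma=1.0, T=T,
                             n_steps=2000, compiled=compiled)
            acc.append(np.mean(state.v ** 2))
        assert np.mean(acc) == pytest.approx(T, rel=0.05)

    def test_same_seed_reproduces_state(self, toy_dimer, toy_topology):
        runs = []
        for _ in range(2):
            state = SimulationState.from_structure(toy_dimer.native,
                                                   temperature=0.5, seed=42)
            for _ in range(50):
                langevin_step(state, toy_topology, dt=0.005, gamma=0.05, T=0.5)
            runs.append((state.x.copy(), state.v.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_invalid_dt(self, toy_dimer, toy_topology):
        state = SimulationState.from_structure(toy_dimer.native, seed=0)
        with pytest.raises(ValueError):
            langevin_step(state, toy_topology, dt=0.0, gamma=1.0, T=0.5)


class TestRunStage:
    def test_docked_pose_converges_quickly(self, toy_dimer, toy_topology):
        stage = Stage(r0=8.0, A=4.0, w=1.5, max_steps=100000, window=20)
        state = SimulationState.from_structure(toy_dimer.native,
                                               temperature=0.2, seed=3)
        traj, converged = run_stage(state, toy_topology, stage,
                                    record_stride=25)
        assert converged
        assert traj.n_frames <= 200

    def test_zero_budget_gives_empty_trajectory(self, toy_dimer, toy_topology):
        stage = Stage(r0=50.0, A=1.0, w=10.0, max_steps=0)
        state = SimulationState.from_structure(toy_dimer.native, seed=0)
        traj, converged = run_stage(state, toy_topology, stage)
        assert traj.n_frames == 0 and not converged

    def test_restraints_pull_chains_together(self, toy_dimer, toy_topology):
        pose = build_initial_pose(toy_dimer.native, separation=30.0, seed=1)
        state = SimulationState.from_structure(pose, temperature=0.5, seed=1)
        stage = Stage(r0=20.0, A=1.0, w=10.0, max_steps=40000)
        traj, _ = run_stage(state, toy_topology, stage, record_stride=50)
        gap = [np.linalg.norm(f[:20].mean(0) - f[20:].mean(0))
               for f in traj.coords]
        smooth = np.convolve(gap, np.ones(10) / 10, mode="valid")
        assert smooth[-1] < smooth[0] - 5.0


class TestAnnealing:
    def test_no_restraints_means_no_binding(self, toy_dimer):
        rest = restraints_from_pairs([])
        top = build_topology(toy_dimer.monomer("A"),
                             toy_dimer.native.select_chains(["B"]), rest)
        pose = build_initial_pose(toy_dimer.native, separation=50.0, seed=2)
        d0 = np.linalg.norm(pose.ca[:20].mean(0) - pose.ca[20:].mean(0))
        sched = default_schedule(max_steps=3000)
        traj = run_annealing(pose, top, sched, seed=0, mode="predict")
        d1 = np.linalg.norm(traj.coords[-1][:20].mean(0)
                            - traj.coords[-1][20:].mean(0))
        assert abs(d1 - d0) < 0.2 * d0

    def test_validate_mode_requires_native(self, toy_dimer, toy_topology):
        pose = build_initial_pose(toy_dimer.native, separation=50.0, seed=0)
        with pytest.raises(ValueError):
            run_annealing(pose, toy_topology, default_schedule(),
                          mode="validate", native=None)
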