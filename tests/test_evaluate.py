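"""Superposition, dimer RMSD, interfacial RMSD and trajectory scoring."""

import numpy as np
import pytest

from coevdock.evaluate import (EvaluationError, contact_map_report,
                               dimer_rmsd, evaluate_trajectory,
                               interface_residues, interfacial_rmsd,
                               superpose)
from coevdock.simulate import Trajectory
from coevdock.structure import CaStructure

from conftest import restraints_from_pairs
from oracles import superpose_grid_oracle


def rotation(theta, axis=2):
    c, s = np.cos(theta), np.sin(theta)
    r = np.eye(3)
    i, j = [(1, 2), (0, 2), (0, 1)][axis]
    r[i, i] = c
    r[j, j] = c
    r[i, j] = -s
    r[j, i] = s
    return r


def as_dimer(coords, n_a):
    n = len(coords)
    return CaStructure(
        np.array(["A"] * n_a + ["B"] * (n - n_a)),
        np.concatenate([np.arange(1, n_a + 1), np.arange(1, n - n_a + 1)]),
        np.array(["G"] * n), np.asarray(coords, float))


class TestSuperpose:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(0, 3, (10, 3))
        rot, trans, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(rot, np.eye(3), atol=1e-8)

    def test_recovers_rigid_transform(self):
        pts = np.random.default_rng(1).normal(0, 3, (12, 3))
        moved = pts @ rotation(np.pi / 2).T + np.array([4.0, -2.0, 9.0])
        _, _, rmsd = superpose(pts, moved)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_proper_rotation_even_for_reflected_data(self):
        pts = np.random.default_rng(2).normal(0, 3, (10, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        rot, _, _ = superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-8)

    def test_matches_quaternion_grid_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(3):
            a = rng.normal(0, 2, (10, 3))
            b = rng.normal(0, 2, (10, 3))
            _, _, rmsd = superpose(a, b)
            oracle = superpose_grid_oracle(a, b, seed=trial)
            assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(EvaluationError, match="degenerate"):
            superpose(line, line)

    def test_too_few_points_rejected(self):
        with pytest.raises(EvaluationError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestDimerRmsd:
    def test_zero_on_identical(self, toy_dimer):
        assert dimer_rmsd(toy_dimer.native, toy_dimer.native) == \
            pytest.approx(0.0, abs=1e-9)

    def test_zero_on_chain_relabeled(self, toy_dimer):
        n = toy_dimer.n
        swapped = as_dimer(np.vstack([toy_dimer.native.ca[n:],
                                      toy_dimer.native.ca[:n]]), n)
        native = as_dimer(toy_dimer.native.ca, n)
        assert dimer_rmsd(swapped, native) == pytest.approx(0.0, abs=1e-9)

    def test_displaced_chain_matches_oracle(self, toy_dimer):
        n = toy_dimer.n
        coords = toy_dimer.native.ca.copy()
        coords[n:] += np.array([3.0, 0.0, 0.0])
        pred = as_dimer(coords, n)
        native = as_dimer(toy_dimer.native.ca, n)
        got = dimer_rmsd(pred, native)
        oracle = min(
            superpose_grid_oracle(coords, toy_dimer.native.ca, seed=0),
            superpose_grid_oracle(
                np.vstack([coords[n:], coords[:n]]),
                toy_dimer.native.ca, seed=1))
        assert got == pytest.approx(oracle, abs=2e-3)
        assert 0.0 < got < 3.0

    def test_rigid_motion_invariance(self, toy_dimer):
        n = toy_dimer.n
        native = as_dimer(toy_dimer.native.ca, n)
        moved = as_dimer(
            toy_dimer.native.ca @ rotation(1.1, 0).T + np.array([5.0, 1, 2]), n)
        assert dimer_rmsd(moved, native) == pytest.approx(0.0, abs=1e-8)

    def test_chain_length_mismatch_rejected(self, toy_dimer):
        pred = as_dimer(toy_dimer.native.ca[:30], 20)
        with pytest.raises(EvaluationError):
            dimer_rmsd(pred, as_dimer(toy_dimer.native.ca, 20))


class TestInterfacialRmsd:
    def test_zero_on_identical(self, toy_dimer):
        assert interfacial_rmsd(toy_dimer.native, toy_dimer.native) == \
            pytest.approx(0.0, abs=1e-9)

    def test_everything_interfacial_reduces_to_dimer_rmsd(self, toy_dimer):
        n = toy_dimer.n
        coords = toy_dimer.native.ca.copy()
        coords[n:] += np.array([0.5, 0.2, -0.1])
        pred = as_dimer(coords, n)
        native = as_dimer(toy_dimer.native.ca, n)
        huge = 1e4  # every residue within the interface cutoff
        assert interfacial_rmsd(pred, native, huge) == \
            pytest.approx(dimer_rmsd(pred, native), abs=1e-9)

    def test_shrinking_cutoff_never_grows_interface(self, toy_dimer):
        prev = None
        for cutoff in (14.0, 11.0, 9.0, 8.5):
            res = set(interface_residues(toy_dimer.native, cutoff))
            if prev is not None:
                assert res <= prev
            prev = res

    def test_empty_interface_rejected(self, toy_dimer):
        n = toy_dimer.n
        coords = toy_dimer.native.ca.copy()
        coords[n:] += 500.0
        apart = as_dimer(coords, n)
        with pytest.raises(EvaluationError, match="interface"):
            interfacial_rmsd(as_dimer(coords, n), apart, 10.0)
            # reference with no interface


def make_trajectory(frames, stages=None):
    frames = np.asarray(frames, float)
    n = len(frames)
    stages = np.asarray(stages if stages is not None else np.ones(n), int)
    return Trajectory(coords=frames,
                      energies={"total": np.zeros(n)},
                      stage_labels=stages, monitored=np.zeros(n), stride=1)


class TestEvaluateTrajectory:
    def test_single_native_frame(self, toy_dimer):
        traj = make_trajectory([toy_dimer.native.ca], [7])
        rep = evaluate_trajectory(traj, toy_dimer.native)
        assert rep.rmsd_best == pytest.approx(0.0, abs=1e-9)
        assert rep.rmsd_final_stage_mean == pytest.approx(0.0, abs=1e-9)
        assert rep.contact_recovery == pytest.approx(1.0)

    def test_best_frame_is_argmin(self, toy_dimer):
        n = toy_dimer.n
        frames = []
        for shift in (5.0, 2.0, 3.0):
            c = toy_dimer.native.ca.copy()
            c[n:, 2] += shift
            frames.append(c)
        traj = make_trajectory(frames, [6, 7, 7])
        rep = evaluate_trajectory(traj, toy_dimer.native)
        assert rep.rmsd_best_frame == 1
        assert rep.rmsd_best == pytest.approx(min(rep.rmsd_series))
        final = rep.rmsd_series[1:]
        assert rep.rmsd_final_stage_mean == pytest.approx(final.mean())

    def test_report_matches_frame_by_frame_recomputation(self, toy_dimer):
        rng = np.random.default_rng(7)
        n = toy_dimer.n
        frames = [toy_dimer.native.ca + rng.normal(0, s, (2 * n, 3))
                  for s in (1.0, 0.3, 0.6)]
        traj = make_trajectory(frames, [5, 6, 7])
        rep = evaluate_trajectory(traj, toy_dimer.native)
        recomputed = [dimer_rmsd(as_dimer(f, n), as_dimer(toy_dimer.native.ca, n))
                      for f in frames]
        assert np.allclose(rep.rmsd_series, recomputed, atol=1e-9)
        assert rep.rmsd_best == pytest.approx(min(recomputed))


class TestContactMapReport:
    def test_prediction_equal_to_native(self, toy_dimer):
        table, summary = contact_map_report(toy_dimer.native, toy_dimer.native)
        native_d = set(map(tuple, table[table["set"] == "native_dimeric"]
                           [["i", "j"]].values))
        pred_d = set(map(tuple, table[table["set"] == "predicted_dimeric"]
                         [["i", "j"]].values))
        assert native_d == pred_d and len(native_d) > 0

    def test_true_positive_fraction(self, toy_dimer):
        # 4 true interface pairs + 1 fabricated off-interface pair -> TP 0.8
        true_pairs = toy_dimer.interface_pairs[:4]
        false_pair = (0, 1)  # adjacent beads: never a cross-chain contact
        rest = restraints_from_pairs(true_pairs + [false_pair])
        _, summary = contact_map_report(toy_dimer.native, toy_dimer.native,
                                        rest)
        assert summary["restraint_tp_fraction"] == pytest.approx(0.8)
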