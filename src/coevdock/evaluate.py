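"""Scoring predicted complexes against a reference.

Least-squares rigid superposition (Kabsch), whole-complex dimer RMSD with
homodimer chain-swap handling, CAPRI-style interfacial RMSD (interface =
residues with any cross-chain C-alpha within a cutoff, default 10 A,
superposed on the interface residues), best-frame selection over a
trajectory and contact-map reconstruction reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from coevdock.structure import CaStructure, contact_map
from coevdock.simulate import Trajectory
from coevdock.filtering import DimerRestraintSet


class EvaluationError(ValueError):
    """Raised for degenerate or inconsistent evaluation input."""


@dataclass
class EvaluationReport:
    """Summary metrics of a docking trajectory against a native complex."""

    rmsd_best: float
    rmsd_best_frame: int
    rmsd_final_stage_mean: float
    irmsd_best: float
    rmsd_series: np.ndarray
    irmsd_series: np.ndarray
    interface_residues: list[int]
    contact_recovery: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rmsd_best": self.rmsd_best,
            "rmsd_best_frame": self.rmsd_best_frame,
            "rmsd_final_stage_mean": self.rmsd_final_stage_mean,
            "irmsd_best": self.irmsd_best,
            "contact_recovery": self.contact_recovery,
            "interface_residues": self.interface_residues,
            "rmsd_series": self.rmsd_series.tolist(),
            "irmsd_series": self.irmsd_series.tolist(),
            **self.extras,
        }


def superpose(mobile: np.ndarray, reference: np.ndarray):
    """Optimal least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` best fits ``reference``; the
    rotation is proper (det +1).  Collinear or otherwise rotationally
    degenerate point sets are rejected.
    """
    p = np.asarray(mobile, float)
    q = np.asarray(reference, float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise EvaluationError("point sets must both be (n, 3)")
    if len(p) < 3:
        raise EvaluationError("superposition needs at least 3 points")
    pc = p - p.mean(axis=0)
    qc = q - q.mean(axis=0)
    h = pc.T @ qc
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise EvaluationError("degenerate (collinear) point set: rotation not unique")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    moved = p @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1))))
    return rot, trans, rmsd


def _swap_orders(n_a: int, n_b: int):
    """Index orders for the two chain assignments of a homodimer."""
    direct = np.arange(n_a + n_b)
    if n_a != n_b:
        return [direct]
    swapped = np.concatenate([np.arange(n_a, n_a + n_b), np.arange(n_a)])
    return [direct, swapped]


def dimer_rmsd_coords(pred: np.ndarray, native: np.ndarray, n_a: int) -> float:
    """Chain-swap-minimized whole-complex RMSD from raw coordinate arrays
    (first ``n_a`` points are chain A)."""
    n_b = len(native) - n_a
    best = np.inf
    for order in _swap_orders(n_a, n_b):
        _, _, r = superpose(pred[order], native)
        best = min(best, r)
    return best


def _split_sizes(s: CaStructure) -> tuple[int, int]:
    chains = s.chains
    if len(chains) != 2:
        raise EvaluationError(f"expected a two-chain complex, got chains {chains}")
    n_a = int(np.sum(s.chain_mask(chains[0])))
    return n_a, s.n_residues - n_a


def dimer_rmsd(pred: CaStructure, native: CaStructure) -> float:
    """Whole-complex C-alpha RMSD after optimal superposition, minimized
    over the two chain assignments (homodimer label symmetry)."""
    na_p, nb_p = _split_sizes(pred)
    na_n, nb_n = _split_sizes(native)
    if (na_p, nb_p) != (na_n, nb_n):
        raise EvaluationError(
            f"chain length mismatch: prediction {(na_p, nb_p)} vs native {(na_n, nb_n)}")
    return dimer_rmsd_coords(pred.ca, native.ca, na_n)


def interface_residues(native: CaStructure, cutoff: float = 10.0) -> list[int]:
    """Residues of the native complex with any cross-chain C-alpha within
    ``cutoff`` (CAPRI-style interface definition)."""
    na, _ = _split_sizes(native)
    a = native.ca[:na]
    b = native.ca[na:]
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    ia, jb = np.where(d < cutoff)
    res = sorted(set(ia.tolist()) | {na + j for j in set(jb.tolist())})
    return res


def interfacial_rmsd(pred: CaStructure, native: CaStructure,
                     interface_cutoff: float = 10.0) -> float:
    """RMSD over native-interface residues only, superposed on the
    interface, chain-swap minimized."""
    res = interface_residues(native, interface_cutoff)
    if not res:
        raise EvaluationError(
            f"no inter-chain contacts within {interface_cutoff} A: empty interface")
    na, nb = _split_sizes(native)
    if _split_sizes(pred) != (na, nb):
        raise EvaluationError("chain length mismatch between prediction and native")
    idx = np.array(res)
    best = np.inf
    for order in _swap_orders(na, nb):
        _, _, r = superpose(pred.ca[order][idx], native.ca[idx])
        best = min(best, r)
    return best


def _native_interchain_contacts(native: CaStructure, cutoff: float = 8.0):
    na, _ = _split_sizes(native)
    cm = contact_map(native, cutoff)
    return {(i, j) for i, j in cm.pairs if i < na <= j}, na


def contact_recovery(pred_coords: np.ndarray, native: CaStructure,
                     cutoff: float = 8.0) -> float:
    """Fraction of native inter-chain contacts (C-alpha within ``cutoff``)
    reproduced in the prediction, maximized over chain assignment."""
    contacts, na = _native_interchain_contacts(native, cutoff)
    if not contacts:
        return float("nan")
    nb = native.n_residues - na
    best = 0.0
    for order in _swap_orders(na, nb):
        x = pred_coords[order]
        hits = sum(1 for i, j in contacts
                   if np.linalg.norm(x[i] - x[j]) < cutoff)
        best = max(best, hits / len(contacts))
    return best


def evaluate_trajectory(traj: Trajectory, native: CaStructure,
                        interface_cutoff: float = 10.0,
                        contact_cutoff: float = 8.0) -> EvaluationReport:
    """Per-frame RMSD and interfacial RMSD, best-frame metrics, final-stage
    mean RMSD and dimeric contact recovery of the best frame."""
    if traj.n_frames == 0:
        raise EvaluationError("empty trajectory")
    na, nb = _split_sizes(native)
    if traj.coords.shape[1] != native.n_residues:
        raise EvaluationError("trajectory and native particle counts differ")
    res = interface_residues(native, interface_cutoff)
    idx = np.array(res)
    rmsds = np.empty(traj.n_frames)
    irmsds = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        x = traj.coords[f]
        rmsds[f] = dimer_rmsd_coords(x, native.ca, na)
        best_i = np.inf
        for order in _swap_orders(na, nb):
            _, _, r = superpose(x[order][idx], native.ca[idx])
            best_i = min(best_i, r)
        irmsds[f] = best_i
    best_frame = int(np.argmin(rmsds))
    last_stage = int(traj.stage_labels.max())
    final_mask = traj.stage_labels == last_stage
    return EvaluationReport(
        rmsd_best=float(rmsds[best_frame]),
        rmsd_best_frame=best_frame,
        rmsd_final_stage_mean=float(rmsds[final_mask].mean()),
        irmsd_best=float(irmsds.min()),
        rmsd_series=rmsds,
        irmsd_series=irmsds,
        interface_residues=res,
        contact_recovery=contact_recovery(traj.coords[best_frame], native,
                                          contact_cutoff),
    )


def contact_map_report(pred_best: CaStructure, native: CaStructure,
                       restraints: DimerRestraintSet | None = None,
                       cutoff: float = 8.0):
    """Plot-ready long-format contact table and a summary.

    The table lists native monomeric, native dimeric, predicted monomeric
    and predicted dimeric contact sets plus the restraint overlay; the
    summary reports the restraint true-positive fraction (restraints that
    are native dimeric contacts).
    """
    na_n, _ = _split_sizes(native)
    na_p, _ = _split_sizes(pred_best)
    rows = []

    def classify(s: CaStructure, na: int, label: str):
        cm = contact_map(s, cutoff)
        for i, j in sorted(cm.pairs):
            kind = "dimeric" if (i < na) != (j < na) else "monomeric"
            rows.append({"i": i, "j": j, "set": f"{label}_{kind}"})

    classify(native, na_n, "native")
    classify(pred_best, na_p, "predicted")

    tp_fraction = float("nan")
    if restraints is not None:
        native_dimeric = {(min(i, j), max(i, j)) for i, j, _ in
                          ((i, na_n + j, 0) for i, j, _ in restraints.interchain_restraints)}
        cm = contact_map(native, cutoff)
        native_cross = {(i, j) for i, j in cm.pairs if (i < na_n) != (j < na_n)}
        for a, b, _di in restraints.interchain_restraints:
            i, j = a, na_n + b
            key = (min(i, j), max(i, j))
            rows.append({"i": key[0], "j": key[1], "set": "restraint"})
        if restraints.interchain_restraints:
            hits = sum(1 for p in native_dimeric if p in native_cross)
            tp_fraction = hits / len(native_dimeric)
    table = pd.DataFrame(rows, columns=["i", "j", "set"])
    return table, {"restraint_tp_fraction": tp_fraction}
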