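"""Coarse-grained C-alpha structure-based topology.

Each monomer contributes bonded terms (bonds, angles, dihedrals) at their
native values and intra-chain native contacts modeled as narrow Gaussian
wells — the monomers are meant to stay near-rigid during binding, which is
reinforced by multiplying the dihedral force constant by 100.  Inter-chain
coevolutionary restraints are Gaussian wells whose equilibrium distance
``r0``, amplitude ``A`` and width ``w`` follow a seven-stage annealing
schedule that draws the chains from 50 A separation down to native-like
8 A contact distances.

The contact form is a single-basin Gaussian well on top of an ``r^-12``
excluded volume:

    V(r) = eps * (sigma_ex / r)^12 - A * eps * exp(-(r - r0)^2 / (2 w^2))

All energies are in reduced units of ``eps``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from coevdock.structure import CaStructure, contact_map
from coevdock.filtering import DimerRestraintSet


class TopologyError(ValueError):
    """Raised for inconsistent topology input."""


@dataclass
class SBMParams:
    """Force-field constants in reduced units (energies in eps).

    ``k_d_base`` is the base dihedral constant; the emitted constant is
    ``dihedral_factor`` times larger to keep monomers near-rigid while they
    reorient and bind.
    """

    k_b: float = 200.0          # bond, eps/A^2
    k_a: float = 40.0           # angle, eps/rad^2
    k_d_base: float = 1.0       # base dihedral, eps
    dihedral_factor: float = 100.0
    sigma_ex: float = 4.0       # excluded-volume diameter, A
    epsilon: float = 1.0
    contact_cutoff: float = 8.0  # native contact definition, A
    min_loop_sep: int = 4       # |i-j| >= 4 for intra-chain contacts
    intra_A: float = 1.0        # native-well amplitude
    intra_w: float = 0.5        # native-well width, A

    @property
    def k_d(self) -> float:
        return self.k_d_base * self.dihedral_factor


@dataclass
class Stage:
    """One annealing stage: Gaussian parameters for the inter-chain wells
    plus the integration/convergence budget."""

    r0: float                   # equilibrium distance r^N, A
    A: float                    # amplitude
    w: float                    # width (Gaussian standard deviation), A
    max_steps: int = 100000
    window: int = 50            # convergence window, recorded frames
    tol: float = 0.02           # sliding-window std / |running mean|


@dataclass
class StageSchedule:
    """Ordered seven-stage annealing plan."""

    stages: list[Stage]

    def __post_init__(self) -> None:
        if len(self.stages) != 7:
            raise TopologyError(f"schedule must have exactly 7 stages, got {len(self.stages)}")
        r = [s.r0 for s in self.stages]
        if any(b >= a for a, b in zip(r, r[1:])):
            raise TopologyError(f"stage equilibrium distances must strictly decrease, got {r}")

    def __iter__(self):
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)


def default_schedule(max_steps: int = 100000, window: int = 50,
                     tol: float = 0.02) -> StageSchedule:
    """Default seven-stage plan.

    Equilibrium distances interpolate the anchored endpoints 50 A -> 8 A;
    widths shrink as orientational search gives way to interface locking;
    amplitudes increase only during the last three stages to stabilize the
    final complex.
    """
    r0 = (50.0, 38.0, 28.0, 20.0, 14.0, 10.0, 8.0)
    w = (10.0, 8.0, 6.0, 5.0, 4.0, 3.0, 1.5)
    a = (1.0, 1.0, 1.0, 1.0, 2.0, 3.0, 4.0)
    return StageSchedule([Stage(r0=r, A=amp, w=wd, max_steps=max_steps,
                                window=window, tol=tol)
                          for r, amp, wd in zip(r0, a, w)])


@dataclass
class SBMTopology:
    """Bonded and nonbonded terms of the two-chain C-alpha model.

    Contact terms are ``(i, j, r0, A, w)``; ``dca_contacts`` start at stage
    1 of the schedule and are updated between stages.  ``repulsion_pairs``
    holds every particle pair subject to plain excluded volume (all pairs
    not covered by a bonded or contact term).
    """

    n_particles: int
    chain_index: np.ndarray               # (N,) 0 for chain A, 1 for chain B
    bonds: np.ndarray                     # (nb, 4): i, j, r0, k
    angles: np.ndarray                    # (na, 5): i, j, k, theta0, k_a
    dihedrals: np.ndarray                 # (nd, 6): i, j, k, l, phi0, k_d
    intra_contacts: np.ndarray            # (nc, 5): i, j, r0, A, w
    dca_contacts: np.ndarray              # (nr, 5): i, j, r0, A, w
    repulsion_pairs: np.ndarray           # (np, 2)
    sigma_ex: float
    epsilon: float
    params: SBMParams = field(default_factory=SBMParams)

    def set_stage(self, stage: Stage) -> None:
        """Load one annealing stage's (r0, A, w) into the DCA wells."""
        if len(self.dca_contacts):
            self.dca_contacts[:, 2] = stage.r0
            self.dca_contacts[:, 3] = stage.A
            self.dca_contacts[:, 4] = stage.w

    def to_json(self, path) -> None:
        payload = {
            "n_particles": self.n_particles,
            "chain_index": self.chain_index.tolist(),
            "bonds": self.bonds.tolist(),
            "angles": self.angles.tolist(),
            "dihedrals": self.dihedrals.tolist(),
            "intra_contacts": self.intra_contacts.tolist(),
            "dca_contacts": self.dca_contacts.tolist(),
            "repulsion_pairs": self.repulsion_pairs.tolist(),
            "sigma_ex": self.sigma_ex,
            "epsilon": self.epsilon,
            "params": asdict(self.params),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SBMTopology":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            n_particles=d["n_particles"],
            chain_index=np.array(d["chain_index"], dtype=int),
            bonds=np.array(d["bonds"], dtype=float).reshape(-1, 4),
            angles=np.array(d["angles"], dtype=float).reshape(-1, 5),
            dihedrals=np.array(d["dihedrals"], dtype=float).reshape(-1, 6),
            intra_contacts=np.array(d["intra_contacts"], dtype=float).reshape(-1, 5),
            dca_contacts=np.array(d["dca_contacts"], dtype=float).reshape(-1, 5),
            repulsion_pairs=np.array(d["repulsion_pairs"], dtype=int).reshape(-1, 2),
            sigma_ex=d["sigma_ex"], epsilon=d["epsilon"],
            params=SBMParams(**d["params"]),
        )


def gaussian_contact_energy(r, r0: float, A: float, w: float,
                            sigma_ex: float, epsilon: float = 1.0):
    """Gaussian contact well with excluded volume:
    ``eps (sigma_ex/r)^12 - A eps exp(-(r-r0)^2/(2 w^2))``."""
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("distance must be positive")
    if w <= 0:
        raise ValueError("Gaussian width must be positive")
    return (epsilon * (sigma_ex / r) ** 12
            - A * epsilon * np.exp(-((r - r0) ** 2) / (2.0 * w ** 2)))


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u, v = a - b, c - b
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def _dihedral(a, b, c, d) -> float:
    b1, b2, b3 = b - a, c - b, d - c
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    y = np.dot(m1, n2)
    return float(np.arctan2(y, x))


def _chain_bonded_terms(xyz: np.ndarray, offset: int, p: SBMParams):
    n = len(xyz)
    bonds = [(offset + i, offset + i + 1,
              float(np.linalg.norm(xyz[i + 1] - xyz[i])), p.k_b)
             for i in range(n - 1)]
    angles = [(offset + i, offset + i + 1, offset + i + 2,
               _angle(xyz[i], xyz[i + 1], xyz[i + 2]), p.k_a)
              for i in range(n - 2)]
    dihedrals = [(offset + i, offset + i + 1, offset + i + 2, offset + i + 3,
                  _dihedral(xyz[i], xyz[i + 1], xyz[i + 2], xyz[i + 3]), p.k_d)
                 for i in range(n - 3)]
    return bonds, angles, dihedrals


def build_topology(monomerA: CaStructure, monomerB: CaStructure,
                   restraints: DimerRestraintSet,
                   params: SBMParams | None = None,
                   schedule: StageSchedule | None = None) -> SBMTopology:
    """Assemble the two-chain topology.

    Bonded terms take their equilibrium values from each monomer's native
    geometry.  Intra-chain native contacts (C-alpha map at the configured
    cutoff, ``|i - j| >= 4``) become narrow Gaussian wells at native
    distances; inter-chain coevolutionary restraints become Gaussian wells
    initialized from stage 1 of the annealing schedule.  All bonded and
    contact pairs are excluded from the generic excluded-volume list.
    """
    p = params or SBMParams()
    sched = schedule or default_schedule()
    na, nb = monomerA.n_residues, monomerB.n_residues
    n = na + nb

    bonds, angles, dihedrals = [], [], []
    for xyz, off in ((monomerA.ca, 0), (monomerB.ca, na)):
        b, a, d = _chain_bonded_terms(xyz, off, p)
        bonds += b
        angles += a
        dihedrals += d

    intra = []
    for mono, off in ((monomerA, 0), (monomerB, na)):
        cm = contact_map(mono, p.contact_cutoff)
        for i, j in sorted(cm.pairs):
            if j - i >= p.min_loop_sep:
                intra.append((off + i, off + j, cm.distances[(i, j)],
                              p.intra_A, p.intra_w))

    stage1 = sched.stages[0]
    dca = []
    for a_res, b_res, _di in restraints.interchain_restraints:
        if not (0 <= a_res < na) or not (0 <= b_res < nb):
            bad = [(x, y) for x, y, _ in restraints.interchain_restraints
                   if not (0 <= x < na) or not (0 <= y < nb)]
            raise TopologyError(f"restraints reference missing residues: {bad}")
        dca.append((a_res, na + b_res, stage1.r0, stage1.A, stage1.w))

    excluded = set()
    for i, j, *_ in bonds:
        excluded.add((min(i, j), max(i, j)))
    for i, _j, k, *_ in angles:
        excluded.add((min(i, k), max(i, k)))
    for i, _j, _k, l, *_ in dihedrals:
        excluded.add((min(i, l), max(i, l)))
    for i, j, *_ in intra:
        excluded.add((int(i), int(j)))
    for i, j, *_ in dca:
        excluded.add((min(int(i), int(j)), max(int(i), int(j))))
    iu, ju = np.triu_indices(n, k=1)
    rep = np.array([(i, j) for i, j in zip(iu.tolist(), ju.tolist())
                    if (i, j) not in excluded], dtype=int)

    return SBMTopology(
        n_particles=n,
        chain_index=np.concatenate([np.zeros(na, int), np.ones(nb, int)]),
        bonds=np.array(bonds, float).reshape(-1, 4),
        angles=np.array(angles, float).reshape(-1, 5),
        dihedrals=np.array(dihedrals, float).reshape(-1, 6),
        intra_contacts=np.array(intra, float).reshape(-1, 5),
        dca_contacts=np.array(dca, float).reshape(-1, 5),
        repulsion_pairs=rep.reshape(-1, 2),
        sigma_ex=p.sigma_ex,
        epsilon=p.epsilon,
        params=p,
    )
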