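"""Synthetic fixtures: Potts-sampled alignments with planted couplings and
toy dimer structures with known interfaces.

The Potts model plays the role of family sequence statistics: planted
pairwise couplings stand in for coevolving contacts, and Gibbs sampling
produces alignments on which the whole inference pipeline can be exercised
without any external downloads.  The toy dimer is a pair of identical
idealized C-alpha helices related by a proper two-fold rotation, so its
interface is symmetric the way real homodimer interfaces are; linking the
two generators plants the dimer's interface pairs as Potts couplings,
enabling a full sample -> DCA -> filter -> dock -> evaluate round trip
against a known native complex.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from coevdock.alignment import ALPHABET, MSA
from coevdock.structure import CaStructure, contact_map

logger = logging.getLogger(__name__)


class SynthesisError(ValueError):
    """Raised when a requested fixture cannot be constructed."""


@dataclass
class PottsModel:
    """q-state Potts model with sparse planted pairwise couplings.

    ``couplings`` maps ordered position pairs ``(i, j)`` with ``i < j`` to
    ``(q, q)`` coupling matrices; energies enter the Gibbs measure as
    ``exp(beta * (sum_i h_i(s_i) + sum_(i<j) J_ij(s_i, s_j)))``.
    """

    L: int
    q: int
    fields: np.ndarray                          # (L, q)
    couplings: dict[tuple[int, int], np.ndarray]
    beta: float = 1.0

    def __post_init__(self) -> None:
        for (i, j), jmat in self.couplings.items():
            if not (0 <= i < j < self.L):
                raise SynthesisError(f"invalid planted pair {(i, j)}")
            if jmat.shape != (self.q, self.q):
                raise SynthesisError(f"coupling {(i, j)} must be ({self.q}, {self.q})")

    @property
    def planted_pairs(self) -> list[tuple[int, int]]:
        return sorted(self.couplings)

    def energy(self, s: np.ndarray) -> float:
        """Negative log-weight (up to beta) of one configuration."""
        e = sum(self.fields[i, s[i]] for i in range(self.L))
        e += sum(j[s[i], s[k]] for (i, k), j in self.couplings.items())
        return float(e)


@dataclass
class ToyDimer:
    """Two identical helical chains related by a two-fold rotation.

    ``interface_pairs`` lists the unordered single-chain position pairs
    ``(i, j)``, ``i < j``, realized as cross-chain contacts at 8 A in the
    native coordinates; by the two-fold symmetry each pair appears as both
    ``(i_A, j_B)`` and ``(j_A, i_B)``.
    """

    native: CaStructure
    n: int
    interface_pairs: list[tuple[int, int]]
    contact_cutoff: float = 8.0
    meta: dict = field(default_factory=dict)

    def monomer(self, chain: str = "A") -> CaStructure:
        return self.native.select_chains([chain])


def sample_potts(model: PottsModel, M: int, burn_in: int = 300,
                 thin: int = 5, seed: int | None = None,
                 n_chains: int = 500) -> MSA:
    """Gibbs-sample ``M`` sequences from a Potts model.

    ``n_chains`` independent chains are updated site-by-site in parallel;
    after ``burn_in`` full sweeps, every chain is recorded every ``thin``
    sweeps until ``M`` sequences are collected.  Deterministic given
    ``seed``.  The returned alignment records the planted pairs in its
    metadata.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    l, q, beta = model.L, model.q, model.beta
    nc = min(n_chains, max(M, 2))
    # neighbor lookup: site -> [(other_site, J_as_seen_from_site)]
    neighbors: dict[int, list[tuple[int, np.ndarray]]] = {i: [] for i in range(l)}
    for (i, j), jmat in model.couplings.items():
        neighbors[i].append((j, jmat))
        neighbors[j].append((i, jmat.T))

    state = rng.integers(0, q, size=(nc, l))

    def sweep():
        for i in range(l):
            logits = np.broadcast_to(model.fields[i], (nc, q)).copy()
            for j, jmat in neighbors[i]:
                logits += jmat[:, state[:, j]].T
            logits *= beta
            logits -= logits.max(axis=1, keepdims=True)
            p = np.exp(logits)
            p /= p.sum(axis=1, keepdims=True)
            u = rng.random((nc, 1))
            state[:, i] = (p.cumsum(axis=1) < u).sum(axis=1)

    for _ in range(burn_in):
        sweep()
    samples = []
    while sum(len(s) for s in samples) < M:
        samples.append(state.copy())
        for _ in range(max(thin, 1)):
            sweep()
    seqs = np.concatenate(samples)[:M]
    # states 0..q-1 map onto the first q alphabet letters; q <= 21
    labels = [f"sample_{k}" for k in range(M)]
    msa = MSA(seqs.astype(np.int8), labels, q=q,
              metadata={"planted_pairs": model.planted_pairs,
                        "beta": beta, "seed": seed})
    return msa


def helix_coords(n: int, rise: float = 1.5, radius: float = 2.3,
                 twist_deg: float = 100.0) -> np.ndarray:
    """Idealized C-alpha helix along z, centered at the origin."""
    k = np.arange(n)
    theta = np.deg2rad(twist_deg) * k
    z = rise * (k - (n - 1) / 2.0)
    return np.column_stack([radius * np.cos(theta), radius * np.sin(theta), z])


_TOY_SEQ_LETTERS = ALPHABET[1:]  # 20 amino acids


def _toy_structure(n: int, d: float, seed: int) -> CaStructure:
    """Two-chain toy: chain B is chain A rotated 180 deg about the x-axis
    and shifted by ``d`` along y — a proper two-fold (C2) operation."""
    a = helix_coords(n)
    rot = np.diag([1.0, -1.0, -1.0])
    b = a @ rot.T + np.array([0.0, d, 0.0])
    rng = np.random.default_rng(seed)
    letters = rng.choice(list(_TOY_SEQ_LETTERS), size=n)
    seq = np.concatenate([letters, letters])
    chain_ids = np.array(["A"] * n + ["B"] * n)
    res_numbers = np.concatenate([np.arange(1, n + 1), np.arange(1, n + 1)])
    ca = np.vstack([a, b])
    # one dummy sphere per bead, sized so an isolated bead's accessible area
    # equals the residue type's tabulated maximum (relative SASA of a fully
    # exposed bead == 1)
    from coevdock.structure import MAX_SASA
    radii = np.array([np.sqrt(MAX_SASA[l] / (4 * np.pi)) - 1.4 for l in seq])
    return CaStructure(chain_ids, res_numbers, seq, ca,
                       atom_coords=ca.copy(),
                       atom_res=np.arange(2 * n),
                       atom_radii=radii)


def _cross_pairs(s: CaStructure, n: int, cutoff: float) -> list[tuple[int, int]]:
    cm = contact_map(s, cutoff)
    pairs = set()
    for i, j in cm.pairs:
        if i < n <= j:
            a, b = i, j - n
            if a != b:
                pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def build_toy_dimer(n: int = 30, interface_size: int = 8,
                    seed: int = 0, cutoff: float = 8.0,
                    min_clearance: float = 4.0) -> ToyDimer:
    """Toy homodimer with a known symmetric interface.

    Chain A is an idealized helix (rise 1.5 A, radius 2.3 A, 100 deg
    twist); chain B is a C2-rotated copy translated until exactly
    ``interface_size`` distinct single-chain position pairs appear as
    cross-chain contacts under ``cutoff``.  Beads carry dummy spheres so
    the solvent-accessibility machinery is exercisable.
    """
    if n < 10:
        raise SynthesisError("need at least 10 beads per chain")
    if not (1 <= interface_size <= n):
        raise SynthesisError(f"interface_size must lie in [1, {n}]")
    best = None
    for d in np.arange(25.0, min_clearance, -0.02):
        s = _toy_structure(n, float(d), seed)
        a, b = s.ca[:n], s.ca[n:]
        mind = np.min(np.linalg.norm(a[:, None] - b[None, :], axis=2))
        if mind < min_clearance:
            break
        pairs = _cross_pairs(s, n, cutoff)
        if len(pairs) == interface_size:
            best = (float(d), s, pairs)
            break
        if len(pairs) > interface_size:
            break
    if best is None:
        raise SynthesisError(
            f"infeasible packing: no separation realizes exactly "
            f"{interface_size} interface pairs for n={n}")
    d, s, pairs = best
    return ToyDimer(native=s, n=n, interface_pairs=pairs, contact_cutoff=cutoff,
                    meta={"separation": d, "seed": seed})


def plant_interface_couplings(dimer: ToyDimer, q: int = 8, beta: float = 1.0,
                              coupling_strength: float = 2.0) -> PottsModel:
    """Potts model whose planted pairs are exactly the toy dimer's interface
    pairs (single-chain indexing), with diagonal-favoring couplings
    ``J_ij(a, b) = strength * delta_ab`` and zero fields."""
    if not dimer.interface_pairs:
        raise SynthesisError("dimer has an empty interface")
    jmat = coupling_strength * np.eye(q)
    couplings = {pair: jmat.copy() for pair in dimer.interface_pairs}
    return PottsModel(L=dimer.n, q=q, fields=np.zeros((dimer.n, q)),
                      couplings=couplings, beta=beta)


def random_potts(L: int, q: int, n_planted: int, coupling_strength: float = 2.0,
                 beta: float = 1.0, min_separation: int = 2,
                 seed: int | None = None) -> PottsModel:
    """Potts model with ``n_planted`` random well-separated planted pairs
    (diagonal-favoring couplings, zero fields)."""
    rng = np.random.default_rng(seed)
    pairs: set[tuple[int, int]] = set()
    tries = 0
    while len(pairs) < n_planted:
        i, j = sorted(rng.integers(0, L, size=2).tolist())
        if j - i >= max(min_separation, 1) and (i, j) not in pairs:
            pairs.add((i, j))
        tries += 1
        if tries > 10000:
            raise SynthesisError("could not place the requested planted pairs")
    jmat = coupling_strength * np.eye(q)
    return PottsModel(L=L, q=q, fields=np.zeros((L, q)),
                      couplings={p: jmat.copy() for p in sorted(pairs)}, beta=beta)
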