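"""C-alpha structure handling.

A :class:`CaStructure` stores per-residue chain labels, author residue
numbers, one-letter amino-acid codes and C-alpha coordinates, plus an
optional flat table of all atoms (needed for solvent accessibility).
Operations: PDB reading/writing, C-alpha contact maps, Shrake-Rupley
solvent-accessible surface area, symmetry-mate generation and construction
of the separated, rotated initial pose used to start binding simulations.
"""

from __future__ import annotations

import logging
import string
import warnings
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdbio
from biotite.sequence import ProteinSequence
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


class StructureError(ValueError):
    """Raised for malformed structural input."""


# van-der-Waals radii (A) by element; fallback 1.7 (carbon-like)
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20,
             "P": 1.80, "SE": 1.90}
DEFAULT_VDW = 1.70

# Theoretical maximum SASA (A^2) per residue type, Tien et al. 2013,
# used to normalize absolute SASA into relative SASA.
MAX_SASA = {
    "A": 129.0, "R": 274.0, "N": 195.0, "D": 193.0, "C": 167.0,
    "Q": 225.0, "E": 223.0, "G": 104.0, "H": 224.0, "I": 197.0,
    "L": 201.0, "K": 236.0, "M": 224.0, "F": 240.0, "P": 159.0,
    "S": 155.0, "T": 172.0, "W": 285.0, "Y": 263.0, "V": 174.0,
}


@dataclass
class CaStructure:
    """Per-residue C-alpha model with optional full-atom coordinates.

    ``atom_*`` arrays form one flat table over all atoms; ``atom_res`` maps
    each atom to its residue index.  ``atom_radii`` carries van-der-Waals
    radii so synthetic structures can attach dummy spheres of any size.
    """

    chain_ids: np.ndarray        # (n,) chain label per residue
    res_numbers: np.ndarray      # (n,) author residue numbers
    seq: np.ndarray              # (n,) one-letter codes
    ca: np.ndarray               # (n, 3) C-alpha coordinates, A
    atom_coords: np.ndarray | None = None   # (n_atoms, 3)
    atom_res: np.ndarray | None = None      # (n_atoms,) residue index
    atom_radii: np.ndarray | None = None    # (n_atoms,) vdW radii, A

    def __post_init__(self) -> None:
        self.ca = np.asarray(self.ca, dtype=float)
        self.chain_ids = np.asarray(self.chain_ids)
        self.res_numbers = np.asarray(self.res_numbers, dtype=int)
        self.seq = np.asarray(self.seq)
        if self.ca.ndim != 2 or self.ca.shape[1] != 3:
            raise StructureError("ca must be (n, 3)")
        if len(self.ca) < 2:
            raise StructureError("structure needs at least 2 residues")
        if not np.all(np.isfinite(self.ca)):
            raise StructureError("non-finite C-alpha coordinates")

    @property
    def n_residues(self) -> int:
        return len(self.ca)

    @property
    def chains(self) -> list[str]:
        """Ordered unique chain labels."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(str(c), None)
        return list(seen)

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_ids == chain

    def select_chains(self, chains) -> "CaStructure":
        """Sub-structure restricted to the given chains (order preserved)."""
        chains = list(chains)
        missing = [c for c in chains if c not in self.chains]
        if missing:
            raise StructureError(f"chain(s) not present: {missing} (have {self.chains})")
        mask = np.isin(self.chain_ids, chains)
        idx = np.where(mask)[0]
        atom_coords = atom_res = atom_radii = None
        if self.atom_coords is not None:
            amask = np.isin(self.atom_res, idx)
            remap = -np.ones(self.n_residues, dtype=int)
            remap[idx] = np.arange(len(idx))
            atom_coords = self.atom_coords[amask]
            atom_res = remap[self.atom_res[amask]]
            atom_radii = self.atom_radii[amask]
        return CaStructure(self.chain_ids[mask], self.res_numbers[mask],
                           self.seq[mask], self.ca[mask],
                           atom_coords, atom_res, atom_radii)

    def sequence_str(self, chain: str | None = None) -> str:
        mask = slice(None) if chain is None else self.chain_mask(chain)
        return "".join(self.seq[mask])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "CaStructure":
        """Rigidly transformed copy: ``x -> R x + t``."""
        r = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        atom_coords = None if self.atom_coords is None else self.atom_coords @ r.T + t
        return CaStructure(self.chain_ids.copy(), self.res_numbers.copy(),
                           self.seq.copy(), self.ca @ r.T + t,
                           atom_coords,
                           None if self.atom_res is None else self.atom_res.copy(),
                           None if self.atom_radii is None else self.atom_radii.copy())


@dataclass
class ContactMap:
    """Set of residue pairs with C-alpha distance below a cutoff."""

    n: int
    pairs: set[tuple[int, int]]          # (i, j) with i < j
    cutoff: float
    distances: dict[tuple[int, int], float] = field(default_factory=dict)
    dmat: np.ndarray | None = None       # full pairwise distance matrix

    def __contains__(self, pair) -> bool:
        i, j = pair
        return (min(i, j), max(i, j)) in self.pairs


@dataclass
class SasaProfile:
    """Per-residue absolute (A^2) and relative solvent accessibility."""

    absolute: np.ndarray
    relative: np.ndarray
    flagged: list[int] = field(default_factory=list)  # residues with missing atoms


def read_pdb(path, chain_selection=None) -> CaStructure:
    """Read a PDB file into a :class:`CaStructure`.

    First model only; alternate locations resolved by highest occupancy;
    heteroatoms and waters dropped.  Residues without a C-alpha are dropped
    with a warning; an empty result is an error.
    """
    pdb_file = pdbio.PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1, altloc="occupancy")
    arr = arr[struc.filter_amino_acids(arr) & ~arr.hetero]
    if arr.array_length() == 0:
        raise StructureError(f"no protein atoms in {path}")
    if chain_selection is not None:
        wanted = list(chain_selection)
        present = set(np.unique(arr.chain_id))
        missing = [c for c in wanted if c not in present]
        if missing:
            raise StructureError(
                f"requested chain(s) {missing} not present in {path} "
                f"(available: {sorted(present)})")
        arr = arr[np.isin(arr.chain_id, wanted)]

    starts = struc.get_residue_starts(arr)
    chain_ids, res_numbers, seq, ca = [], [], [], []
    atom_coords, atom_res, atom_radii = [], [], []
    bounds = list(starts) + [arr.array_length()]
    kept = 0
    for s, e in zip(bounds[:-1], bounds[1:]):
        names = arr.atom_name[s:e]
        ca_idx = np.where(names == "CA")[0]
        if len(ca_idx) == 0:
            warnings.warn(
                f"residue {arr.res_name[s]} {arr.res_id[s]} (chain {arr.chain_id[s]}) "
                "has no C-alpha; dropped")
            continue
        try:
            one = ProteinSequence.convert_letter_3to1(arr.res_name[s])
        except KeyError:
            one = "X"
        chain_ids.append(str(arr.chain_id[s]))
        res_numbers.append(int(arr.res_id[s]))
        seq.append(one)
        ca.append(arr.coord[s:e][ca_idx[0]])
        for k in range(s, e):
            atom_coords.append(arr.coord[k])
            atom_res.append(kept)
            atom_radii.append(VDW_RADII.get(str(arr.element[k]).upper(), DEFAULT_VDW))
        kept += 1
    if kept == 0:
        raise StructureError(f"no usable residues in {path}")
    return CaStructure(np.array(chain_ids), np.array(res_numbers), np.array(seq),
                       np.array(ca), np.array(atom_coords), np.array(atom_res),
                       np.array(atom_radii))


_ONE_TO_THREE = {v: k for k, v in ProteinSequence._dict_3to1.items()} \
    if hasattr(ProteinSequence, "_dict_3to1") else {}


def _one_to_three(letter: str) -> str:
    try:
        return ProteinSequence.convert_letter_1to3(letter)
    except KeyError:
        return "UNK"


def write_pdb(s: CaStructure, path, coords: np.ndarray | None = None) -> None:
    """Write C-alpha ATOM records (chain IDs preserved).

    ``coords`` optionally overrides the stored C-alpha coordinates (used to
    dump trajectory frames against a fixed topology).
    """
    xyz = s.ca if coords is None else np.asarray(coords, float)
    arr = struc.AtomArray(s.n_residues)
    arr.coord = xyz
    arr.chain_id = np.array([str(c) for c in s.chain_ids])
    arr.res_id = s.res_numbers
    arr.res_name = np.array([_one_to_three(l) for l in s.seq])
    arr.atom_name = np.array(["CA"] * s.n_residues)
    arr.element = np.array(["C"] * s.n_residues)
    pdb_file = pdbio.PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def contact_map(s: CaStructure, cutoff: float = 8.0) -> ContactMap:
    """C-alpha contact map: ``(i, j)`` is a contact iff the distance is
    strictly below ``cutoff`` and ``i < j``."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    d = squareform(pdist(s.ca))
    iu, ju = np.triu_indices(s.n_residues, k=1)
    mask = d[iu, ju] < cutoff
    pairs = set(zip(iu[mask].tolist(), ju[mask].tolist()))
    distances = {(int(i), int(j)): float(d[i, j])
                 for i, j in zip(iu[mask], ju[mask])}
    return ContactMap(n=s.n_residues, pairs=pairs, cutoff=cutoff,
                      distances=distances, dmat=d)


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` quasi-uniform points on the unit sphere (Fibonacci lattice)."""
    k = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sasa(s: CaStructure, probe: float = 1.4, n_points: int = 960) -> SasaProfile:
    """Shrake-Rupley numerical solvent-accessible surface area.

    Each atom's sphere (vdW radius + probe) is sampled at ``n_points``
    quasi-uniform points; a point counts as exposed if it lies outside every
    neighboring atom's expanded sphere.  Residue SASA sums its atoms;
    relative SASA divides by the residue type's tabulated maximum, falling
    back to the residue's isolated-atom area for unknown types (synthetic
    dummy beads).
    """
    if s.atom_coords is None:
        raise StructureError("full-atom coordinates required for SASA")
    if probe <= 0:
        raise ValueError("probe radius must be positive")
    coords = s.atom_coords
    radii = s.atom_radii + probe
    n_atoms = len(coords)
    sphere = fibonacci_sphere(n_points)
    exposed_area = np.zeros(n_atoms)
    # neighbor lists via one distance matrix; structures here are small
    d = squareform(pdist(coords)) if n_atoms > 1 else np.zeros((1, 1))
    for a in range(n_atoms):
        pts = coords[a] + radii[a] * sphere
        nbr = np.where((d[a] < radii[a] + radii.max()) & (np.arange(n_atoms) != a))[0]
        nbr = nbr[d[a, nbr] < radii[a] + radii[nbr]]
        free = np.ones(n_points, dtype=bool)
        for b in nbr:
            free &= np.einsum("ij,ij->i", pts - coords[b], pts - coords[b]) > radii[b] ** 2
            if not free.any():
                break
        exposed_area[a] = 4.0 * np.pi * radii[a] ** 2 * free.sum() / n_points

    absolute = np.zeros(s.n_residues)
    np.add.at(absolute, s.atom_res, exposed_area)
    relative = np.zeros(s.n_residues)
    flagged = []
    for r in range(s.n_residues):
        letter = str(s.seq[r])
        atoms = np.where(s.atom_res == r)[0]
        if letter in MAX_SASA and len(atoms) > 3:
            ref = MAX_SASA[letter]
        else:
            # isolated-atom reference: dummy beads and incomplete residues
            ref = float(np.sum(4.0 * np.pi * (s.atom_radii[atoms] + probe) ** 2))
            if letter in MAX_SASA and len(atoms) <= 3:
                flagged.append(r)
        relative[r] = absolute[r] / ref if ref > 0 else 0.0
    if flagged:
        logger.info("SASA computed from incomplete atom sets for residues %s", flagged)
    return SasaProfile(absolute=absolute, relative=relative, flagged=flagged)


def _check_rotation(rotation: np.ndarray) -> np.ndarray:
    r = np.asarray(rotation, dtype=float)
    if r.shape != (3, 3) or not np.allclose(r @ r.T, np.eye(3), atol=1e-8) \
            or not np.isclose(np.linalg.det(r), 1.0, atol=1e-8):
        raise StructureError("rotation must be a proper orthonormal 3x3 matrix (det +1)")
    return r


def make_symmetry_mate(s: CaStructure, rotation: np.ndarray,
                       translation: np.ndarray) -> CaStructure:
    """Append a rigidly transformed copy of the structure as a new chain.

    Used to complete homodimers whose crystal asymmetric unit contains only
    one monomer.
    """
    r = _check_rotation(rotation)
    t = np.asarray(translation, dtype=float)
    mate = s.transformed(r, t)
    used = set(s.chains)
    fresh = [c for c in string.ascii_uppercase if c not in used]
    relabel = {old: fresh[k] for k, old in enumerate(mate.chains)}
    mate_chain_ids = np.array([relabel[str(c)] for c in mate.chain_ids])

    atom_coords = atom_res = atom_radii = None
    if s.atom_coords is not None:
        atom_coords = np.vstack([s.atom_coords, mate.atom_coords])
        atom_res = np.concatenate([s.atom_res, mate.atom_res + s.n_residues])
        atom_radii = np.concatenate([s.atom_radii, mate.atom_radii])
    return CaStructure(
        np.concatenate([s.chain_ids, mate_chain_ids]),
        np.concatenate([s.res_numbers, mate.res_numbers]),
        np.concatenate([s.seq, mate.seq]),
        np.vstack([s.ca, mate.ca]),
        atom_coords, atom_res, atom_radii)


def _rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation matrix."""
    u = np.asarray(axis, float)
    u = u / np.linalg.norm(u)
    k = np.array([[0, -u[2], u[1]], [u[2], 0, -u[0]], [-u[1], u[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def build_initial_pose(dimer: CaStructure, separation: float = 50.0,
                       rotate_axis: str = "centroid", angle_deg: float = 180.0,
                       seed: int | None = None) -> CaStructure:
    """Separate a two-chain dimer and scramble the relative orientation.

    The second chain is translated along the line joining the chain
    centroids until the centroid distance increases by ``separation``, then
    rotated by ``angle_deg`` about that axis through its own centroid
    (``rotate_axis='centroid'``) or about a seeded random axis
    (``rotate_axis='random'``).  With the default 50 A separation the output
    retains no native inter-chain contacts at 8 A.
    """
    chains = dimer.chains
    if len(chains) != 2:
        raise StructureError(f"initial pose needs exactly two chains, got {chains}")
    if rotate_axis not in ("centroid", "random"):
        raise ValueError("rotate_axis must be 'centroid' or 'random'")
    a = dimer.select_chains([chains[0]])
    b = dimer.select_chains([chains[1]])
    ca_cent = a.ca.mean(axis=0)
    cb_cent = b.ca.mean(axis=0)
    axis = cb_cent - ca_cent
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        axis = np.array([0.0, 0.0, 1.0])  # superposed chains: arbitrary axis
    else:
        axis = axis / norm
    b_shift = b.transformed(np.eye(3), separation * axis)

    angle = np.deg2rad(angle_deg)
    if angle != 0.0:
        if rotate_axis == "random":
            rng = np.random.default_rng(seed)
            v = rng.normal(size=3)
            rot_axis = v / np.linalg.norm(v)
        else:
            rot_axis = axis
        r = _rotation_about_axis(rot_axis, angle)
        cent = b_shift.ca.mean(axis=0)
        b_shift = b_shift.transformed(r, cent - r @ cent)

    atom_coords = atom_res = atom_radii = None
    if a.atom_coords is not None and b_shift.atom_coords is not None:
        atom_coords = np.vstack([a.atom_coords, b_shift.atom_coords])
        atom_res = np.concatenate([a.atom_res, b_shift.atom_res + a.n_residues])
        atom_radii = np.concatenate([a.atom_radii, b_shift.atom_radii])
    return CaStructure(
        np.concatenate([a.chain_ids, b_shift.chain_ids]),
        np.concatenate([a.res_numbers, b_shift.res_numbers]),
        np.concatenate([a.seq, b_shift.seq]),
        np.vstack([a.ca, b_shift.ca]),
        atom_coords, atom_res, atom_radii)


def write_contact_map(cm: ContactMap, path) -> None:
    """Contact map as TSV ``i\\tj\\tdistance``."""
    with open(path, "w") as fh:
        fh.write("i\tj\tdistance\n")
        for i, j in sorted(cm.pairs):
            fh.write(f"{i}\t{j}\t{cm.distances.get((i, j), float('nan')):.4f}\n")
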