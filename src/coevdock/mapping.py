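"""Alignment-column to structure-residue mapping.

Real protein-family alignments are mapped onto structures with profile-HMM
tools (e.g. hmmscan); the output of such a tool can be supplied here as a
two-column table.  As a fallback, a global pairwise alignment between the
alignment's consensus sequence and the structure's sequence produces a
collinear mapping.  Results for real family alignments should prefer the
external table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align

from coevdock.alignment import MSA
from coevdock.structure import CaStructure

logger = logging.getLogger(__name__)


class MappingError(ValueError):
    """Raised when a column-to-residue mapping cannot be established."""


@dataclass
class ResidueMapping:
    """Collinear mapping of alignment columns onto structure residues.

    ``pairs`` holds ``(alignment_column, residue_index)``, both 0-based,
    strictly increasing on both sides; ``coverage`` is the fraction of
    alignment columns mapped.
    """

    pairs: list[tuple[int, int]]
    coverage: float

    def __post_init__(self) -> None:
        cols = [c for c, _ in self.pairs]
        residues = [r for _, r in self.pairs]
        if sorted(set(cols)) != cols or sorted(set(residues)) != residues:
            raise MappingError("mapping must be strictly increasing and duplicate-free "
                               "on both columns and residues (collinear)")

    def column_to_residue(self) -> dict[int, int]:
        return dict(self.pairs)

    def residue_to_column(self) -> dict[int, int]:
        return {r: c for c, r in self.pairs}


def read_mapping_table(path) -> list[tuple[int, int]]:
    """Read a TSV mapping table with header ``aln_col\\tres_index``."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != ["aln_col", "res_index"]:
        raise MappingError(
            f"mapping table must have header 'aln_col\\tres_index', got {list(df.columns)}")
    return [(int(c), int(r)) for c, r in zip(df["aln_col"], df["res_index"])]


def map_alignment_to_structure(msa: MSA, structure: CaStructure,
                               method: str = "pairwise",
                               table: list[tuple[int, int]] | None = None,
                               chain: str | None = None,
                               min_coverage: float = 0.30,
                               match: float = 1.0, mismatch: float = -1.0,
                               gap: float = -2.0) -> ResidueMapping:
    """Map alignment columns to residue indices of ``structure``.

    ``method='pairwise'`` globally aligns the alignment's consensus sequence
    (most frequent non-gap state per column) against the structure sequence
    (match +1, mismatch -1, gap -2 by default) and keeps aligned positions,
    matched or substituted.  ``method='external_table'`` takes a
    user-supplied two-column table (e.g. derived from hmmscan output).

    Raises :class:`MappingError` when coverage falls below ``min_coverage``,
    which signals a wrong family/structure pairing.
    """
    if chain is not None:
        structure = structure.select_chains([chain])
    if method == "external_table":
        if table is None:
            raise MappingError("external_table method requires a mapping table")
        pairs = [(int(c), int(r)) for c, r in table]
        for _, r in pairs:
            if r < 0 or r >= structure.n_residues:
                raise MappingError(f"residue index {r} outside structure (n={structure.n_residues})")
        mapping = ResidueMapping(pairs, coverage=len(pairs) / msa.L)
    elif method == "pairwise":
        consensus = msa.consensus()
        target = structure.sequence_str()
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = match
        aligner.mismatch_score = mismatch
        aligner.open_gap_score = gap
        aligner.extend_gap_score = gap
        aln = aligner.align(consensus, target)[0]
        pairs = []
        for (cs, ce), (rs, re) in zip(aln.aligned[0], aln.aligned[1]):
            pairs.extend((cs + k, rs + k) for k in range(ce - cs))
        mapping = ResidueMapping(pairs, coverage=len(pairs) / msa.L)
    else:
        raise ValueError(f"unknown mapping method: {method!r}")

    if mapping.coverage < min_coverage:
        raise MappingError(
            f"mapping failed: coverage {mapping.coverage:.2f} < {min_coverage:.2f} "
            "(alignment and structure are probably from different families)")
    return mapping


def map_ranking(ranking, mapping: ResidueMapping):
    """Translate a DI ranking from alignment columns to residue indices.

    Pairs involving unmapped columns are dropped and logged; order is
    preserved.  Returns a new ranking in residue-index space.
    """
    from coevdock.dca import DIRanking

    col2res = mapping.column_to_residue()
    entries, dropped = [], []
    for i, j, di in ranking.entries:
        if i in col2res and j in col2res:
            a, b = col2res[i], col2res[j]
            entries.append((min(a, b), max(a, b), di))
        else:
            dropped.append((i, j))
    if dropped:
        logger.info("dropped %d DI pairs with unmapped columns: %s",
                    len(dropped), dropped[:10])
    return DIRanking(entries=entries, meta={**ranking.meta, "mapped": True,
                                            "dropped_unmapped": len(dropped)})


def write_mapping(mapping: ResidueMapping, path) -> None:
    with open(path, "w") as fh:
        fh.write("aln_col\tres_index\n")
        for c, r in mapping.pairs:
            fh.write(f"{c}\t{r}\n")
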