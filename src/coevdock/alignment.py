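"""Multiple sequence alignment I/O and integer encoding.

Alignments are encoded over a 21-letter alphabet: state 0 is the gap and
states 1..20 are the twenty standard amino acids in alphabetical one-letter
order (``ACDEFGHIKLMNPQRSTVWY``).  Lowercase letters and ``.`` characters
(insert states in Stockholm files) as well as ambiguous letters
(``B``, ``J``, ``O``, ``U``, ``X``, ``Z``) are mapped to the gap state.
Mean-field DCA results are invariant to the alphabet order, but serialized
models record it so downstream consumers can decode parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

#: Alphabet used for integer encoding; index in this string == integer state.
ALPHABET = "-ACDEFGHIKLMNPQRSTVWY"

#: Number of states: 20 amino acids + gap.
Q = len(ALPHABET)

_ENCODE = np.zeros(256, dtype=np.int8)  # default: unknown byte -> gap (0)
for _state, _letter in enumerate(ALPHABET):
    _ENCODE[ord(_letter)] = _state
_ENCODE[ord(".")] = 0


class AlignmentError(ValueError):
    """Raised for malformed alignment input."""


@dataclass
class MSA:
    """Integer-encoded gapped alignment.

    Attributes
    ----------
    sequences:
        ``(M, L)`` int8 matrix; entry in ``[0, q)``.
    labels:
        ``M`` sequence identifiers.
    q:
        Alphabet size (21).
    metadata:
        Free-form provenance (e.g. planted couplings for synthetic data).
    """

    sequences: np.ndarray
    labels: list[str]
    q: int = Q
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sequences = np.asarray(self.sequences, dtype=np.int8)
        if self.sequences.ndim != 2:
            raise AlignmentError("sequences must be a 2-D matrix")
        m, l = self.sequences.shape
        if m < 2 or l < 2:
            raise AlignmentError(f"alignment too small: M={m}, L={l} (need M>=2, L>=2)")
        if len(self.labels) != m:
            raise AlignmentError("number of labels does not match number of rows")
        if self.sequences.min() < 0 or self.sequences.max() >= self.q:
            raise AlignmentError(f"states must lie in [0, {self.q})")

    @property
    def M(self) -> int:
        """Number of sequences."""
        return self.sequences.shape[0]

    @property
    def L(self) -> int:
        """Number of alignment columns."""
        return self.sequences.shape[1]

    def decode(self) -> list[str]:
        """Return the alignment as uppercase/gap text, one string per row."""
        lut = np.frombuffer(ALPHABET.encode(), dtype="S1")
        return [b"".join(lut[row]).decode() for row in self.sequences]

    def consensus(self) -> str:
        """Most frequent non-gap state per column; ``X`` for all-gap columns."""
        out = []
        for col in self.sequences.T:
            counts = np.bincount(col, minlength=self.q)
            counts[0] = 0
            out.append(ALPHABET[int(np.argmax(counts))] if counts.sum() else "X")
        return "".join(out)


def encode_sequences(seqs: list[str], labels: list[str], metadata: dict | None = None) -> MSA:
    """Encode aligned text sequences into an :class:`MSA`."""
    if not seqs:
        raise AlignmentError("empty alignment")
    length = len(seqs[0])
    for label, s in zip(labels, seqs):
        if len(s) != length:
            raise AlignmentError(
                f"ragged alignment: sequence '{label}' has length {len(s)}, expected {length}"
            )
    mat = np.vstack(
        [_ENCODE[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs]
    )
    return MSA(mat, list(labels), metadata=metadata or {})


def read_alignment(path, format: str = "fasta") -> MSA:
    """Read a FASTA or Stockholm alignment into an integer-encoded :class:`MSA`.

    Uppercase amino acids map to states 1..20 (alphabetical order); gaps
    (``-``, ``.``), lowercase insert states and ambiguous letters map to the
    gap state 0.

    Raises
    ------
    AlignmentError
        If the file is empty, or (FASTA) sequences have unequal lengths; the
        error names the offending sequence.
    """
    if format not in ("fasta", "stockholm"):
        raise ValueError(f"unsupported format: {format!r}")
    if format == "fasta":
        records = list(SeqIO.parse(str(path), "fasta"))
    else:
        try:
            records = list(AlignIO.read(str(path), "stockholm"))
        except ValueError as exc:
            raise AlignmentError(f"could not parse Stockholm file {path}: {exc}") from exc
    if not records:
        raise AlignmentError(f"empty alignment file: {path}")
    seqs = [str(r.seq) for r in records]
    labels = [r.id for r in records]
    return encode_sequences(seqs, labels)


def write_alignment(msa: MSA, path) -> None:
    """Write an MSA back out as aligned FASTA."""
    with open(path, "w") as fh:
        for label, text in zip(msa.labels, msa.decode()):
            fh.write(f">{label}\n{text}\n")
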