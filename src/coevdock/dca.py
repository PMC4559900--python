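"""Mean-field direct coupling analysis (mfDCA).

Given an encoded alignment, the steps are:

1. similarity-based sequence reweighting (threshold ``theta``), giving an
   effective sequence count ``Meff``;
2. pseudocount-regularized single-site and pair frequencies
   (pseudocount mass ``lambda``);
3. mean-field inversion of the connected-correlation matrix, yielding
   pairwise couplings ``e_ij(a, b)`` in the gauge where the last alphabet
   state is zeroed;
4. direct information (DI): the mutual information of the two-site model
   built from one pair's couplings with single-site marginals re-imposed by
   fixed-point iteration; pairs are ranked by DI descending.

DI separates direct statistical coupling from transitive correlation and is
used as a plausibility ranking for residue-residue contacts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from coevdock.alignment import ALPHABET, MSA

logger = logging.getLogger(__name__)


class ConvergenceError(RuntimeError):
    """Raised when the two-site marginal matching does not converge."""


@dataclass
class FrequencyModel:
    """Reweighted, pseudocount-regularized alignment statistics."""

    weights: np.ndarray          # (M,) positive sequence weights
    Meff: float                  # sum of weights
    theta: float                 # reweighting similarity threshold
    lam: float                   # pseudocount mass (lambda)
    f_i: np.ndarray              # (L, q) single-site frequencies
    f_ij: np.ndarray             # (L, L, q, q) pair frequencies
    q: int = 21

    @property
    def L(self) -> int:
        return self.f_i.shape[0]


@dataclass
class CouplingModel:
    """Mean-field couplings and the connected-correlation matrix.

    ``e_ij`` has shape ``(L, L, q, q)`` with the last state's row and column
    zero (gauge); only off-diagonal position blocks are meaningful.
    """

    e_ij: np.ndarray
    C: np.ndarray
    q: int = 21

    @property
    def L(self) -> int:
        return self.e_ij.shape[0]


@dataclass
class DIRanking:
    """Ordered position pairs with direct-information scores.

    ``entries`` is a list of ``(i, j, DI)`` with ``i < j``, sorted by DI
    descending, ties broken by ``(i, j)`` lexicographic.
    """

    entries: list[tuple[int, int, float]]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, _ in self.entries]


def compute_weights(msa: MSA, theta: float = 0.8) -> tuple[np.ndarray, float]:
    """Similarity-based sequence reweighting.

    The weight of sequence ``s`` is ``1 / |{t : id(s, t) >= theta}|`` where
    ``id`` is the fraction of identical positions (gaps included, self
    included).  ``Meff`` is the sum of weights.
    """
    if not (0 < theta <= 1):
        raise ValueError(f"theta must lie in (0, 1], got {theta}")
    seqs = msa.sequences
    m, l = seqs.shape
    counts = np.zeros(m, dtype=np.int64)
    # chunked pairwise identity; O(M^2 L) but vectorized over the chunk
    chunk = max(1, int(2e7 // (m * l + 1)) or 1)
    thresh = theta * l
    for start in range(0, m, chunk):
        block = seqs[start : start + chunk]
        ident = (block[:, None, :] == seqs[None, :, :]).sum(axis=2)
        counts[start : start + chunk] = (ident >= thresh - 1e-9).sum(axis=1)
    weights = 1.0 / counts
    return weights, float(weights.sum())


def compute_frequencies(msa: MSA, weights: np.ndarray, lam: float) -> FrequencyModel:
    """Pseudocount-regularized weighted frequencies.

    ``f_i(a) = (lam/q + sum_s w_s [s_i = a]) / (lam + Meff)`` and analogously
    for pairs with ``lam/q^2``; the diagonal blocks follow the convention
    ``f_ii(a, b) = delta_ab f_i(a)``.
    """
    if lam < 0:
        raise ValueError("pseudocount mass must be nonnegative")
    seqs = msa.sequences
    m, l = seqs.shape
    q = msa.q
    weights = np.asarray(weights, dtype=float)
    meff = weights.sum()

    onehot = np.zeros((m, l, q), dtype=np.float64)
    onehot[np.arange(m)[:, None], np.arange(l)[None, :], seqs] = 1.0

    f_i = (lam / q + np.einsum("s,sla->la", weights, onehot)) / (lam + meff)

    flat = onehot.reshape(m, l * q)
    pair = (flat * weights[:, None]).T @ flat  # (L q, L q) weighted pair counts
    f_ij = (lam / q**2 + pair.reshape(l, q, l, q).transpose(0, 2, 1, 3)) / (lam + meff)
    # diagonal convention: f_ii(a,b) = delta_ab * f_i(a)
    for i in range(l):
        f_ij[i, i] = np.diag(f_i[i])

    return FrequencyModel(weights=weights, Meff=float(meff), theta=np.nan, lam=lam,
                          f_i=f_i, f_ij=f_ij, q=q)


def invert_mean_field(freq: FrequencyModel) -> CouplingModel:
    """Mean-field inversion: couplings are minus the inverse of the
    connected-correlation matrix restricted to the first ``q - 1`` states
    (last state zeroed by gauge); diagonal position blocks of the inverse are
    not couplings and are discarded.
    """
    l, q = freq.L, freq.q
    qr = q - 1
    c = (freq.f_ij[:, :, :qr, :qr]
         - freq.f_i[:, None, :qr, None] * freq.f_i[None, :, None, :qr])
    cmat = c.transpose(0, 2, 1, 3).reshape(l * qr, l * qr)
    try:
        cinv = scipy.linalg.inv(cmat)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "connected-correlation matrix is singular; use a positive "
            "pseudocount (lambda > 0) to regularize"
        ) from exc
    e = np.zeros((l, l, q, q))
    eblocks = (-cinv).reshape(l, qr, l, qr).transpose(0, 2, 1, 3)
    e[:, :, :qr, :qr] = eblocks
    for i in range(l):
        e[i, i] = 0.0
    cfull = cmat  # keep the matrix actually inverted, in (i,a),(j,b) layout
    return CouplingModel(e_ij=e, C=cfull, q=q)


def _two_site_model(K: np.ndarray, fi: np.ndarray, fj: np.ndarray,
                    tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Joint distribution ``P(a,b) ∝ K(a,b) x(a) y(b)`` with marginals matched
    to ``fi``, ``fj``.

    Primary route: fixed-point (Sinkhorn-style) iteration with damping 0.5
    once oscillation is detected.  The fixed point converges only linearly
    and can be slow for sparse high-q statistics, so on non-convergence a
    quasi-Newton root find on the log-fields finishes the job; failure of
    both raises with diagnostics.
    """
    q = K.shape[0]
    x = np.ones(q)
    y = np.ones(q)
    prev_err = np.inf
    damping = 1.0
    for it in range(max_iter):
        x_new = fi / (K @ y)
        y_new = fj / (K.T @ x_new)
        x = damping * x_new + (1 - damping) * x
        y = damping * y_new + (1 - damping) * y
        p = K * np.outer(x, y)
        p /= p.sum()
        err = max(np.abs(p.sum(axis=1) - fi).max(), np.abs(p.sum(axis=0) - fj).max())
        if err < tol:
            return p
        if err > prev_err and damping > 0.5:
            damping = 0.5  # oscillation: damp the update
        prev_err = err

    import scipy.optimize

    def residual(logxy):
        px = K * np.outer(np.exp(logxy[:q]), np.exp(logxy[q:]))
        px /= px.sum()
        return np.concatenate([px.sum(axis=1) - fi, px.sum(axis=0) - fj])

    sol = scipy.optimize.root(residual, np.log(np.concatenate([x, y])),
                              method="hybr", options={"xtol": 1e-12})
    p = K * np.outer(np.exp(sol.x[:q]), np.exp(sol.x[q:]))
    p /= p.sum()
    err = max(np.abs(p.sum(axis=1) - fi).max(), np.abs(p.sum(axis=0) - fj).max())
    if err < tol:
        return p
    raise ConvergenceError(
        f"two-site marginal matching did not converge (fixed point "
        f"{max_iter} iterations, error {prev_err:.2e}; root find error "
        f"{err:.2e}; tol {tol:.0e})"
    )


def direct_information(coupling: CouplingModel, freq: FrequencyModel,
                       i: int, j: int) -> float:
    """Direct information of pair ``(i, j)``.

    Builds the two-site model ``P_dir(a,b) ∝ exp(e_ij(a,b)) h_i(a) h_j(b)``
    with auxiliary fields fixed by matching the marginals of ``P_dir`` to the
    empirical single-site frequencies, then returns the Kullback-Leibler
    divergence of ``P_dir`` from the independent product ``f_i f_j``.
    """
    if i == j:
        raise ValueError("direct information is defined for i != j")
    K = np.exp(coupling.e_ij[i, j])
    fi, fj = freq.f_i[i], freq.f_i[j]
    p = _two_site_model(K, fi, fj)
    ref = np.outer(fi, fj)
    mask = p > 1e-300
    di = float(np.sum(p[mask] * np.log(p[mask] / ref[mask])))
    # clamp below the numerical noise floor so exact ties stay exact
    return di if di > 1e-12 else 0.0


def rank_pairs(coupling: CouplingModel, freq: FrequencyModel,
               min_separation: int = 2) -> DIRanking:
    """All pairs with ``j - i >= min_separation`` sorted by DI descending,
    ties broken lexicographically by ``(i, j)``."""
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    entries = []
    for i in range(coupling.L):
        for j in range(i + max(min_separation, 1), coupling.L):
            entries.append((i, j, direct_information(coupling, freq, i, j)))
    entries.sort(key=lambda e: (-e[2], e[0], e[1]))
    return DIRanking(entries=entries)


def run_dca(msa: MSA, theta: float = 0.8, lam: float | None = None,
            min_separation: int = 2) -> tuple[DIRanking, FrequencyModel, CouplingModel]:
    """Full mfDCA pipeline: reweight, count, invert, rank.

    ``lam`` defaults to ``Meff`` (pseudocount mass equal to the effective
    sequence count, the conventional mean-field choice).
    """
    weights, meff = compute_weights(msa, theta)
    if lam is None:
        lam = meff
    freq = compute_frequencies(msa, weights, lam)
    freq.theta = theta
    coupling = invert_mean_field(freq)
    ranking = rank_pairs(coupling, freq, min_separation)
    ranking.meta = {"theta": theta, "lambda": lam, "Meff": meff,
                    "alphabet": ALPHABET, "min_separation": min_separation}
    return ranking, freq, coupling


def write_di_table(ranking: DIRanking, path) -> None:
    """Write the ranking as TSV ``i\\tj\\tDI`` (0-based columns) with a JSON
    sidecar recording theta, lambda, Meff and the alphabet."""
    with open(path, "w") as fh:
        fh.write("i\tj\tDI\n")
        for i, j, di in ranking.entries:
            fh.write(f"{i}\t{j}\t{di:.10g}\n")
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(ranking.meta, fh, indent=2)


def read_di_table(path) -> DIRanking:
    """Read a TSV DI table written by :func:`write_di_table`."""
    entries = []
    with open(path) as fh:
        header = fh.readline()
        if header.strip() != "i\tj\tDI":
            raise ValueError(f"unexpected DI table header: {header!r}")
        for line in fh:
            i, j, di = line.split("\t")
            entries.append((int(i), int(j), float(di)))
    meta = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    return DIRanking(entries=entries, meta=meta)
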