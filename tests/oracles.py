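"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a different route than the library
(brute-force enumeration, grid search, direct counting) so that agreement
is evidence of correctness rather than self-consistency.
"""

from __future__ import annotations

import itertools

import numpy as np


def weights_bruteforce(seqs: np.ndarray, theta: float) -> np.ndarray:
    """O(M^2 L) loop implementation of similarity reweighting."""
    m, l = seqs.shape
    weights = np.zeros(m)
    for s in range(m):
        count = 0
        for t in range(m):
            ident = sum(1 for k in range(l) if seqs[s, k] == seqs[t, k])
            if ident / l >= theta - 1e-12:
                count += 1
        weights[s] = 1.0 / count
    return weights


def frequencies_bruteforce(seqs: np.ndarray, weights: np.ndarray,
                           lam: float, q: int):
    """Direct weighted counting of single and pair frequencies."""
    m, l = seqs.shape
    meff = weights.sum()
    f_i = np.full((l, q), lam / q)
    for s in range(m):
        for i in range(l):
            f_i[i, seqs[s, i]] += weights[s]
    f_i /= lam + meff
    f_ij = np.full((l, l, q, q), lam / q ** 2)
    for s in range(m):
        for i in range(l):
            for j in range(l):
                f_ij[i, j, seqs[s, i], seqs[s, j]] += weights[s]
    f_ij /= lam + meff
    for i in range(l):
        f_ij[i, i] = np.diag(f_i[i])
    return f_i, f_ij


def di_two_state_oracle(e: np.ndarray, fi: np.ndarray, fj: np.ndarray,
                        grid: int = 20001) -> float:
    """Direct information for q = 2 by exhaustive grid search.

    The two-site model with couplings ``e`` and fixed marginals is the
    unique joint distribution with odds ratio
    ``R = K00 K11 / (K01 K10)`` (``K = exp(e)``) and the given marginals;
    the oracle finds ``p00`` on a fine grid minimizing the odds-ratio
    mismatch, then refines twice, and returns the KL divergence from the
    independent product.
    """
    K = np.exp(e)
    R = (K[0, 0] * K[1, 1]) / (K[0, 1] * K[1, 0])
    lo = max(0.0, fi[0] + fj[0] - 1.0) + 1e-12
    hi = min(fi[0], fj[0]) - 1e-12

    def mismatch(p00):
        p01 = fi[0] - p00
        p10 = fj[0] - p00
        p11 = 1.0 - fi[0] - fj[0] + p00
        return np.abs(p00 * p11 - R * p01 * p10)

    for _ in range(3):
        cand = np.linspace(lo, hi, grid)
        err = mismatch(cand)
        best = int(np.argmin(err))
        span = (hi - lo) / (grid - 1)
        lo = max(lo, cand[best] - 2 * span)
        hi = min(hi, cand[best] + 2 * span)
    p00 = cand[best]
    p = np.array([[p00, fi[0] - p00], [fj[0] - p00, 1 - fi[0] - fj[0] + p00]])
    ref = np.outer(fi, fj)
    mask = p > 1e-300
    return float(np.sum(p[mask] * np.log(p[mask] / ref[mask])))


def mutual_information_counts(seqs: np.ndarray, i: int, j: int, q: int) -> float:
    """Plug-in mutual information of two alignment columns."""
    joint = np.zeros((q, q))
    for s in range(len(seqs)):
        joint[seqs[s, i], seqs[s, j]] += 1
    joint /= joint.sum()
    pi = joint.sum(axis=1)
    pj = joint.sum(axis=0)
    mi = 0.0
    for a in range(q):
        for b in range(q):
            if joint[a, b] > 0:
                mi += joint[a, b] * np.log(joint[a, b] / (pi[a] * pj[b]))
    return mi


def contact_map_bruteforce(coords: np.ndarray, cutoff: float):
    """O(n^2) scan for pairs strictly below the cutoff."""
    n = len(coords)
    pairs = set()
    for i in range(n):
        for j in range(i + 1, n):
            if np.sqrt(np.sum((coords[i] - coords[j]) ** 2)) < cutoff:
                pairs.add((i, j))
    return pairs


def superpose_grid_oracle(mobile: np.ndarray, reference: np.ndarray,
                          levels: int = 40, n_per_level: int = 600,
                          seed: int = 0) -> float:
    """Minimum RMSD by derivative-free rotation search.

    Samples random unit quaternions around the current best rotation with a
    shrinking angular scale; translations are optimal (centroid-matching)
    for any rotation, so only rotations are searched.  Independent of the
    SVD route.
    """
    rng = np.random.default_rng(seed)
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)

    def rmsd_for(quat):
        w, x, y, z = quat
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        moved = p @ rot.T
        return np.sqrt(np.mean(np.sum((moved - q) ** 2, axis=1)))

    best_q = np.array([1.0, 0.0, 0.0, 0.0])
    best = rmsd_for(best_q)
    scale = 1.0
    for _ in range(levels):
        perturb = rng.normal(0.0, scale, size=(n_per_level, 4))
        cand = best_q[None, :] + perturb
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        for quat in cand:
            r = rmsd_for(quat)
            if r < best:
                best = r
                best_q = quat
        scale *= 0.75
    return float(best)


def potts_exact_distribution(model) -> np.ndarray:
    """Exact Boltzmann distribution of a small Potts model by enumeration."""
    shape = (model.q,) * model.L
    logw = np.zeros(shape)
    for s in itertools.product(range(model.q), repeat=model.L):
        logw[s] = model.beta * model.energy(np.array(s))
    w = np.exp(logw - logw.max())
    return w / w.sum()
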