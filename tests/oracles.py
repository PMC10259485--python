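"""Independent test oracles, coded separately from the package internals.

Each oracle recomputes a quantity by the most direct route available
(explicit loops, exhaustive enumeration, literal transcription of a
published procedure) so that agreement with the package is informative.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def naive_pair_alignment(
    mate1: str, mate2: str, transcripts: dict[str, str], cap: int
):
    """Exhaustive per-offset Hamming scan of a read pair, pure Python.

    Mates must land on the same transcript in opposite orientations; the
    summed distance is minimized over every (transcript, configuration,
    offset, offset). Returns (best_distance, n_best_placements, gene) with
    best_distance None when it exceeds the cap.
    """

    def distances(mate: str, seq: str) -> list[int]:
        k = len(mate)
        return [
            sum(a != b for a, b in zip(mate, seq[off : off + k]))
            for off in range(len(seq) - k + 1)
        ]

    best = None
    count = 0
    gene = None
    for name, seq in transcripts.items():
        if len(seq) < max(len(mate1), len(mate2)):
            continue
        for m_a, m_b in ((mate1, revcomp(mate2)), (revcomp(mate1), mate2)):
            da = distances(m_a, seq)
            db = distances(m_b, seq)
            for x in da:
                for y in db:
                    tot = x + y
                    if best is None or tot < best:
                        best, count, gene = tot, 1, name
                    elif tot == best:
                        count += 1
    if best is None or best > cap:
        return None, 0, None
    return best, count, gene


def shifted_copy_alignment(
    mate1: str, mate2: str, names: list[str], seqs: list[str], cap: int
):
    """Same scan as :func:`naive_pair_alignment`, vectorized via explicitly
    stacked shifted copies (a different construction from the package's
    sliding-window view); usable on thousands of reads."""

    def enc(s: str) -> np.ndarray:
        return np.frombuffer(s.encode(), dtype=np.uint8)

    def dist_all(mate: np.ndarray, seq: np.ndarray) -> np.ndarray:
        k = len(mate)
        stack = np.stack([seq[i : i + k] for i in range(len(seq) - k + 1)])
        return (stack != mate).sum(axis=1)

    best = None
    count = 0
    gene = None
    m1f, m1r = enc(mate1), enc(revcomp(mate1))
    m2f, m2r = enc(mate2), enc(revcomp(mate2))
    for name, seq in zip(names, seqs):
        s = enc(seq)
        if len(s) < max(len(m1f), len(m2f)):
            continue
        for a, b in ((m1f, m2r), (m1r, m2f)):
            da = dist_all(a, s)
            db = dist_all(b, s)
            tot = int(da.min() + db.min())
            n = int((da == da.min()).sum() * (db == db.min()).sum())
            if best is None or tot < best:
                best, count, gene = tot, n, name
            elif tot == best:
                count += n
    if best is None or best > cap:
        return None, 0, None
    return best, count, gene


def bky_two_stage_rejections(p_values, alpha: float) -> np.ndarray:
    """Literal transcription of the two-stage linear step-up procedure."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    if m == 0:
        return np.array([], dtype=bool)
    a1 = alpha / (1.0 + alpha)
    order = np.argsort(p, kind="stable")
    ps = p[order]

    def step_up(level: float) -> int:
        for i in range(m, 0, -1):
            if ps[i - 1] <= i * level / m:
                return i
        return 0

    r1 = step_up(a1)
    if r1 == 0:
        return np.zeros(m, dtype=bool)
    if r1 == m:
        return np.ones(m, dtype=bool)
    r2 = step_up(a1 * m / (m - r1))
    reject = np.zeros(m, dtype=bool)
    reject[order[:r2]] = True
    return reject


def hypergeometric_tail_enumeration(
    universe_size: int, size_a: int, size_b: int, overlap: int
) -> float:
    """P(X >= overlap) by exhaustive enumeration of all draws of B."""
    universe = range(universe_size)
    a = set(range(size_a))
    hits = 0
    total = 0
    for combo in itertools.combinations(universe, size_b):
        total += 1
        if len(a.intersection(combo)) >= overlap:
            hits += 1
    return hits / total


def hypergeometric_tail_sum(
    universe_size: int, size_a: int, size_b: int, overlap: int
) -> float:
    """P(X >= overlap) summed directly from binomial coefficients."""
    denom = math.comb(universe_size, size_b)
    total = 0
    for k in range(overlap, min(size_a, size_b) + 1):
        total += math.comb(size_a, k) * math.comb(universe_size - size_a, size_b - k)
    return total / denom


def permutation_one_sided_p(co, mix) -> float:
    """Exact permutation p for mean(co) - mean(mix) over all relabelings."""
    pooled = list(co) + list(mix)
    n_co = len(co)
    observed = np.mean(co) - np.mean(mix)
    count = 0
    total = 0
    for idx in itertools.combinations(range(len(pooled)), n_co):
        grp = [pooled[i] for i in idx]
        rest = [pooled[i] for i in range(len(pooled)) if i not in idx]
        diff = np.mean(grp) - np.mean(rest)
        total += 1
        if diff >= observed - 1e-12:
            count += 1
    return count / total
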