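"""Independent brute-force oracles used by the test suite.

These are deliberately written from the definitions, without reusing any
code from the package's alignment or accumulation machinery, so they can
serve as ground truth on small instances.
"""

from __future__ import annotations

import math
from itertools import permutations
from typing import List, Sequence, Set, Tuple

NEG = float("-inf")


def global_optimal_alignments(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -0.5,
) -> Tuple[float, Set[Tuple[int, int]]]:
    """All optimal global (Needleman-Wunsch) affine alignments of two strings.

    A gap run of length L costs gap_open + L*gap_extend, terminal runs
    included.  Returns (optimal score, set of (matches, columns) pairs over
    every optimal alignment), where columns span the first to the last
    aligned pair, so terminal gap runs do not count as columns.
    """
    la, lb = len(a), len(b)
    go, ge = gap_open, gap_extend
    M = [[NEG] * (lb + 1) for _ in range(la + 1)]
    X = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap run consuming a
    Y = [[NEG] * (lb + 1) for _ in range(la + 1)]  # gap run consuming b
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = go + i * ge
    for j in range(1, lb + 1):
        Y[0][j] = go + j * ge
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = s + max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            X[i][j] = max(
                M[i - 1][j] + go + ge, X[i - 1][j] + ge, Y[i - 1][j] + go + ge
            )
            Y[i][j] = max(
                M[i][j - 1] + go + ge, Y[i][j - 1] + ge, X[i][j - 1] + go + ge
            )
    best = max(M[la][lb], X[la][lb], Y[la][lb])

    tol = 1e-9
    results: Set[Tuple[int, int]] = set()

    def record(matches, pairs, first, last):
        if last is None:
            results.add((0, 0))
            return
        i1, j1 = first
        i2, j2 = last
        columns = (i2 - i1 + 1) + (j2 - j1 + 1) - pairs
        results.add((matches, columns))

    def trace(i, j, state, matches, pairs, first, last):
        # backward walk; `last` is the alignment's final aligned pair,
        # `first` the earliest one seen so far
        if i == 0 and j == 0:
            if state == "M":
                record(matches, pairs, first, last)
            return
        if state == "M":
            s = match if a[i - 1] == b[j - 1] else mismatch
            pos = (i - 1, j - 1)
            m2 = matches + (a[i - 1] == b[j - 1])
            last2 = last if last is not None else pos
            target = M[i][j] - s
            for pstate, val in (
                ("M", M[i - 1][j - 1]),
                ("X", X[i - 1][j - 1]),
                ("Y", Y[i - 1][j - 1]),
            ):
                if abs(val - target) < tol:
                    trace(i - 1, j - 1, pstate, m2, pairs + 1, pos, last2)
            if i - 1 == 0 and j - 1 == 0 and abs(target) < tol:
                record(m2, pairs + 1, pos, last2)
        elif state == "X":
            for pstate, val in (
                ("M", M[i - 1][j] + go + ge),
                ("X", X[i - 1][j] + ge),
                ("Y", Y[i - 1][j] + go + ge),
            ):
                if abs(val - X[i][j]) < tol:
                    trace(i - 1, j, pstate, matches, pairs, first, last)
        else:
            for pstate, val in (
                ("M", M[i][j - 1] + go + ge),
                ("Y", Y[i][j - 1] + ge),
                ("X", X[i][j - 1] + go + ge),
            ):
                if abs(val - Y[i][j]) < tol:
                    trace(i, j - 1, pstate, matches, pairs, first, last)

    for state, val in (("M", M[la][lb]), ("X", X[la][lb]), ("Y", Y[la][lb])):
        if abs(val - best) < tol:
            if state == "M":
                trace(la, lb, "M", 0, 0, None, None)
            else:
                trace(la, lb, state, 0, 0, None, None)
    return best, results


def smith_waterman_local(
    query: str,
    subject: str,
    score_fn,
    gap_open: float = -12.0,
    gap_extend: float = -1.0,
) -> Tuple[float, int, int, int]:
    """Plain Gotoh local alignment (best score, matches, columns, query span).

    ``score_fn(x, y)`` gives the substitution score.  A gap of length L
    costs -(12 + (L-1)) by default, i.e. the first gapped column costs
    gap_open and each further one gap_extend.  One optimal traceback is
    reported (ties broken match-first).
    """
    m, n = len(query), len(subject)
    H = [[0.0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (consume query)
    F = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consume subject)
    best, bi, bj = 0.0, 0, 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] + gap_open, E[i - 1][j] + gap_extend)
            F[i][j] = max(H[i][j - 1] + gap_open, F[i][j - 1] + gap_extend)
            diag = H[i - 1][j - 1] + score_fn(query[i - 1], subject[j - 1])
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best, bi, bj = H[i][j], i, j
    # traceback one optimal path
    matches = columns = 0
    i, j = bi, bj
    state = "H"
    q_end = bi
    tol = 1e-9
    while i > 0 and j > 0:
        if state == "H":
            if H[i][j] <= tol:
                break
            diag = H[i - 1][j - 1] + score_fn(query[i - 1], subject[j - 1])
            if abs(H[i][j] - diag) < tol:
                matches += query[i - 1] == subject[j - 1]
                columns += 1
                i, j = i - 1, j - 1
            elif abs(H[i][j] - E[i][j]) < tol:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            if abs(E[i][j] - (H[i - 1][j] + gap_open)) < tol:
                state = "H"
            i -= 1
        else:
            columns += 1
            if abs(F[i][j] - (H[i][j - 1] + gap_open)) < tol:
                state = "H"
            j -= 1
    q_start = i
    return best, matches, columns, q_end - q_start


def blosum62_score_fn():
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    return lambda x, y: float(mat[x, y])


def oracle_conserved(
    query,
    subjects,
    min_identity: float,
    min_alignable: float,
    evalue_max,
    db_length: int,
) -> bool:
    """Conserved-protein decision recomputed from the brute-force engine."""
    fn = blosum62_score_fn()
    for subj in subjects:
        score, matches, columns, q_span = smith_waterman_local(
            query.residues, subj.residues, fn
        )
        if columns == 0:
            continue
        identity = matches / columns
        qcov = q_span / len(query.residues)
        ev = 0.041 * len(query.residues) * db_length * math.exp(-0.267 * score)
        if identity >= min_identity and qcov >= min_alignable:
            if evalue_max is None or ev <= evalue_max:
                return True
    return False


def exact_accumulation_mean(profiles: Sequence, target) -> List[float]:
    """Exact expected coverage after k genomes, by enumerating permutations."""
    n = len(profiles)
    sums = [0.0] * n
    t = target.kos
    for perm in permutations(range(n)):
        acc: set = set()
        for k, idx in enumerate(perm):
            acc |= profiles[idx].kos & t
            sums[k] += len(acc) / len(t)
    total = math.factorial(n)
    return [s / total for s in sums]


def connected_components_at_threshold(seqs, threshold: float, identity_fn) -> List[Set[str]]:
    """Partition by single-linkage on the all-pairs identity graph."""
    ids = [s.id for s in seqs]
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, s1 in enumerate(seqs):
        for s2 in seqs[i + 1:]:
            if identity_fn(s1, s2) >= threshold:
                parent[find(s1.id)] = find(s2.id)
    groups: dict = {}
    for i in ids:
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())
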