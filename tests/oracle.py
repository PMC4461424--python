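"""Independent reference implementations used only by the test suite.

A plain-Python quadratic dynamic-programming aligner (affine gaps, free
terminal gaps, match +1 / mismatch -2 / gap open -10 / gap extend -1) and
a naive greedy clustering reference built on it.  Both follow the same
published decision rules as the package (diagonal-first tie-breaking,
smallest-overhang end point, best-centroid assignment with exact integer
threshold comparisons) but share no code with it: scores are kept in
nested lists and the traceback re-derives each step from the score
matrices instead of stored pointers.
"""

from __future__ import annotations

NEG = -(10**8)
MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -10, -1


def align_counts(a: str, b: str):
    """(total, match, mismatch, internal_gap, terminal_gap) columns."""
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        ai = a[i - 1]
        Mi, Mi1 = M[i], M[i - 1]
        Xi, Xi1 = X[i], X[i - 1]
        Yi, Yi1 = Y[i], Y[i - 1]
        for j in range(1, m + 1):
            s = MATCH if ai == b[j - 1] else MISMATCH
            prev = max(Mi1[j - 1], Xi1[j - 1], Yi1[j - 1])
            if (i == 1 or j == 1) and prev < 0:
                prev = 0
            Mi[j] = prev + s
            Xi[j] = max(Mi1[j] + GAP_OPEN, Xi1[j] + GAP_EXTEND)
            Yi[j] = max(Mi[j - 1] + GAP_OPEN, Yi[j - 1] + GAP_EXTEND)

    def cell_best(i, j):
        # value and state at (i, j), diagonal-first preference
        v, st = M[i][j], 0
        if X[i][j] > v:
            v, st = X[i][j], 1
        if Y[i][j] > v:
            v, st = Y[i][j], 2
        return v, st

    best, bi, bj, bstate = NEG - 1, n, m, 0
    for j in range(m, 0, -1):
        v, st = cell_best(n, j)
        if v > best:
            best, bi, bj, bstate = v, n, j, st
    for i in range(n, 0, -1):
        v, st = cell_best(i, m)
        if v > best:
            best, bi, bj, bstate = v, i, m, st

    terminal = (n - bi) + (m - bj)
    match = mismatch = internal = 0
    i, j, st = bi, bj, bstate
    while True:
        if st == 0:
            if a[i - 1] == b[j - 1]:
                match += 1
            else:
                mismatch += 1
            s = MATCH if a[i - 1] == b[j - 1] else MISMATCH
            target = M[i][j] - s
            # re-derive the predecessor with the same preference order
            if M[i - 1][j - 1] == target:
                st = 0
            elif X[i - 1][j - 1] == target:
                st = 1
            elif Y[i - 1][j - 1] == target:
                st = 2
            else:
                assert (i - 1 == 0 or j - 1 == 0) and target == 0
                terminal += (i - 1) + (j - 1)
                break
            i -= 1
            j -= 1
            # boundary beats an equal-scoring state only when it is strictly
            # better, which cannot happen here (boundary value is 0 and the
            # chosen state matched the target); nothing more to do.
        elif st == 1:
            internal += 1
            st = 0 if M[i - 1][j] + GAP_OPEN >= X[i - 1][j] + GAP_EXTEND else 1
            i -= 1
        else:
            internal += 1
            st = 0 if M[i][j - 1] + GAP_OPEN >= Y[i][j - 1] + GAP_EXTEND else 2
            j -= 1
    total = match + mismatch + internal + terminal
    return total, match, mismatch, internal, terminal


def div_fraction(a: str, b: str, convention: str):
    """Divergence as an exact (numerator, denominator) column pair."""
    total, _match, mismatch, internal, terminal = align_counts(a, b)
    if convention == "all":
        return mismatch + internal + terminal, total
    return mismatch + internal, total - terminal


def naive_cluster(uniques, threshold_percent: int, convention: str):
    """Greedy clustering replayed naively from all pairwise divergences.

    ``uniques`` is a list of (sequence, abundance).  Returns a list of
    clusters, each a (centroid_sequence, [member sequences]) pair in
    creation order, mirroring the published decision rules: decreasing
    abundance (ties lexicographic), join the minimum-divergence centroid
    within threshold (ties to the higher-abundance then earlier centroid).
    """
    ordered = sorted(uniques, key=lambda u: (-u[1], u[0]))
    centroids = []  # (sequence, abundance)
    members = []
    for seq, abund in ordered:
        chosen = None
        best_num = best_den = best_ab = None
        for idx, (cen, cab) in enumerate(centroids):
            num, den = div_fraction(seq, cen, convention)
            if den == 0:
                continue
            if chosen is None or num * best_den < best_num * den or (
                num * best_den == best_num * den and cab > best_ab
            ):
                chosen, best_num, best_den, best_ab = idx, num, den, cab
        if chosen is not None and best_num * 100 <= threshold_percent * best_den:
            members[chosen].append(seq)
        else:
            centroids.append((seq, abund))
            members.append([seq])
    return [
        (cen, mem) for (cen, _ab), mem in zip(centroids, members)
    ]
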