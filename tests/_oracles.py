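"""Independent reference implementations used only to check the package.

These are deliberately naive (full-matrix, pure Python) and share no code
with the implementation they validate.
"""

from __future__ import annotations

NEG_INF = float("-inf")


def affine_local_score(a, b, score, gap_open, gap_extend):
    """Smith-Waterman with affine gaps (Gotoh); gap of length k costs
    gap_open + k * gap_extend.  Returns the optimal local score."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = max(0.0, diag + score(a[i - 1], b[j - 1]))
            best = max(best, M[i][j], X[i][j], Y[i][j])
    return best


def affine_global_score(a, b, score, gap_open, gap_extend):
    """Needleman-Wunsch with affine gaps, end gaps penalized."""
    n, m = len(a), len(b)
    first = gap_open + gap_extend
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Y[0][j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            X[i][j] = max(M[i - 1][j] - first, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - first)
            Y[i][j] = max(M[i][j - 1] - first, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - first)
            diag = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = diag + score(a[i - 1], b[j - 1])
    return max(M[n][m], X[n][m], Y[n][m])


def greedy_centroid_clusters(seqs, identity_fn, threshold):
    """Reference greedy centroid clustering: longest-first (ties by id),
    join the first centroid at >= threshold identity, else found."""
    order = sorted(seqs, key=lambda k: (-len(seqs[k]), k))
    clusters = []
    for sid in order:
        placed = False
        for cl in clusters:
            if identity_fn(seqs[sid], seqs[cl[0]]) >= threshold:
                cl.append(sid)
                placed = True
                break
        if not placed:
            clusters.append([sid])
    return clusters
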