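"""Independent definitional oracles used to validate the implementation.

Everything here is written from first principles with explicit loops and
must stay independent of the sdcornet code paths it checks.
"""
import math

import numpy as np


def dcor_oracle(x, y):
    """Distance correlation via the definitional O(n^2) double loop:
    absolute-difference matrices, explicit double centering, explicit sums."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)

    def centered(v):
        Yt = [[abs(v[h] - v[k]) for k in range(n)] for h in range(n)]
        row = [sum(Yt[h]) / n for h in range(n)]
        col = [sum(Yt[h][k] for h in range(n)) / n for k in range(n)]
        grand = sum(row) / n
        return [[Yt[h][k] - row[h] - col[k] + grand for k in range(n)] for h in range(n)]

    A = centered(x)
    B = centered(y)

    def dcov(U, V):
        total = 0.0
        for h in range(n):
            for k in range(n):
                total += U[h][k] * V[h][k]
        return (1.0 / n) * math.sqrt(max(total, 0.0))

    denom = math.sqrt(dcov(A, A) * dcov(B, B))
    return dcov(A, B) / denom if denom > 0 else 0.0


def pearson_oracle(x, y):
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def quantile_normalize_oracle(columns):
    """Textbook quantile normalization of a list of equal-length columns
    (no ties): replace each value by the rank-wise mean of sorted columns."""
    cols = [list(map(float, c)) for c in columns]
    sorted_cols = [sorted(c) for c in cols]
    u = len(cols[0])
    reference = [sum(sc[r] for sc in sorted_cols) / len(cols) for r in range(u)]
    out = []
    for c in cols:
        ranks = sorted(range(u), key=lambda i: c[i])
        col = [0.0] * u
        for r, i in enumerate(ranks):
            col[i] = reference[r]
        out.append(col)
    return out


def mi_oracle_from_counts(joint):
    """Plug-in mutual information (nats) from a joint contingency table."""
    joint = np.asarray(joint, float)
    n = joint.sum()
    pa = joint.sum(axis=1) / n
    pb = joint.sum(axis=0) / n
    mi = 0.0
    for a in range(joint.shape[0]):
        for b in range(joint.shape[1]):
            if joint[a, b] > 0:
                p = joint[a, b] / n
                mi += p * math.log(p / (pa[a] * pb[b]))
    return mi
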