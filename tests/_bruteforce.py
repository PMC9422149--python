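"""Independent brute-force re-implementation used as an oracle.

Everything here is written with plain Python loops and ``math`` only —
no code shared with the package — so that agreement between the two
routes is a meaningful check of the probability/score matrices, the
total-score classification and the covariance-correlation severity
degree.
"""

import math

DELTA = 0.2
M_MAX = 30
COHORTS = ("CN", "MCI", "AD")
KERNEL_RATIOS = {-4: 1, -3: 7, -2: 21, -1: 43, 0: 56, 1: 43, 2: 21, 3: 7, 4: 1}


def bin_of(t):
    # lower-inclusive / upper-exclusive with the same boundary guard
    return int(t / DELTA + 1e-9) + 1


def kernel():
    total = sum(KERNEL_RATIOS.values())
    return {l: r / total for l, r in KERNEL_RATIOS.items()}


def probability(values_by_image):
    """values_by_image: list over images of per-vertex value lists."""
    n_img = len(values_by_image)
    n_v = len(values_by_image[0])
    P = [[0.0] * M_MAX for _ in range(n_v)]
    k = kernel()
    for img in values_by_image:
        for p, t in enumerate(img):
            m = bin_of(t)
            for l, w in k.items():
                tm = m + l
                if 1 <= tm <= M_MAX:
                    P[p][tm - 1] += w
    for p in range(n_v):
        for m in range(M_MAX):
            P[p][m] /= n_img
    return P


def score(P, cap=50.0):
    n_v = len(P)
    row = [sum(P[p]) for p in range(n_v)]
    total = sum(row)
    S = [[cap] * M_MAX for _ in range(n_v)]
    for p in range(n_v):
        qp = row[p] / total
        for m in range(M_MAX):
            qpm = P[p][m] / row[p]
            if qpm > 0.0:
                S[p][m] = -math.log(qpm / qp)
    return S


def total_scores(profile, S_by_cohort):
    """profile: per-vertex thickness list; returns ({cohort: S'}, predicted)."""
    totals = {}
    for k in COHORTS:
        s = 0.0
        for p, t in enumerate(profile):
            s += S_by_cohort[k][p][bin_of(t) - 1]
        totals[k] = s
    best = min(COHORTS, key=lambda k: (totals[k], COHORTS.index(k)))
    return totals, best


def severity(values, cohorts):
    """values: vertex x image nested list; cohorts: per-image labels.

    Returns (C, SD) with C the image x image covariance correlation
    matrix and SD the severity degrees, both as nested lists / lists.
    """
    n_v = len(values)
    n_i = len(values[0])
    tprime = [[0.0] * n_i for _ in range(n_v)]
    for p in range(n_v):
        mean = sum(values[p]) / n_i
        var = sum(v * v for v in values[p]) / n_i - mean * mean
        sd = math.sqrt(var)
        for h in range(n_i):
            tprime[p][h] = (values[p][h] - mean) / sd
    gram = [[0.0] * n_i for _ in range(n_i)]
    for i in range(n_i):
        for j in range(n_i):
            gram[i][j] = sum(tprime[p][i] * tprime[p][j] for p in range(n_v))
    gmax = max(max(r) for r in gram)
    C = [[gram[i][j] / gmax for j in range(n_i)] for i in range(n_i)]
    ad = [i for i, c in enumerate(cohorts) if c == "AD"]
    cn = [i for i, c in enumerate(cohorts) if c == "CN"]
    cbar = [
        sum(C[i][j] for j in ad) / len(ad) - sum(C[i][j] for j in cn) / len(cn)
        for i in range(n_i)
    ]
    anchor_cn = sum(cbar[i] for i in cn) / len(cn)
    anchor_ad = sum(cbar[i] for i in ad) / len(ad)
    SD = [(c - anchor_cn) / (anchor_ad - anchor_cn) for c in cbar]
    return C, SD
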