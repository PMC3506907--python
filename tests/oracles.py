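"""Independent naive reference implementations used only by the tests.

Every function here is written as a direct transcription of the defining
formula, with explicit Python loops and no shared code with the package,
so that agreement is a meaningful check.
"""

import itertools
import math

import numpy as np
import scipy.stats


def entropy_empirical(counts):
    n = sum(counts)
    return -sum((c / n) * math.log(c / n) for c in counts if c > 0)


def entropy_mm(counts):
    occupied = sum(1 for c in counts if c > 0)
    return entropy_empirical(counts) + (occupied - 1) / (2.0 * sum(counts))


def entropy_sg(counts):
    m = len(counts)
    n = sum(counts)
    ps = [(c + 1.0 / m) / (n + 1.0) for c in counts]
    return -sum(p * math.log(p) for p in ps if p > 0)


def entropy_shrink(counts):
    m = len(counts)
    n = sum(counts)
    p_hat = [c / n for c in counts]
    target = 1.0 / m
    denom = (n - 1) * sum((target - p) ** 2 for p in p_hat)
    lam = 1.0 if denom <= 0 else min(1.0, max(0.0, (
        1.0 - sum(p * p for p in p_hat)) / denom))
    ps = [lam * target + (1 - lam) * p for p in p_hat]
    return -sum(p * math.log(p) for p in ps if p > 0)


def mi_from_joint(joint):
    """Direct double-sum MI over a joint count table (empirical)."""
    joint = np.asarray(joint, dtype=float)
    n = joint.sum()
    px = joint.sum(axis=1) / n
    py = joint.sum(axis=0) / n
    mi = 0.0
    for i in range(joint.shape[0]):
        for j in range(joint.shape[1]):
            p = joint[i, j] / n
            if p > 0:
                mi += p * math.log(p / (px[i] * py[j]))
    return mi


def auc_pair_counting(scores, labels):
    """Fraction of positive-negative pairs correctly ordered, ties = 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def clr_naive(m):
    g = m.shape[0]
    z = np.zeros((g, g))
    for i in range(g):
        row = [m[i, j] for j in range(g) if j != i]
        mu, sd = np.mean(row), np.std(row)
        for j in range(g):
            if i == j or sd == 0:
                continue
            z[i, j] = max(0.0, (m[i, j] - mu) / sd)
    out = np.zeros((g, g))
    for i in range(g):
        for j in range(g):
            if i != j:
                out[i, j] = math.sqrt(z[i, j] ** 2 + z[j, i] ** 2)
    return out


def aracne_naive(m, eps=0.0):
    g = m.shape[0]
    removed = set()
    for i, j, k in itertools.combinations(range(g), 3):
        trio = [(i, j, k), (i, k, j), (j, k, i)]
        if m[i, j] > 0 and m[i, k] > 0 and m[j, k] > 0:
            for a, b, c in trio:
                if m[a, b] < min(m[a, c], m[b, c]) - eps:
                    removed.add((a, b))
                    removed.add((b, a))
    out = m.copy()
    for a, b in removed:
        out[a, b] = 0.0
    return out


def mrnet_naive(m):
    g = m.shape[0]
    directional = np.zeros((g, g))
    for y in range(g):
        candidates = [x for x in range(g) if x != y]
        selected = []
        while candidates:
            us = []
            for x in candidates:
                if selected:
                    red = sum(m[x, k] for k in selected) / len(selected)
                else:
                    red = 0.0
                us.append(m[x, y] - red)
            best_i = max(range(len(us)), key=lambda i: (us[i], -i))
            if us[best_i] <= 0:
                break
            x = candidates.pop(best_i)
            directional[x, y] = us[best_i]
            selected.append(x)
    return np.maximum(directional, directional.T)


def pcit_naive(x, kind="pearson"):
    """Trio-filtered absolute correlation, direct loop transcription."""
    g = x.shape[0]
    if kind == "pearson":
        r = np.corrcoef(x)
    else:
        r = scipy.stats.spearmanr(x.T).statistic
    absr = np.abs(r)
    flagged = set()
    for xg, yg, zg in itertools.permutations(range(g), 3):
        if xg > yg:
            continue
        denom_ok = all(abs(r[a, b]) < 1 for a, b in
                       [(xg, zg), (zg, yg), (xg, yg)])
        if not denom_ok:
            continue

        def pc(a, b, c):
            return (r[a, b] - r[a, c] * r[c, b]) / math.sqrt(
                (1 - r[a, c] ** 2) * (1 - r[c, b] ** 2))

        direct = [r[xg, yg], r[xg, zg], r[zg, yg]]
        if any(d == 0 for d in direct):
            continue
        partials = [pc(xg, yg, zg), pc(xg, zg, yg), pc(zg, yg, xg)]
        eps = np.mean([abs(p / d) for p, d in zip(partials, direct)])
        if abs(r[xg, yg]) <= eps * abs(r[xg, zg]) and \
                abs(r[xg, yg]) <= eps * abs(r[yg, zg]):
            flagged.add((xg, yg))
            flagged.add((yg, xg))
    out = absr.copy()
    np.fill_diagonal(out, 0.0)
    for a, b in flagged:
        out[a, b] = 0.0
    return out


def wgcna_naive(x, kind, softpower):
    if kind == "pearson":
        r = np.corrcoef(x)
    else:
        r = scipy.stats.spearmanr(x.T).statistic
    a = np.abs(r) ** softpower
    np.fill_diagonal(a, 0.0)
    return a
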