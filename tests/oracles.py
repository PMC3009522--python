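"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain double loops from the defining
formulas, deliberately sharing no code with the package.
"""

import math

import numpy as np


def brute_entropy(counts):
    """Shannon entropy in bits of a count vector."""
    n = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / n
            h -= p * math.log2(p)
    return h


def brute_chi2(counts):
    """Pearson chi-square from a bins x classes count matrix."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    stat = 0.0
    for v in range(counts.shape[0]):
        for c in range(counts.shape[1]):
            e = counts[v].sum() * counts[:, c].sum() / n
            if e > 0:
                stat += (counts[v, c] - e) ** 2 / e
    return stat


def brute_info_gain(counts):
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    h_class = brute_entropy(counts.sum(axis=0))
    cond = 0.0
    for v in range(counts.shape[0]):
        nv = counts[v].sum()
        if nv > 0:
            cond += (nv / n) * brute_entropy(counts[v])
    return h_class - cond


def brute_gain_ratio(counts):
    counts = np.asarray(counts, dtype=float)
    split = brute_entropy(counts.sum(axis=1))
    if split == 0:
        return 0.0
    return brute_info_gain(counts) / split


def brute_symmetrical_uncertainty(counts):
    counts = np.asarray(counts, dtype=float)
    h_class = brute_entropy(counts.sum(axis=0))
    h_gene = brute_entropy(counts.sum(axis=1))
    if h_class + h_gene == 0:
        return 0.0
    return 2.0 * brute_info_gain(counts) / (h_class + h_gene)


def brute_relieff(X, y, gene):
    """Exhaustive single-nearest-hit/miss ReliefF probing every sample.

    X is samples x genes in [0, 1]; multi-class misses weighted by prior /
    (1 - prior of the probe's class); ties broken by lowest sample index.
    """
    n = len(y)
    classes = sorted(set(y))
    prior = {c: sum(1 for v in y if v == c) / n for c in classes}
    w = 0.0
    for i in range(n):
        best_hit, best_hit_d = None, None
        nearest_miss = {}
        for j in range(n):
            if j == i:
                continue
            d = sum((X[i, g] - X[j, g]) ** 2 for g in range(X.shape[1]))
            if y[j] == y[i]:
                if best_hit_d is None or d < best_hit_d:
                    best_hit, best_hit_d = j, d
            else:
                cur = nearest_miss.get(y[j])
                if cur is None or d < cur[1]:
                    nearest_miss[y[j]] = (j, d)
        hit_diff = abs(X[i, gene] - X[best_hit, gene])
        miss_diff = 0.0
        for c, (j, _) in nearest_miss.items():
            miss_diff += prior[c] / (1 - prior[y[i]]) * abs(X[i, gene] - X[j, gene])
        w += miss_diff - hit_diff
    return w / n


def brute_bss_wss(X, y):
    """Per-gene BSS/WSS ratio via explicit loops (genes x samples X)."""
    n_genes, n_samples = X.shape
    classes = sorted(set(y))
    out = np.zeros(n_genes)
    for g in range(n_genes):
        grand = sum(X[g]) / n_samples
        cls_mean = {c: np.mean([X[g, i] for i in range(n_samples) if y[i] == c])
                    for c in classes}
        bss = sum((cls_mean[y[i]] - grand) ** 2 for i in range(n_samples))
        wss = sum((X[g, i] - cls_mean[y[i]]) ** 2 for i in range(n_samples))
        if wss == 0:
            out[g] = np.inf if bss > 0 else 0.0
        else:
            out[g] = bss / wss
    return out


def brute_balanced_accuracy(pred, actual, class_set):
    ses = []
    for c in class_set:
        idx = [i for i, a in enumerate(actual) if a == c]
        if not idx:
            ses.append(0.0)
        else:
            ses.append(sum(1 for i in idx if pred[i] == c) / len(idx))
    return sum(ses) / len(ses)
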