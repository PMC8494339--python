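"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over outcomes, deliberately
sharing no code with the package, so agreement is meaningful.
"""

import itertools
import math

import numpy as np


def mi_bruteforce(x, y):
    """MI in bits by a double loop over the contingency table."""
    x = list(x)
    y = list(y)
    n = len(x)
    xs, ys = sorted(set(x)), sorted(set(y))
    total = 0.0
    for xv in xs:
        for yv in ys:
            nxy = sum(1 for a, b in zip(x, y) if a == xv and b == yv)
            if nxy == 0:
                continue
            nx = sum(1 for a in x if a == xv)
            ny = sum(1 for b in y if b == yv)
            total += (nxy / n) * math.log2((nxy / n) / ((nx / n) * (ny / n)))
    return total


def cmi_bruteforce(x, y, z):
    """Conditional MI in bits by a triple loop."""
    x, y, z = list(x), list(y), list(z)
    n = len(z)
    total = 0.0
    for zv in sorted(set(z)):
        idx = [i for i in range(n) if z[i] == zv]
        pz = len(idx) / n
        total += pz * mi_bruteforce([x[i] for i in idx], [y[i] for i in idx])
    return total


def entropy_bruteforce(labels):
    labels = list(labels)
    n = len(labels)
    h = 0.0
    for v in sorted(set(labels)):
        p = labels.count(v) / n
        h -= p * math.log2(p)
    return h


def weighted_ig_bruteforce(parent, left, right, n_total):
    """Weighted information gain of one split, direct formula."""
    nt = len(parent)
    gain = entropy_bruteforce(parent)
    if left:
        gain -= len(left) / nt * entropy_bruteforce(left)
    if right:
        gain -= len(right) / nt * entropy_bruteforce(right)
    return nt / n_total * gain


def auroc_bruteforce(scores, labels):
    """AUROC by enumerating all positive x negative pairs (ties = 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    if not pos or not neg:
        raise ValueError("both classes required")
    wins = 0.0
    for p, q in itertools.product(pos, neg):
        if p > q:
            wins += 1.0
        elif p == q:
            wins += 0.5
    return wins / (len(pos) * len(neg))


def collapse_mean_bruteforce(rows):
    """Column-wise mean over non-missing values by explicit loops."""
    rows = [list(r) for r in rows]
    n = len(rows[0])
    out = []
    for j in range(n):
        vals = [r[j] for r in rows if not (isinstance(r[j], float) and math.isnan(r[j]))]
        out.append(sum(vals) / len(vals) if vals else float("nan"))
    return np.array(out)
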