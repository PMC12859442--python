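"""Independent brute-force reference implementations used as oracles.

Deliberately written as plain Python loops / direct formulas, sharing no
code with the package, so agreement is a meaningful check.
"""

import cmath
import math


def wamp_oracle(x, threshold):
    count = 0
    for i in range(len(x) - 1):
        if abs(x[i + 1] - x[i]) >= threshold:
            count += 1
    return count


def avser_oracle(x, exponent):
    s = 0.0
    for v in x:
        s += math.copysign(abs(v) ** exponent, v) if v != 0 else 0.0
    return abs(s)


def ssi_oracle(x):
    return sum(v * v for v in x)


def rms_oracle(x):
    return math.sqrt(sum(v * v for v in x) / len(x))


def mav_oracle(x):
    return sum(abs(v) for v in x) / len(x)


def rssq_oracle(x):
    return math.sqrt(sum(v * v for v in x))


def mmav1_oracle(x):
    n = len(x)
    total = 0.0
    for i, v in enumerate(x, start=1):  # 1-based index
        w = 1.0 if 0.25 * n <= i <= 0.75 * n else 0.5
        total += w * abs(v)
    return total / n


def pkf_oracle(x, fs):
    """Direct O(N^2) DFT periodogram argmax (one-sided scaling)."""
    n = len(x)
    n_freqs = n // 2 + 1
    best_k, best_p = 0, -1.0
    for k in range(n_freqs):
        acc = 0j
        for i, v in enumerate(x):
            acc += v * cmath.exp(-2j * cmath.pi * k * i / n)
        p = abs(acc) ** 2
        if k not in (0, n // 2 if n % 2 == 0 else -1):
            p *= 2.0
        if p > best_p:
            best_k, best_p = k, p
    return best_k * fs / n


def knn_reference(pool_x, pool_y, query, k, metric="l1", epsilon=1e-8,
                  weighted=True):
    """Full-scan k-nearest-neighbor vote.

    Ties in the k-th distance break toward the smaller pool index; ties
    in vote mass toward the smallest class id.  Returns the label.
    """
    dists = []
    for i, p in enumerate(pool_x):
        if metric == "l1":
            d = sum(abs(a - b) for a, b in zip(p, query))
        else:
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(p, query)))
        dists.append((d, i))
    dists.sort()
    mass = {}
    for d, i in dists[:min(k, len(dists))]:
        w = 1.0 / (d + epsilon) if weighted else 1.0
        mass[pool_y[i]] = mass.get(pool_y[i], 0.0) + w
    return min(mass, key=lambda c: (-mass[c], c))


def metrics_oracle(y_true, y_pred):
    """Accuracy and macro precision/recall/F1 over classes in y_true."""
    n = len(y_true)
    acc = sum(t == p for t, p in zip(y_true, y_pred)) / n
    present = sorted(set(y_true))
    precs, recs, f1s = [], [], []
    for c in present:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(y_true, y_pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(y_true, y_pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    k = len(present)
    return acc, sum(precs) / k, sum(recs) / k, sum(f1s) / k
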