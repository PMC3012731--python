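"""Independent brute-force oracles used by unit and acceptance tests.

Deliberately naive implementations (pairwise enumeration, explicit
threshold scans, exact rational arithmetic) kept separate from the
package code paths they validate.
"""

from fractions import Fraction
from math import comb

import numpy as np


def mann_whitney_auc(scores, labels):
    """AUC by exhaustive positive-negative pair enumeration; ties count 1/2."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_roc(scores, labels):
    """ROC vertices by explicit threshold enumeration (score >= t rule)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    points = [(0.0, 0.0)]
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        points.append(((pred & ~labels).sum() / n_neg,
                       (pred & labels).sum() / n_pos))
    return points


def brute_force_pauc(scores, labels, fpr_max=0.1):
    """Partial trapezoid area with linear interpolation at fpr_max."""
    pts = brute_force_roc(scores, labels)
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2.0
        elif x0 < fpr_max:
            ym = y0 + (y1 - y0) * (fpr_max - x0) / (x1 - x0)
            area += (fpr_max - x0) * (y0 + ym) / 2.0
    return area / fpr_max


def exact_binomial_two_sided(k, n, p0=Fraction(1, 2)):
    """Exact rational tail sums, 2*min(tails) capped at 1."""
    probs = [Fraction(comb(n, i)) * p0**i * (1 - p0)**(n - i)
             for i in range(n + 1)]
    lower = sum(probs[:k + 1])
    upper = sum(probs[k:])
    return float(min(Fraction(1), 2 * min(lower, upper)))


def random_roc_instance(rng, max_windows=50, allow_ties=True):
    """Small random scored instance with at least one of each class."""
    n = int(rng.integers(4, max_windows + 1))
    if allow_ties and rng.random() < 0.5:
        scores = rng.integers(0, 6, n).astype(float) / 5.0
    else:
        scores = rng.uniform(0, 1, n)
    labels = np.zeros(n, dtype=bool)
    n_pos = int(rng.integers(1, max(2, n // 3)))
    labels[rng.choice(n, n_pos, replace=False)] = True
    return scores, labels
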