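"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exhaustive enumeration and two-pass
arithmetic, sharing no code path with the package.
"""

from __future__ import annotations

import numpy as np


def exhaustive_alignment_identity(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -1
) -> float:
    """Enumerate every global alignment; identity of the best one.

    "Best" is the lexicographic maximum of (score, identities).  Exponential:
    only usable for sequences of length <= ~8.
    """

    def walk(i: int, j: int) -> tuple[int, int]:
        if i == len(a) and j == len(b):
            return (0, 0)
        options = []
        if i < len(a) and j < len(b):
            s, c = walk(i + 1, j + 1)
            if a[i] == b[j]:
                options.append((s + match, c + 1))
            else:
                options.append((s + mismatch, c))
        if i < len(a):
            s, c = walk(i + 1, j)
            options.append((s + gap, c))
        if j < len(b):
            s, c = walk(i, j + 1)
            options.append((s + gap, c))
        return max(options)

    _, identities = walk(0, 0)
    return identities / min(len(a), len(b))


def two_pass_f_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature F-score by explicit two-pass mean/variance loops."""
    X = np.asarray(X, dtype=float)
    out = np.empty(X.shape[1])
    pos_rows = [i for i in range(len(y)) if y[i] == 1]
    neg_rows = [i for i in range(len(y)) if y[i] == 0]
    for f in range(X.shape[1]):
        pos = [X[i, f] for i in pos_rows]
        neg = [X[i, f] for i in neg_rows]
        allv = pos + neg
        m_all = sum(allv) / len(allv)
        m_pos = sum(pos) / len(pos)
        m_neg = sum(neg) / len(neg)
        var_pos = sum((v - m_pos) ** 2 for v in pos) / (len(pos) - 1)
        var_neg = sum((v - m_neg) ** 2 for v in neg) / (len(neg) - 1)
        num = (m_pos - m_all) ** 2 + (m_neg - m_all) ** 2
        den = var_pos + var_neg
        if den == 0:
            out[f] = np.inf if num > 0 else 0.0
        else:
            out[f] = num / den
    return out


def pairwise_auc(scores, labels) -> float:
    """Tie-corrected probability a random positive outscores a random negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos) * len(neg))
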