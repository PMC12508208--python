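"""Independent brute-force oracles shared by unit and acceptance tests.

Each of these recomputes a quantity by the most direct method available
(double loops, pairwise enumeration) and is kept deliberately separate from
the library implementations it checks.
"""

import numpy as np


def brute_force_sampen(x, m=2, r_ratio=0.2):
    """O(n^2) double-loop template-counting sample entropy."""
    x = np.asarray(x, float)
    n = x.size
    r = r_ratio * np.std(x)
    b = a = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a += 1
    if b == 0:
        return 0.0
    if a == 0:
        return float(np.log(max(b * (b - 1), 2)))
    return float(-np.log(a / b))


def brute_force_auc(y_true, scores):
    """Pairwise-comparison AUC: P(score_pos > score_neg) + half ties."""
    y_true = np.asarray(y_true, int)
    scores = np.asarray(scores, float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_knn(train_F, train_y, test_F, k=3):
    """Exhaustive-distance 3-NN with lowest-training-index tie break."""
    train_F = np.asarray(train_F, float)
    train_y = np.asarray(train_y, int)
    out = []
    for x in np.asarray(test_F, float):
        d = np.sqrt(((train_F - x) ** 2).sum(axis=1))
        order = np.lexsort((np.arange(len(d)), d))[:k]
        votes = train_y[order]
        out.append(1 if votes.sum() * 2 >= k else 0)
    return np.array(out)
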