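"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as explicit Python loops over instances, kept
deliberately separate from (and slower than) the vectorized code under test.
"""

from __future__ import annotations

import math

import numpy as np


def knn_predict_loop(x_train, y_train, x_test, k=1):
    """Nearest-neighbor prediction by exhaustive distance loops.

    Neighbors ordered by (distance, training index); vote ties go to the class
    of the single nearest neighbor when it is among the tied classes, else the
    first tied class in sorted order.
    """
    preds = []
    for row in x_test:
        dists = []
        for j, tr in enumerate(x_train):
            d = math.sqrt(sum((a - b) ** 2 for a, b in zip(row, tr)))
            dists.append((d, j))
        dists.sort()
        neigh = [y_train[j] for _, j in dists[:k]]
        counts = {}
        for lab in neigh:
            counts[lab] = counts.get(lab, 0) + 1
        top = max(counts.values())
        tied = sorted(lab for lab, c in counts.items() if c == top)
        preds.append(neigh[0] if neigh[0] in tied else tied[0])
    return np.array(preds)


def gnb_predict_loop(x_train, y_train, x_test, variance_floor=1e-9):
    """Gaussian naive Bayes by explicit per-class likelihood loops; posterior
    ties resolve to the earlier class in sorted order."""
    classes = sorted(set(y_train))
    stats = {}
    for c in classes:
        rows = [x for x, y in zip(x_train, y_train) if y == c]
        mu = [sum(col) / len(rows) for col in zip(*rows)]
        var = [
            max(sum((v - m) ** 2 for v in col) / len(rows), variance_floor)
            for col, m in zip(zip(*rows), mu)
        ]
        stats[c] = (mu, var, len(rows) / len(x_train))
    preds = []
    for row in x_test:
        best_c, best_ll = None, -math.inf
        for c in classes:
            mu, var, prior = stats[c]
            ll = math.log(prior)
            for v, m, s2 in zip(row, mu, var):
                ll += -0.5 * (math.log(2 * math.pi * s2) + (v - m) ** 2 / s2)
            if ll > best_ll:  # strict: ties keep the earlier class
                best_c, best_ll = c, ll
        preds.append(best_c)
    return np.array(preds)


def kfold_hits_loop(values, labels, subset, folds, kind, k=1, variance_floor=1e-9):
    """Cross-validated hit count by explicit fold/instance loops."""
    values = np.asarray(values)[:, list(subset)]
    labels = np.asarray(labels)
    hits = 0
    for fold in sorted(set(folds)):
        test = np.asarray(folds) == fold
        x_tr, y_tr = values[~test], labels[~test]
        x_te, y_te = values[test], labels[test]
        if len(set(y_tr)) == 1:
            pred = np.full(len(y_te), y_tr[0])
        elif kind == "knn":
            pred = knn_predict_loop(x_tr, y_tr, x_te, k=min(k, len(y_tr)))
        else:
            pred = gnb_predict_loop(x_tr, y_tr, x_te, variance_floor)
        hits += sum(p == t for p, t in zip(pred, y_te))
    return hits


def confusion_counts_loop(y_true, y_pred, positive):
    """TP/FP/FN/TN by a pair-counting loop."""
    tp = fp = fn = tn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive and p == positive:
            tp += 1
        elif t != positive and p == positive:
            fp += 1
        elif t == positive and p != positive:
            fn += 1
        else:
            tn += 1
    return tp, fp, fn, tn
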