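"""Numba kernels for the motif-alignment network.

The training loop performs per-example stochastic gradient descent where
each presentation first re-aligns the peptide (picks the best-scoring
motif core offset under the current weights) and then backpropagates the
squared error through that offset only.  This is far too slow in pure
Python, so the inner loops are JIT-compiled; all randomness is driven by
an explicit seed so training is bitwise reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _forward_best(X, n_off, W1, b1, W2, b2):
    """Best core placement for one peptide.

    X : (max_off, d) encoded cores, rows beyond n_off are padding.
    Returns (best score, best offset); ties go to the lowest offset.
    """
    d = W1.shape[0]
    h = np.empty(W1.shape[1])
    best = -1.0
    best_off = 0
    for o in range(n_off):
        for j in range(W1.shape[1]):
            s = b1[j]
            for i in range(d):
                s += X[o, i] * W1[i, j]
            h[j] = 1.0 / (1.0 + np.exp(-s))
        z = b2
        for j in range(W1.shape[1]):
            z += h[j] * W2[j]
        out = 1.0 / (1.0 + np.exp(-z))
        if out > best:
            best = out
            best_off = o
    return best, best_off


@njit(cache=True)
def _auc_rank(scores, y):
    """Mann-Whitney AUC with ties counted half; NaN if one class absent."""
    n = scores.shape[0]
    npos = 0
    for i in range(n):
        if y[i] > 0.5:
            npos += 1
    nneg = n - npos
    if npos == 0 or nneg == 0:
        return np.nan
    order = np.argsort(scores)
    ranks = np.empty(n)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and scores[order[j + 1]] == scores[order[i]]:
            j += 1
        avg = 0.5 * (i + j) + 1.0
        for t in range(i, j + 1):
            ranks[order[t]] = avg
        i = j + 1
    rpos = 0.0
    for i in range(n):
        if y[i] > 0.5:
            rpos += ranks[i]
    u = rpos - npos * (npos + 1) / 2.0
    return u / (npos * nneg)


@njit(cache=True)
def train_sgd(X, n_off, y, train_idx, val_idx, n_hidden, lr, max_epochs, patience, seed):
    """Train one motif network by aligned per-example SGD.

    X : (n_peptides, max_off, d) float64 encoded offset cores.
    Early stopping: snapshot the weights at the best validation AUC
    (negative MSE if the hold-out is single-class), stop after `patience`
    epochs without improvement.

    Returns (W1, b1, W2, b2, epochs_run, best_criterion).
    """
    np.random.seed(seed)
    d = X.shape[2]
    W1 = np.random.uniform(-0.1, 0.1, (d, n_hidden))
    b1 = np.random.uniform(-0.1, 0.1, n_hidden)
    W2 = np.random.uniform(-0.1, 0.1, n_hidden)
    b2 = np.random.uniform(-0.1, 0.1)

    bW1 = W1.copy()
    bb1 = b1.copy()
    bW2 = W2.copy()
    bb2 = b2

    h = np.empty(n_hidden)
    dh = np.empty(n_hidden)
    n_train = train_idx.shape[0]
    n_val = val_idx.shape[0]
    val_scores = np.empty(n_val)
    val_y = np.empty(n_val)
    for v in range(n_val):
        val_y[v] = y[val_idx[v]]

    best_crit = -1e300
    stall = 0
    epochs_run = 0
    for epoch in range(max_epochs):
        perm = np.random.permutation(n_train)
        for p in range(n_train):
            i = train_idx[perm[p]]
            # re-align: best offset under current weights
            best = -1.0
            off = 0
            for o in range(n_off[i]):
                for j in range(n_hidden):
                    s = b1[j]
                    for q in range(d):
                        s += X[i, o, q] * W1[q, j]
                    h[j] = 1.0 / (1.0 + np.exp(-s))
                z = b2
                for j in range(n_hidden):
                    z += h[j] * W2[j]
                out = 1.0 / (1.0 + np.exp(-z))
                if out > best:
                    best = out
                    off = o
            # recompute hidden at the chosen offset
            for j in range(n_hidden):
                s = b1[j]
                for q in range(d):
                    s += X[i, off, q] * W1[q, j]
                h[j] = 1.0 / (1.0 + np.exp(-s))
            z = b2
            for j in range(n_hidden):
                z += h[j] * W2[j]
            out = 1.0 / (1.0 + np.exp(-z))
            # backprop squared error at the aligned core
            do = (out - y[i]) * out * (1.0 - out)
            for j in range(n_hidden):
                dh[j] = do * W2[j] * h[j] * (1.0 - h[j])
            for j in range(n_hidden):
                W2[j] -= lr * do * h[j]
            b2 -= lr * do
            for j in range(n_hidden):
                g = lr * dh[j]
                for q in range(d):
                    W1[q, j] -= g * X[i, off, q]
                b1[j] -= lr * dh[j]
        epochs_run = epoch + 1

        # validation criterion
        if n_val > 0:
            for v in range(n_val):
                s_v, _ = _forward_best(X[val_idx[v]], n_off[val_idx[v]], W1, b1, W2, b2)
                val_scores[v] = s_v
            crit = _auc_rank(val_scores, val_y)
            if np.isnan(crit):
                mse = 0.0
                for v in range(n_val):
                    mse += (val_scores[v] - val_y[v]) ** 2
                crit = -mse / n_val
        else:
            crit = float(epoch)  # no hold-out: keep the last epoch

        if crit > best_crit:
            best_crit = crit
            bW1 = W1.copy()
            bb1 = b1.copy()
            bW2 = W2.copy()
            bb2 = b2
            stall = 0
        else:
            stall += 1
            if stall >= patience:
                break

    return bW1, bb1, bW2, bb2, epochs_run, best_crit
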