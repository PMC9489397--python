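"""Independent brute-force oracles used by the tests.

Everything here is deliberately naive — explicit loops and pair counting — so the
library implementations are checked against code that shares nothing with them.
"""

import numpy as np


def naive_conv2d(x, w, stride=1, dilation=1, depthwise=False):
    """Dense or depthwise same-padded convolution by explicit loops.

    Returns ``(output, multiply_count)`` where the count increments once per scalar
    multiplication actually performed (zero-padding positions included).
    """
    b, cin, h, wd = x.shape
    if depthwise:
        cout, n = w.shape[0], w.shape[-1]
    else:
        cout, _, n, _ = w.shape
    total = dilation * (n - 1)
    plo = total // 2
    ho, wo = -(-h // stride), -(-wd // stride)
    xp = np.zeros((b, cin, h + total, wd + total))
    xp[:, :, plo:plo + h, plo:plo + wd] = x
    out = np.zeros((b, cout, ho, wo))
    count = 0
    for bi in range(b):
        for oy in range(ho):
            for ox in range(wo):
                for co in range(cout):
                    acc = 0.0
                    cins = [co] if depthwise else range(cin)
                    for ci in cins:
                        for ky in range(n):
                            for kx in range(n):
                                iv = xp[bi, ci, oy * stride + ky * dilation,
                                        ox * stride + kx * dilation]
                                kv = w[co, 0, ky, kx] if depthwise else w[co, ci, ky, kx]
                                acc += iv * kv
                                count += 1
                    out[bi, co, oy, ox] = acc
    return out, count


def naive_conv_mult_count(w_dim, h_dim, cin, cout, n, depthwise=False):
    """Literal multiply count of a stride-1 same-padded conv: one increment per
    scalar multiplication a naive loop implementation would perform."""
    count = 0
    for _oy in range(h_dim):
        for _ox in range(w_dim):
            for _co in range(cout):
                for _ci in range(1 if depthwise else cin):
                    for _ky in range(n):
                        for _kx in range(n):
                            count += 1
    return count


def shuffle_index_map(c, groups):
    """Brute-force reshape(G, n)-transpose-reshape permutation of channel indices."""
    n = c // groups
    return np.arange(c).reshape(groups, n).T.reshape(-1)


def tally_metrics(y_true, y_pred, num_classes):
    """Percent metrics recomputed from raw (true, predicted) pairs, loop style."""
    y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
    total = len(y_true)
    acc = float((y_true == y_pred).sum()) / total * 100
    prec, rec, f1 = [], [], []
    for k in range(num_classes):
        tp = int(((y_true == k) & (y_pred == k)).sum())
        fp = int(((y_true != k) & (y_pred == k)).sum())
        fn = int(((y_true == k) & (y_pred != k)).sum())
        p = tp / (tp + fp) * 100 if tp + fp else 0.0
        r = tp / (tp + fn) * 100 if tp + fn else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        prec.append(p)
        rec.append(r)
        f1.append(f)
    return acc, prec, rec, f1


def pairwise_auc(scores, positives):
    """AUC as P(score_pos > score_neg) + 0.5 P(tie) by exhaustive pair comparison."""
    pos = scores[positives]
    neg = scores[~positives]
    wins = ties = 0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1
            elif sp == sn:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def cm_to_pairs(cm):
    """Expand a confusion-count matrix into the raw (true, pred) label lists."""
    yt, yp = [], []
    k = cm.shape[0]
    for i in range(k):
        for j in range(k):
            yt.extend([i] * cm[i, j])
            yp.extend([j] * cm[i, j])
    return yt, yp
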