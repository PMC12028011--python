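"""Independent brute-force oracles used by the test suite.

These are written as plain nested loops over scalar elements, deliberately
independent of the vectorized implementations they check.
"""

from __future__ import annotations

import math

import numpy as np


def attention_oracle(
    hs: list[np.ndarray],
    wq: list[np.ndarray],
    wk: list[np.ndarray],
    wv: list[np.ndarray],
    H: int,
    cascade: bool = True,
    residual: str = "ADD",
):
    """Nested-loop evaluation of the cross-sequence attention equations.

    hs: three length-d vectors; wq/wk/wv: three d x d matrices each.
    Returns (attended vectors, attention probabilities [head][i][j]).
    """
    d = len(hs[0])
    dh = d // H
    originals = [np.array(h, dtype=float) for h in hs]
    running = [h.copy() for h in originals]
    head_outputs = [[] for _ in range(3)]
    all_probs = np.zeros((H, 3, 3))

    for head in range(H):
        lo = head * dh
        source = running if cascade else originals
        # full-width projections, then split into per-head sub-vectors
        q = [np.zeros(d) for _ in range(3)]
        k = [np.zeros(d) for _ in range(3)]
        v = [np.zeros(d) for _ in range(3)]
        for s in range(3):
            for col in range(d):
                for row in range(d):
                    q[s][col] += source[s][row] * wq[s][row][col]
                    k[s][col] += source[s][row] * wk[s][row][col]
                    v[s][col] += source[s][row] * wv[s][row][col]
        outs = []
        for i in range(3):
            scores = []
            for j in range(3):
                dot = 0.0
                for t in range(dh):
                    dot += q[i][lo + t] * k[j][lo + t]
                scores.append(dot / math.sqrt(dh))
            exps = [math.exp(s - max(scores)) for s in scores]
            z = sum(exps)
            probs = [e / z for e in exps]
            for j in range(3):
                all_probs[head][i][j] = probs[j]
            out_i = np.zeros(dh)
            for j in range(3):
                for t in range(dh):
                    out_i[t] += probs[j] * v[j][lo + t]
            outs.append(out_i)
            head_outputs[i].append(out_i)
        if cascade:
            for i in range(3):
                for t in range(dh):
                    running[i][lo + t] += outs[i][t]

    attended = []
    for i in range(3):
        concat_out = np.concatenate(head_outputs[i])
        if residual == "ADD":
            attended.append(originals[i] + concat_out)
        else:
            attended.append(concat_out)
    return attended, all_probs


def auc_pair_counting(scores, labels) -> float:
    """Exhaustive positive/negative pair counting with ties worth 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            if p > n:
                total += 1.0
            elif p == n:
                total += 0.5
    return total / (len(pos) * len(neg))


def permutation_auc_diff_test(scores_a, scores_b, labels, n_perm=10000, seed=0) -> float:
    """Two-sided permutation p-value for the paired AUC difference.

    Randomly swaps the two models' scores per case (sign-flip of the paired
    difference structure) and compares |AUC_a - AUC_b| against the null.
    """
    from bpfuse.evaluation import auc

    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    observed = abs(auc(scores_a, labels) - auc(scores_b, labels))
    rng = np.random.default_rng(seed)
    count = 0
    n = len(labels)
    for _ in range(n_perm):
        swap = rng.random(n) < 0.5
        sa = np.where(swap, scores_b, scores_a)
        sb = np.where(swap, scores_a, scores_b)
        if abs(auc(sa, labels) - auc(sb, labels)) >= observed - 1e-12:
            count += 1
    return count / n_perm
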