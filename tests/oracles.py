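"""Independent brute-force oracles used by the unit and acceptance tests.

Each function implements the mathematical definition directly (explicit sums,
loops, enumeration), deliberately avoiding the code paths of the package and
the vectorised library routines they wrap.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np


def dft_amplitude_direct(x: np.ndarray) -> np.ndarray:
    """One-sided amplitude spectrum by the O(N^2) sum definition."""
    n = len(x)
    out = []
    for k in range(n // 2 + 1):
        re = sum(x[i] * math.cos(2 * math.pi * k * i / n) for i in range(n))
        im = -sum(x[i] * math.sin(2 * math.pi * k * i / n) for i in range(n))
        out.append(math.sqrt(re * re + im * im))
    return np.array(out)


def dwt_direct(x: np.ndarray, dec_lo: np.ndarray, dec_hi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Single-level DWT: symmetric half-point extension, convolve, decimate.

    The signal is extended by L-1 samples on each side (mirror without
    repeating the edge sample's neighbour order), fully convolved with each
    analysis filter and decimated by 2 starting at index L, producing
    floor((n + L - 1) / 2) coefficients per band.
    """
    n, L = len(x), len(dec_lo)
    n_out = (n + L - 1) // 2
    ext = np.concatenate([x[:L - 1][::-1], x, x[-(L - 1):][::-1]])
    bands = []
    for filt in (dec_lo, dec_hi):
        full = np.convolve(ext, filt)
        bands.append(full[L:L + 2 * n_out:2])
    return bands[0], bands[1]


def gelu_direct(x):
    return 0.5 * x * (1.0 + math.erf(x / math.sqrt(2.0)))


def attention_pool_direct(Y: np.ndarray, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Softmax-weighted column pooling by explicit loops."""
    C, T = Y.shape
    scores = [sum(w[c] * Y[c, t] for c in range(C)) for t in range(T)]
    m = max(scores)
    exps = [math.exp(s - m) for s in scores]
    z = sum(exps)
    alpha = np.array([e / z for e in exps])
    pooled = np.array([sum(alpha[t] * Y[c, t] for t in range(T)) for c in range(C)])
    return pooled, alpha


def cmix_stage_direct(x: np.ndarray, token_w: np.ndarray, token_b: np.ndarray,
                      chan_w: np.ndarray, chan_b: np.ndarray) -> np.ndarray:
    """Residual token mix then residual channel mix, element by element."""
    C, F = x.shape
    g_token = np.empty_like(x)
    for c in range(C):
        for gcol in range(F):
            acc = sum(x[c, f] * token_w[f, gcol] for f in range(F)) + token_b[gcol]
            g_token[c, gcol] = x[c, gcol] + gelu_direct(acc)
    g_chan = np.empty_like(x)
    for d in range(C):
        for f in range(F):
            acc = sum(chan_w[d, c] * g_token[c, f] for c in range(C)) + chan_b[d]
            g_chan[d, f] = g_token[d, f] + gelu_direct(acc)
    return g_chan


def auc_pair_count(y_true, scores) -> float:
    """AUC as the normalized Mann-Whitney pair statistic (ties count 1/2)."""
    pos = [s for s, t in zip(scores, y_true) if t == 1]
    neg = [s for s, t in zip(scores, y_true) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def majority_vote_direct(probs, threshold: float = 0.5) -> int:
    """Voted label by explicit label counting; mean probability on ties."""
    labels = [1 if p >= threshold else 0 for p in probs]
    counts = Counter(labels)
    if counts[1] > counts[0]:
        return 1
    if counts[1] < counts[0]:
        return 0
    return 1 if sum(probs) / len(probs) >= 0.5 else 0


def paired_t_direct(a, b) -> float:
    """Paired t statistic from the textbook formula."""
    d = [x - y for x, y in zip(a, b)]
    k = len(d)
    mean = sum(d) / k
    sd = math.sqrt(sum((x - mean) ** 2 for x in d) / (k - 1))
    return mean / (sd / math.sqrt(k))
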