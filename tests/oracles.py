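"""Independent reference implementations used as test oracles.

Everything here is deliberately naive (double loops, pair counting,
closed-form algebra) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.linalg


# ---------------------------------------------------------------------------
# naive feature functionals (double loops over components and samples)

def naive_variance(S):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    variances = []
    for row in S:
        mu = sum(row) / len(row)
        variances.append(sum((x - mu) ** 2 for x in row) / len(row))
    total = sum(variances)
    return np.array([math.log(v / total) for v in variances])


def naive_bandpower(S):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    out = []
    for row in S:
        out.append(math.log(sum(x * x for x in row) / len(row)))
    return np.array(out)


def naive_energy(S):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    return np.array([sum(x * x for x in row) for row in S])


def naive_threshold_entropy(S, alpha=0.2):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    return np.array([float(sum(1 for x in row if abs(x) > alpha)) for row in S])


def naive_norm_entropy(S, p=1.1):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    return np.array([sum(abs(x) ** p for x in row) for row in S])


def naive_sure_entropy(S, q=3.0):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    out = []
    for row in S:
        n_below = sum(1 for x in row if abs(x) <= q)
        out.append(len(row) - n_below + sum(min(x * x, q * q) for x in row))
    return np.array(out)


def naive_log_energy_entropy(S):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    out = []
    for row in S:
        out.append(sum(math.log(x * x) for x in row if x != 0.0))
    return np.array(out)


def naive_shannon_entropy(S):
    S = np.atleast_2d(np.asarray(S, dtype=float))
    out = []
    for row in S:
        out.append(sum(x * x * math.log(x * x) for x in row if x != 0.0))
    return np.array(out)


# ---------------------------------------------------------------------------
# CSP via generalized eigendecomposition: C_a v = lambda (C_a + C_b) v

def generalized_csp(C_a, C_b):
    """Eigenvalues (descending) and filters (rows) from scipy's GEVD."""
    vals, vecs = scipy.linalg.eigh(C_a, C_a + C_b)
    order = np.argsort(vals)[::-1]
    return vals[order], vecs[:, order].T


# ---------------------------------------------------------------------------
# AUC by Mann-Whitney pair counting

def pair_count_auc(scores, labels, positive):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == positive]
    neg = scores[labels != positive]
    wins = 0.0
    for sp in pos:
        for sn in neg:
            if sp > sn:
                wins += 1.0
            elif sp == sn:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# minimal EDF writer (synthetic fixtures only; no EDF export library exists
# in the environment, and this writer is never part of the package surface)

def write_synthetic_edf(path, data, fs, channel_names):
    """Write a one-file EDF with a 1:1 digital/physical mapping.

    ``data`` is rounded to integers; record duration is 1 s, so ``fs`` must
    be an integer and the sample count a multiple of ``fs``.
    """
    data = np.asarray(data)
    ch, n = data.shape
    fs = int(fs)
    assert n % fs == 0, "sample count must be a multiple of fs"
    n_records = n // fs

    def field(text, width):
        text = str(text)[:width]
        return text.ljust(width).encode("ascii")

    header = b"".join([
        field("0", 8),
        field("synthetic fixture", 80),
        field("pdcsp test", 80),
        field("01.01.20", 8),
        field("00.00.00", 8),
        field(256 * (ch + 1), 8),
        field("", 44),
        field(n_records, 8),
        field("1", 8),
        field(ch, 4),
    ])
    per_signal = [
        (channel_names, 16),
        (["" for _ in range(ch)], 80),       # transducer
        (["" for _ in range(ch)], 8),        # physical dimension
        ([-32768] * ch, 8),                  # physical minimum
        ([32767] * ch, 8),                   # physical maximum
        ([-32768] * ch, 8),                  # digital minimum
        ([32767] * ch, 8),                   # digital maximum
        (["" for _ in range(ch)], 80),       # prefiltering
        ([fs] * ch, 8),                      # samples per record
        (["" for _ in range(ch)], 32),       # reserved
    ]
    for values, width in per_signal:
        header += b"".join(field(v, width) for v in values)

    digital = np.rint(data).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for r in range(n_records):
            for c in range(ch):
                fh.write(digital[c, r * fs:(r + 1) * fs].tobytes())
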