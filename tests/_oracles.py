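"""Independent brute-force reference implementations used only by tests.

Every function here is written as a direct, naive transcription of the
defining formula (explicit Python loops, no shared code with the package)
so it can serve as an oracle for the vectorised implementations.
"""

from __future__ import annotations

import math

import numpy as np


def iir_difference_equation(b, a, x):
    """Direct-form causal recursion y(n) = (sum b x - sum a y) / a0."""
    b = [float(v) for v in b]
    a = [float(v) for v in a]
    y = [0.0] * len(x)
    for n in range(len(x)):
        acc = 0.0
        for i, bi in enumerate(b):
            if bi and n - i >= 0:
                acc += bi * x[n - i]
        for j, aj in enumerate(a[1:], start=1):
            if aj and n - j >= 0:
                acc -= aj * y[n - j]
        y[n] = acc / a[0]
    return np.asarray(y)


def polynomial_response(b, a, f, fs):
    """Transfer function evaluated on the unit circle at frequency f."""
    z = np.exp(-1j * 2 * np.pi * f / fs)
    num = sum(bi * z**i for i, bi in enumerate(b))
    den = sum(aj * z**j for j, aj in enumerate(a))
    return num / den


def sample_entropy(x, m, r):
    """Naive O(n^2) template-pair counting sample entropy."""
    x = list(map(float, x))
    n = len(x)
    nt = n - m
    b_count = 0
    a_count = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b_count += 1
            if max(abs(x[i + k] - x[j + k]) for k in range(m + 1)) <= r:
                a_count += 1
    if b_count == 0 or a_count == 0:
        return math.nan
    return -math.log(a_count / b_count)


def permutation_entropy(x, m):
    """Ordinal-pattern entropy by explicit pattern enumeration (nats)."""
    x = list(map(float, x))
    counts: dict[tuple, int] = {}
    for i in range(len(x) - m + 1):
        w = x[i : i + m]
        pattern = tuple(sorted(range(m), key=lambda k: (w[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    total = sum(counts.values())
    return -sum((c / total) * math.log(c / total) for c in counts.values())


def shannon_entropy(x, bins):
    """Histogram entropy normalised by log2(bins)."""
    x = list(map(float, x))
    lo, hi = min(x), max(x)
    if lo == hi:
        return 0.0
    width = (hi - lo) / bins
    counts = [0] * bins
    for v in x:
        k = min(int((v - lo) / width), bins - 1)
        counts[k] += 1
    n = len(x)
    h = -sum((c / n) * math.log2(c / n) for c in counts if c)
    return h / math.log2(bins)


def turning_point_ratio(x):
    x = list(map(float, x))
    count = 0
    for i in range(1, len(x) - 1):
        if (x[i] - x[i - 1]) * (x[i] - x[i + 1]) > 0:
            count += 1
    return count / len(x)


def poincare(x):
    """Direct-sum evaluation of the lag-1 dispersion statistics."""
    x = list(map(float, x))
    n = len(x)
    mean = sum(x) / n
    s1 = sum((x[i + 1] - x[i]) ** 2 / 2.0 for i in range(n - 1))
    s2 = sum((x[i + 1] + x[i] - 2 * mean) ** 2 / 2.0 for i in range(n - 1))
    sd1 = math.sqrt(s1 / (n - 1))
    sd2 = math.sqrt(s2 / (n - 1))
    return sd1, sd2


def cohen_kappa(counts):
    """Textbook kappa from a square count table."""
    counts = [[float(v) for v in row] for row in counts]
    m = sum(sum(row) for row in counts)
    k = len(counts)
    p1 = sum(counts[i][i] for i in range(k)) / m
    p2 = sum(
        sum(counts[i]) * sum(counts[j][i] for j in range(k)) for i in range(k)
    ) / m**2
    return (p1 - p2) / (1 - p2)
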