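"""Brute-force oracle implementations of every texture feature.

Deliberately naive, dictionary/loop-based re-derivations from first
principles, independent of the vectorized package code.  Used to freeze
expected values and for randomized equivalence testing.
"""

from __future__ import annotations

import math
from collections import Counter


def oracle_histogram(values, bits=8):
    values = [int(v) for v in values]
    counts = Counter(values)
    n = len(values)
    return {k: counts.get(k, 0) / n for k in range(1 << bits)}


def oracle_hs(values, bits=8, window=10):
    """Direct-summation first-order features from the raw pixel list."""
    values = [int(v) for v in values]
    n = len(values)
    k_max = 1 << bits
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    if var > 0:
        skew = sum((v - mean) ** 3 for v in values) / n / var**1.5
        kurt = sum((v - mean) ** 4 for v in values) / n / var**2 - 3.0
    else:
        skew = kurt = 0.0
    hist = oracle_histogram(values, bits)

    counts = Counter(values)

    def perc(q):
        cum = 0
        for k in range(k_max):
            cum += counts.get(k, 0)
            if cum >= q * n:
                return float(k)
        return float(k_max - 1)

    moving = [
        sum(hist[k + t] for t in range(window)) for k in range(k_max - window + 1)
    ]
    maxm01 = max(hist.values())
    domn01 = min(k for k, h in hist.items() if h == maxm01)
    maxm10 = max(moving)
    domn10 = moving.index(maxm10)
    return {
        "Mean": mean,
        "Variance": var,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Perc01": perc(0.01),
        "Perc10": perc(0.10),
        "Perc50": perc(0.50),
        "Perc90": perc(0.90),
        "Perc99": perc(0.99),
        "Domn01": float(domn01),
        "Domn10": float(domn10),
        "Maxm01": maxm01,
        "Maxm10": maxm10,
    }


def _lines(plane, direction):
    """All scan lines of a 2-D list along one of the canonical directions."""
    h, w = len(plane), len(plane[0])
    if direction == 0:
        return [[plane[r][c] for c in range(w)] for r in range(h)]
    if direction == 90:
        return [[plane[r][c] for r in range(h)] for c in range(w)]
    if direction == 135:  # top-left to bottom-right diagonals
        return [
            [plane[r][r - k] for r in range(max(0, k), min(h, w + k))]
            for k in range(-(w - 1), h)
        ]
    if direction == 45:  # bottom-left to top-right anti-diagonals
        return [
            [plane[r][s - r] for r in range(min(h - 1, s), max(-1, s - w), -1)]
            for s in range(h + w - 1)
        ]
    raise ValueError(direction)


def oracle_glrlm_counts(plane, direction=0):
    """Run-length counts {(gray, length): n} by explicit scan enumeration."""
    runs = Counter()
    for line in _lines(plane, direction):
        i = 0
        while i < len(line):
            j = i
            while j < len(line) and line[j] == line[i]:
                j += 1
            runs[(int(line[i]), j - i)] += 1
            i = j
    return dict(runs)


def oracle_glrlm_features(runs):
    np_runs = sum(runs.values())
    levels = Counter()
    lengths = Counter()
    for (i, j), c in runs.items():
        levels[i] += c
        lengths[j] += c
    return {
        "GLN": sum(c**2 for c in levels.values()) / np_runs,
        "RLN": sum(c**2 for c in lengths.values()) / np_runs,
        "LRE": sum(j**2 * c for (_, j), c in runs.items()) / np_runs,
        "SRE": sum(c / j**2 for (_, j), c in runs.items()) / np_runs,
        "Fraction": np_runs / sum(j * c for (_, j), c in runs.items()),
        "MRLN": sum(c**2 for c in lengths.values()) / np_runs**2,
        "MGLN": sum(c**2 for c in levels.values()) / np_runs**2,
    }


_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_glcm_probs(plane, distance=1, direction=0):
    """Symmetric normalized co-occurrence {(a, b): p} by pair enumeration."""
    h, w = len(plane), len(plane[0])
    dr, dc = _OFFSETS[direction]
    dr, dc = dr * distance, dc * distance
    pairs = Counter()
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                a, b = int(plane[r][c]), int(plane[r2][c2])
                pairs[(a, b)] += 1
                pairs[(b, a)] += 1
    total = sum(pairs.values())
    return {k: v / total for k, v in pairs.items()}


def oracle_glcm_features(probs, log_base=2.0):
    px = Counter()
    py = Counter()
    psum = Counter()
    pdiff = Counter()
    for (i, j), p in probs.items():
        px[i] += p
        py[j] += p
        psum[i + j] += p
        pdiff[abs(i - j)] += p
    mu_x = sum(i * p for i, p in px.items())
    mu_y = sum(j * p for j, p in py.items())
    sd_x = math.sqrt(sum((i - mu_x) ** 2 * p for i, p in px.items()))
    sd_y = math.sqrt(sum((j - mu_y) ** 2 * p for j, p in py.items()))
    mu_sum = sum(k * p for k, p in psum.items())
    mu_diff = sum(k * p for k, p in pdiff.items())

    def ent(dist):
        return -sum(p * math.log(p, log_base) for p in dist.values() if p > 0)

    if sd_x > 0 and sd_y > 0:
        correlat = (
            sum(i * j * p for (i, j), p in probs.items()) - mu_x * mu_y
        ) / (sd_x * sd_y)
    else:
        correlat = 0.0
    return {
        "AngScMom": sum(p**2 for p in probs.values()),
        "Contrast": sum((i - j) ** 2 * p for (i, j), p in probs.items()),
        "Correlat": correlat,
        "SumOfSqs": sum((i - mu_x) ** 2 * p for (i, j), p in probs.items()),
        "InvDefMom": sum(p / (1 + (i - j) ** 2) for (i, j), p in probs.items()),
        "SumAverg": mu_sum,
        "SumVarnc": sum((k - mu_sum) ** 2 * p for k, p in psum.items()),
        "SumEntrp": ent(psum),
        "Entropy": ent(probs),
        "DifVarnc": sum((k - mu_diff) ** 2 * p for k, p in pdiff.items()),
        "DifEntrp": ent(pdiff),
    }


def oracle_texture_vector(plane, bits=8, distance=1, glcm_directions=(0, 45, 90, 135),
                          glrlm_direction=0, window=10):
    """All 31 features from the oracles, matching the package's conventions."""
    flat = [int(v) for row in plane for v in row]
    out = dict(oracle_hs(flat, bits, window))
    out.update(oracle_glrlm_features(oracle_glrlm_counts(plane, glrlm_direction)))
    per_dir = [
        oracle_glcm_features(oracle_glcm_probs(plane, distance, d))
        for d in glcm_directions
    ]
    for name in per_dir[0]:
        out[name] = sum(d[name] for d in per_dir) / len(per_dir)
    return out
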