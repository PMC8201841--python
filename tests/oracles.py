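"""Independent brute-force oracles, deliberately coded apart from the package.

These recompute the same quantities by naive enumeration so that the
package implementations can be checked against a second, independent path.
"""

import numpy as np


def rr_oracle(window, periods, breaths):
    """Naive cycle enumerator for the respiratory rate.

    ``window``: (start, end); ``periods``: sorted disjoint (s, e) pairs
    clipped to the window; ``breaths``: certain-breath times (any order).
    Returns (rr_bpm, numerator, calm_duration) or None when no calm time.
    """
    w0, w1 = window
    # calm pieces by sweeping over all breakpoints and testing midpoints
    points = sorted({w0, w1, *(x for p in periods for x in p)})
    calm = []
    for a, b in zip(points, points[1:]):
        mid = (a + b) / 2.0
        if w0 <= mid < w1 and not any(s <= mid < e for s, e in periods):
            if calm and calm[-1][1] == a:
                calm[-1] = (calm[-1][0], b)
            else:
                calm.append((a, b))
    calm_duration = sum(b - a for a, b in calm)
    if calm_duration <= 0:
        return None
    per_seg = []
    for a, b in calm:
        inside = sorted(t for t in breaths if a <= t < b)
        per_seg.append((a, b, inside))
    all_gaps = []
    for a, b, inside in per_seg:
        for t0, t1 in zip(inside, inside[1:]):
            all_gaps.append(t1 - t0)
    numerator = 0.0
    for a, b, inside in per_seg:
        if not inside:
            continue
        numerator += len(inside) - 1
        if len(inside) >= 2:
            gaps = [t1 - t0 for t0, t1 in zip(inside, inside[1:])]
            ref = sum(gaps) / len(gaps)
        elif all_gaps:
            ref = sum(all_gaps) / len(all_gaps)
        else:
            ref = None
        if ref is not None:
            numerator += (inside[0] - a) / ref + (b - inside[-1]) / ref
    return 60.0 * numerator / calm_duration, numerator, calm_duration


def kruskal_h_oracle(groups):
    """Tie-corrected Kruskal-Wallis H by the textbook formula, from scratch."""
    pooled = [x for g in groups for x in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for m in range(i, j + 1):
            ranks[order[m]] = avg
        i = j + 1
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start: start + len(g)])
        h += r * r / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    from collections import Counter

    ties = Counter(pooled)
    c = 1.0 - sum(t**3 - t for t in ties.values()) / (n**3 - n)
    return h / c if c > 0 else float("nan")


def fleiss_kappa_oracle(counts):
    """Fleiss' kappa by direct summation (independent of the package)."""
    counts = np.asarray(counts, dtype=float)
    n, _ = counts.shape
    k = counts[0].sum()
    p_agree = []
    for row in counts:
        pairs = sum(c * (c - 1) for c in row)
        p_agree.append(pairs / (k * (k - 1)))
    pbar = sum(p_agree) / n
    pj = counts.sum(axis=0) / (n * k)
    pe = sum(p * p for p in pj)
    if pe == 1:
        return None
    return (pbar - pe) / (1 - pe)


def random_rr_instance(rng):
    """Random small RR instance: window, disjoint periods, breath times."""
    L = rng.uniform(10.0, 80.0)
    n_periods = rng.integers(0, 4)
    cuts = np.sort(rng.uniform(0.0, L, size=2 * n_periods))
    periods = [(float(cuts[2 * i]), float(cuts[2 * i + 1])) for i in range(n_periods)]
    periods = [(s, e) for s, e in periods if e > s]
    n_breaths = rng.integers(0, 16)
    breaths = np.sort(rng.uniform(0.0, L, size=n_breaths))
    breaths = np.unique(breaths)
    return (0.0, float(L)), periods, [float(t) for t in breaths]
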