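"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and ``math.fsum`` so
that it shares no code path (and no vectorised summation order) with the
package under test.
"""

from __future__ import annotations

import itertools
import math


# ---------------------------------------------------------------------------
# Moment statistics


def central_moment(xs, k):
    xs = [float(v) for v in xs]
    mean = math.fsum(xs) / len(xs)
    return math.fsum((v - mean) ** k for v in xs) / len(xs)


def kurtosis_oracle(xs, estimator="G2"):
    n = len(xs)
    m2 = central_moment(xs, 2)
    m4 = central_moment(xs, 4)
    g2 = m4 / m2**2 - 3.0
    if estimator == "g2":
        return g2
    if estimator == "G2":
        return ((n + 1) * g2 + 6) * (n - 1) / ((n - 2) * (n - 3))
    if estimator == "b2":
        s2 = n * m2 / (n - 1)
        return m4 / s2**2 - 3.0
    raise ValueError(estimator)


def median_oracle(xs):
    xs = sorted(float(v) for v in xs)
    n = len(xs)
    mid = n // 2
    return xs[mid] if n % 2 else (xs[mid - 1] + xs[mid]) / 2.0


def pcd_oracle(xs, ddof=1):
    n = len(xs)
    mean = math.fsum(float(v) for v in xs) / n
    var = math.fsum((float(v) - mean) ** 2 for v in xs) / (n - ddof)
    return 3.0 * (mean - median_oracle(xs)) / math.sqrt(var)


# ---------------------------------------------------------------------------
# SphI exhaustive scan


def _smooth_oracle(counts, window):
    """Centered moving sum with reflected ends (pure loops, exact ints)."""
    n = len(counts)
    half = window // 2
    out = []
    for j in range(n):
        acc = 0
        for k in range(-half, half + 1):
            idx = j + k
            if idx < 0:
                idx = -idx
            elif idx > n - 1:
                idx = 2 * (n - 1) - idx
            acc += int(counts[idx])
        out.append(acc)
    return out


def _local_maxima_oracle(x):
    """Local maxima with plateau handling: the midpoint of each flat top
    that is strictly above both neighbours.  Edges are never peaks."""
    peaks = []
    n = len(x)
    i = 1
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[i]:
                j += 1
            if j < n - 1 and x[j + 1] < x[i]:
                peaks.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def _prominence_oracle(x, peak):
    """Topographic prominence: walk out on each side until a strictly
    higher sample (or the signal end); the base is the higher of the two
    side minima."""
    h = x[peak]
    left_min = h
    i = peak
    while i >= 0 and x[i] <= h:
        left_min = min(left_min, x[i])
        i -= 1
    right_min = h
    i = peak
    while i < len(x) and x[i] <= h:
        right_min = min(right_min, x[i])
        i += 1
    return h - max(left_min, right_min)


def _part_median_oracle(channels, counts):
    total = sum(counts)
    if total == 0:
        return None
    acc = 0
    for ch, c in zip(channels, counts):
        acc += c
        if 2 * acc >= total:
            return ch
    raise AssertionError("unreachable")


def sphi_oracle(counts, window=9, min_prominence_fraction=0.05):
    """Exhaustive-scan SphI: every minimum, mode and median is found by
    scanning all channels; returns (sphi-or-None, details dict)."""
    counts = [int(c) for c in counts]
    smoothed = _smooth_oracle(counts, window)
    threshold = min_prominence_fraction * max(smoothed)
    cands = [(p, _prominence_oracle(smoothed, p)) for p in _local_maxima_oracle(smoothed)]
    qual = [(p, pr) for p, pr in cands if pr > threshold]
    qual.sort(key=lambda t: (-t[1], t[0]))
    top = sorted(p for p, _ in qual[:2])
    details = {"bimodal": len(top) == 2}
    if len(top) < 2:
        return None, details
    p1, p2 = top
    split, best = None, None
    for c in range(p1 + 1, p2):
        if best is None or smoothed[c] < best:
            best, split = smoothed[c], c
    mode_lower, best = 0, counts[0]
    for c in range(split + 1):
        if counts[c] > best:
            best, mode_lower = counts[c], c
    mode_upper, best = split + 1, counts[split + 1]
    for c in range(split + 1, len(counts)):
        if counts[c] > best:
            best, mode_upper = counts[c], c
    cutoff = (mode_lower + mode_upper) / 2.0
    boundary = math.floor(cutoff)
    med_lo = _part_median_oracle(range(boundary + 1), counts[: boundary + 1])
    med_hi = _part_median_oracle(
        range(boundary + 1, len(counts)), counts[boundary + 1 :]
    )
    details.update(
        split_channel=split, mode_lower=mode_lower, mode_upper=mode_upper,
        cutoff_channel=cutoff, median_lower=med_lo, median_upper=med_hi,
    )
    if med_lo is None or med_hi is None or med_lo == 0:
        return None, details
    return med_hi / med_lo, details


# ---------------------------------------------------------------------------
# Rank statistics


def rank_oracle(xs):
    """Average ranks (1-based) with ties."""
    order = sorted(range(len(xs)), key=lambda i: xs[i])
    ranks = [0.0] * len(xs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and xs[order[j + 1]] == xs[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    rx, ry = rank_oracle(list(x)), rank_oracle(list(y))
    n = len(rx)
    mx, my = math.fsum(rx) / n, math.fsum(ry) / n
    num = math.fsum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        math.fsum((a - mx) ** 2 for a in rx) * math.fsum((b - my) ** 2 for b in ry)
    )
    return num / den


def friedman_statistic_oracle(matrix):
    """Tie-corrected Friedman chi-square from first principles."""
    n = len(matrix)
    k = len(matrix[0])
    col_sums = [0.0] * k
    tie_term = 0.0
    for row in matrix:
        ranks = rank_oracle(list(row))
        for j, r in enumerate(ranks):
            col_sums[j] += r
        seen = {}
        for v in row:
            seen[v] = seen.get(v, 0) + 1
        tie_term += sum(t**3 - t for t in seen.values())
    denom = 1.0 - tie_term / (n * k * (k * k - 1))
    if denom <= 0:
        return 0.0
    raw = 12.0 / (n * k * (k + 1)) * math.fsum(s * s for s in col_sums) - 3.0 * n * (k + 1)
    return raw / denom


def friedman_permutation_pvalue(matrix):
    """Exact permutation p-value of the Friedman statistic: enumerate all
    within-row orderings (feasible for tiny designs only)."""
    observed = friedman_statistic_oracle(matrix)
    k = len(matrix[0])
    perms = list(itertools.permutations(range(k)))
    total = 0
    at_least = 0
    for combo in itertools.product(perms, repeat=len(matrix)):
        permuted = [[row[p[j]] for j in range(k)] for row, p in zip(matrix, combo)]
        total += 1
        if friedman_statistic_oracle(permuted) >= observed - 1e-12:
            at_least += 1
    return at_least / total


# ---------------------------------------------------------------------------
# Balanced one-way random-effects ML closed form


def ml_variance_components_oracle(values_by_subject):
    """ML estimates for the balanced random-intercept model.

    ``values_by_subject`` is a list of equal-length per-subject lists.
    Returns (mu, var_between, var_within); no boundary truncation, so
    only valid where the between-subject signal is clearly positive.
    """
    a = len(values_by_subject)
    m = len(values_by_subject[0])
    assert all(len(v) == m for v in values_by_subject)
    grand = math.fsum(math.fsum(v) for v in values_by_subject) / (a * m)
    subj_means = [math.fsum(v) / m for v in values_by_subject]
    ssw = math.fsum(
        math.fsum((x - mu_i) ** 2 for x in v)
        for v, mu_i in zip(values_by_subject, subj_means)
    )
    var_within = ssw / (a * (m - 1))
    var_between = math.fsum((mu_i - grand) ** 2 for mu_i in subj_means) / a - var_within / m
    return grand, var_between, var_within
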