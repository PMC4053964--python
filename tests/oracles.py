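"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's vectorized helpers: everything is
plain Python loops implementing the declared rules directly, so agreement
with the implementation is a meaningful check.
"""

import numpy as np


def smooth_bruteforce(depth, sigma):
    """Edge-renormalized Gaussian moving average, O(n*k) double loop."""
    import math

    radius = max(1, int(math.ceil(4 * sigma)))
    n = len(depth)
    out = np.zeros(n)
    for i in range(n):
        num = den = 0.0
        for k in range(-radius, radius + 1):
            j = i + k
            if 0 <= j < n:
                w = math.exp(-0.5 * (k / sigma) ** 2)
                num += w * depth[j]
                den += w
        out[i] = num / den
    return out


def segment_bruteforce(smoothed, tc_depth):
    """Exhaustive scan implementing the segmentation rule.

    One site per local maximum (plateaus collapse to the left-biased
    midpoint), bounded by the nearest second-difference sign change on each
    side (zeros adopt the next nonzero sign to the right); cluster ends
    otherwise; overlapping neighbors truncated left-to-right; sites without
    conversion-positive positions dropped. Returns [(start, end)] half-open
    relative to the cluster.
    """
    s = list(smoothed)
    L = len(s)

    maxima = []
    i = 0
    while i < L:
        j = i
        while j + 1 < L and s[j + 1] == s[i]:
            j += 1
        if (i == 0 or s[i - 1] < s[i]) and (j == L - 1 or s[j + 1] < s[j]):
            maxima.append((i + j) // 2)
        i = j + 1

    # second-difference sign at interior positions 1..L-2
    sign_at = {}
    pending = []
    for p in range(1, L - 1):
        d2 = s[p + 1] - 2 * s[p] + s[p - 1]
        if d2 > 0:
            sig = 1
        elif d2 < 0:
            sig = -1
        else:
            pending.append(p)
            continue
        for q in pending:
            sign_at[q] = sig
        pending = []
        sign_at[p] = sig
    for q in pending:
        sign_at[q] = 0

    inflections = []
    for p in range(2, L - 1):
        a, b = sign_at.get(p - 1, 0), sign_at.get(p, 0)
        if a != 0 and b != 0 and a != b:
            inflections.append(p)

    sites = []
    for m in maxima:
        lo = 0
        for p in inflections:
            if p <= m and p > lo:
                lo = p
        hi = L - 1
        for p in reversed(inflections):
            if p >= m and p < hi:
                hi = p
        sites.append([lo, hi + 1])
    sites.sort()
    for k in range(1, len(sites)):
        if sites[k][0] < sites[k - 1][1]:
            sites[k][0] = sites[k - 1][1]
    out = []
    for lo, hi in sites:
        if hi <= lo:
            continue
        if any(tc_depth[q] > 0 for q in range(lo, hi)):
            out.append((lo, hi))
    return out


def random_profile(rng, max_len=500):
    """A random nonnegative coverage profile: a few smooth bumps plus
    integer noise, mimicking read pileups."""
    n = int(rng.integers(10, max_len + 1))
    x = np.arange(n)
    prof = np.zeros(n)
    for _ in range(int(rng.integers(1, 4))):
        center = rng.uniform(0, n)
        width = rng.uniform(2, max(3.0, n / 4))
        height = rng.uniform(1, 50)
        prof += height * np.exp(-0.5 * ((x - center) / width) ** 2)
    prof += rng.integers(0, 3, size=n)
    return np.maximum(prof, 0.0) + 1.0  # clusters have depth >= 1
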