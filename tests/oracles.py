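"""Independent brute-force oracles used by the unit and acceptance tests.

Deliberately naive: plain Python loops and first-principles formulas, sharing
no code path with the package implementation.
"""

import statistics


def brute_force_zc_peaks(x, fs_hz, maxima_fraction=0.4, maxima_window_s=2.5, refractory_fraction=0.5):
    """Exhaustive scan: local-maximum test by direct comparison, threshold by
    a naive clipped-window max of |x|, then greedy left-to-right refractory
    acceptance keeping the larger peak on conflict."""
    x = list(map(float, x))
    n = len(x)
    half = int(round(maxima_window_s * fs_hz / 2))
    candidates = []
    for i in range(1, n - 1):
        if not x[i] > x[i - 1]:
            continue
        j = i
        while j + 1 < n and x[j + 1] == x[i]:
            j += 1
        if j + 1 >= n or not x[j + 1] < x[i]:
            continue  # plateau runs to the end or never falls
        lo, hi = max(0, i - half), min(n, i + half + 1)
        threshold = maxima_fraction * max(abs(v) for v in x[lo:hi])
        if x[i] > threshold:
            candidates.append(i)
    if refractory_fraction is not None and len(candidates) >= 2:
        gaps = [candidates[k + 1] - candidates[k] for k in range(len(candidates) - 1)]
        gap = refractory_fraction * statistics.median(gaps)
        accepted = []
        for i in candidates:
            if accepted and i - accepted[-1] < gap:
                if x[i] > x[accepted[-1]]:
                    accepted[-1] = i
            else:
                accepted.append(i)
        candidates = accepted
    return candidates


def icc_2_1_oracle(a, b):
    """ICC(2,1) from first-principles sums of squares (SSE via SST - SSR - SSC)."""
    a = list(map(float, a))
    b = list(map(float, b))
    n, k = len(a), 2
    rows = list(zip(a, b))
    grand = sum(v for r in rows for v in r) / (n * k)
    row_means = [sum(r) / k for r in rows]
    col_means = [sum(a) / n, sum(b) / n]
    ssr = k * sum((m - grand) ** 2 for m in row_means)
    ssc = n * sum((m - grand) ** 2 for m in col_means)
    sst = sum((v - grand) ** 2 for r in rows for v in r)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def rolling_max_oracle(x, fs_hz, window_s):
    """Naive centered clipped-window maximum of |x|."""
    x = [abs(float(v)) for v in x]
    n = len(x)
    half = int(round(window_s * fs_hz / 2))
    return [max(x[max(0, i - half): min(n, i + half + 1)]) for i in range(n)]
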