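"""Independent brute-force oracles for feature post-conditions.

Pure-Python reimplementations kept deliberately separate from the package's
vectorized code paths; used to pin down expected values in tests.
"""

from __future__ import annotations

import itertools
import math


def lcs_brute(a: list[str], b: list[str]) -> int:
    """Longest common subsequence by exhaustive subsequence enumeration.

    Only feasible for len(a) <= ~14.
    """
    best = 0
    for r in range(len(a), 0, -1):
        for combo in itertools.combinations(a, r):
            # is combo a subsequence of b?
            it = iter(b)
            if all(word in it for word in combo):
                return r
    return best


def intertap_oracle(t_s: list[float], phases: list[str]) -> float:
    """Mean lift-off -> next touch-down interval (ms) by explicit pairing."""
    events = sorted(zip(t_s, phases))
    intervals = []
    pending_up = None
    for t, phase in events:
        if phase == "up":
            pending_up = t
        elif phase == "down" and pending_up is not None:
            intervals.append(t - pending_up)
            pending_up = None
    assert intervals, "oracle needs at least one completed in-air interval"
    return sum(intervals) / len(intervals) * 1000.0


def speed_cv_oracle(t_s: list[float], x: list[float], y: list[float]) -> float:
    """CV of instantaneous speeds, population SD, explicit loops."""
    speeds = []
    for i in range(len(t_s) - 1):
        d = math.hypot(x[i + 1] - x[i], y[i + 1] - y[i])
        speeds.append(d / (t_s[i + 1] - t_s[i]))
    mean = sum(speeds) / len(speeds)
    var = sum((s - mean) ** 2 for s in speeds) / len(speeds)
    return math.sqrt(var) / mean


def sway_path_oracle(acc: list[tuple[float, float, float]]) -> float:
    total = 0.0
    for i in range(len(acc) - 1):
        dx = acc[i + 1][0] - acc[i][0]
        dy = acc[i + 1][1] - acc[i][1]
        dz = acc[i + 1][2] - acc[i][2]
        total += math.sqrt(dx * dx + dy * dy + dz * dz)
    return total


def freq_variance_oracle(step_times: list[float]) -> float:
    freqs = [1.0 / (step_times[i + 1] - step_times[i]) for i in range(len(step_times) - 1)]
    mean = sum(freqs) / len(freqs)
    return sum((f - mean) ** 2 for f in freqs) / len(freqs)


def median_oracle(values: list[float]) -> float:
    s = sorted(values)
    n = len(s)
    mid = n // 2
    if n % 2:
        return s[mid]
    return 0.5 * (s[mid - 1] + s[mid])


def icc_a1_oracle(pairs: list[tuple[float, float]]) -> float:
    """ICC(A,1) from an explicitly computed two-way ANOVA table."""
    n = len(pairs)
    k = 2
    all_vals = [v for pair in pairs for v in pair]
    grand = sum(all_vals) / (n * k)
    row_means = [(a + b) / 2 for a, b in pairs]
    col_means = [sum(p[j] for p in pairs) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((v - grand) ** 2 for v in all_vals)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
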