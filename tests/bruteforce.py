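"""Independent brute-force oracles for trajectory measures.

Deliberately written as plain-Python scans over sample lists, sharing no
code with the package, so they can certify the vectorized
implementations.
"""

import math


def angle_of(x, y):
    return math.degrees(math.atan2(-x, y))


def ia_scan(samples, threshold=1.2):
    """(index, angle) of the first sample at least `threshold` from start."""
    for i, (t, x, y) in enumerate(samples):
        if math.sqrt(x * x + y * y) >= threshold:
            return i, angle_of(x, y)
    return None


def final_angle_scan(samples):
    t, x, y = samples[-1]
    return angle_of(x, y)


def path_length_ratio_scan(samples):
    total = 0.0
    for (t0, x0, y0), (t1, x1, y1) in zip(samples, samples[1:]):
        total += math.hypot(x1 - x0, y1 - y0)
    chord = math.hypot(samples[-1][1] - samples[0][1], samples[-1][2] - samples[0][2])
    return total / chord


def onset_scan(samples, t_click):
    for i in range(1, len(samples)):
        moved = samples[i][1] != samples[i - 1][1] or samples[i][2] != samples[i - 1][2]
        if moved and samples[i][0] > t_click:
            return i
    return None


def correction_scan(samples, t_click, window=5.0, threshold=1.2):
    """Normalized correction time by first-exit scan, or None."""
    hit = ia_scan(samples, threshold)
    if hit is None:
        return None
    i, ia = hit
    onset = onset_scan(samples, t_click)
    if onset is None:
        return None
    movement = samples[-1][0] - samples[onset][0]
    if movement <= 0:
        return None
    for j in range(i + 1, len(samples)):
        if abs(angle_of(samples[j][1], samples[j][2]) - ia) > window:
            return (samples[j][0] - samples[onset][0]) / movement
    return None


def angle_spread_scan(samples, threshold=1.2):
    hit = ia_scan(samples, threshold)
    if hit is None:
        return None
    i, _ = hit
    angles = [angle_of(x, y) for (t, x, y) in samples[i:]]
    return max(angles) - min(angles)


def timing_scan(samples, t_trial_start, t_click):
    onset = onset_scan(samples, t_click)
    reaction = t_click - t_trial_start
    stationary = samples[onset][0] - t_click
    movement = samples[-1][0] - samples[onset][0]
    return reaction, stationary, movement


def state_recursion(retention, rate, errors, x0=0.0):
    """Closed-form scalar state recursion x[n+1] = A x[n] - B e[n]; returns
    the state before each trial."""
    xs = []
    x = x0
    for e in errors:
        xs.append(x)
        x = retention * x - rate * e
    return xs
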