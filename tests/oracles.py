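"""Independent naive-loop reference implementations of the colocalization
statistics, used only to cross-check the vectorized package code.  These
deliberately avoid numpy vector operations over the image."""

from __future__ import annotations

import math


def pearson_naive(red, green):
    """Pearson correlation by explicit loops over paired pixel lists."""
    n = len(red)
    if n == 0:
        raise ValueError("empty region")
    mr = sum(red) / n
    mg = sum(green) / n
    num = sum((r - mr) * (g - mg) for r, g in zip(red, green))
    dr = sum((r - mr) ** 2 for r in red)
    dg = sum((g - mg) ** 2 for g in green)
    if dr == 0 or dg == 0:
        return float("nan")
    return num / math.sqrt(dr * dg)


def manders_naive(red, green, t_red, t_green):
    """Mander's M1/M2 by explicit loops (M1: red in green-positive pixels)."""
    sum_r = sum(red)
    sum_g = sum(green)
    m1_num = sum(r for r, g in zip(red, green) if g > t_green)
    m2_num = sum(g for r, g in zip(red, green) if r > t_red)
    m1 = m1_num / sum_r if sum_r > 0 else float("nan")
    m2 = m2_num / sum_g if sum_g > 0 else float("nan")
    return m1, m2


def costes_naive(red, green, step=1.0):
    """Exhaustive Costes threshold search: OLS line, then every candidate
    t_red from max(red) downward; returns the highest t_red whose
    sub-threshold pixels are non-positively correlated."""
    n = len(red)
    mr = sum(red) / n
    mg = sum(green) / n
    sxx = sum((r - mr) ** 2 for r in red)
    sxy = sum((r - mr) * (g - mg) for r, g in zip(red, green))
    a = sxy / sxx
    b = mg - a * mr
    if a <= 0:
        return None  # procedure not applicable

    t = max(red)
    lo = min(red)
    best = None
    while t >= lo - step / 2:
        t_g = a * t + b
        below_r = [r for r, g in zip(red, green) if r < t and g < t_g]
        below_g = [g for r, g in zip(red, green) if r < t and g < t_g]
        if len(below_r) >= 2:
            rho = pearson_naive(below_r, below_g)
            if not math.isnan(rho) and rho <= 0:
                return a, b, t, t_g, rho
        t -= step
    return a, b, None, None, None


def classify_colors_naive(red, green, t_red, t_green):
    """Sequential three-colour classification by loops: yellow = both
    channels above threshold; red = above-threshold red minus yellow;
    green = above-threshold green minus yellow and red."""
    yellow, red_set, green_set = set(), set(), set()
    for i, (r, g) in enumerate(zip(red, green)):
        if r > t_red and g > t_green:
            yellow.add(i)
    for i, (r, g) in enumerate(zip(red, green)):
        if i not in yellow and r > t_red:
            red_set.add(i)
    for i, (r, g) in enumerate(zip(red, green)):
        if i not in yellow and i not in red_set and g > t_green:
            green_set.add(i)
    return yellow, red_set, green_set
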