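"""Independent brute-force implementations of the validation statistics.

Everything here is written directly from the printed formulas with plain
Python loops, deliberately sharing no code with the package, so the two
routes can be compared to machine precision.
"""

from __future__ import annotations

import math


def det_coeff(observed, predicted, center_observed=True):
    n = len(observed)
    ref = (sum(observed) if center_observed else sum(predicted)) / n
    ss_res = sum((predicted[i] - observed[i]) ** 2 for i in range(n))
    ss_tot = sum((observed[i] - ref) ** 2 for i in range(n))
    return 1.0 - ss_res / ss_tot


def rmse(observed, predicted):
    n = len(observed)
    return math.sqrt(sum((observed[i] - predicted[i]) ** 2 for i in range(n)) / n)


def mae(observed, predicted):
    n = len(observed)
    return sum(abs(observed[i] - predicted[i]) for i in range(n)) / n


def residual_sd(observed, predicted):
    n = len(observed)
    res = [observed[i] - predicted[i] for i in range(n)]
    m = sum(res) / n
    return math.sqrt(sum((r - m) ** 2 for r in res) / (n - 1))


def max_abs_residual(observed, predicted):
    return max(abs(o - p) for o, p in zip(observed, predicted))


def through_origin(x, z):
    """Slope of z = k*x through the origin and the R^2 of the points
    about that line, total sum of squares centred on mean(z)."""
    sxx = sum(v * v for v in x)
    k = sum(x[i] * z[i] for i in range(len(x))) / sxx
    zbar = sum(z) / len(z)
    ss_res = sum((z[i] - k * x[i]) ** 2 for i in range(len(x)))
    ss_tot = sum((v - zbar) ** 2 for v in z)
    return k, 1.0 - ss_res / ss_tot


def origin_stats(observed, predicted):
    k, ro2 = through_origin(observed, predicted)
    _, ro2_prime = through_origin(predicted, observed)
    return ro2, ro2_prime, k


def roy_rm2(r2, r2o, sqrt_variant=True):
    gap = abs(r2 - r2o)
    return r2 * (1.0 - (math.sqrt(gap) if sqrt_variant else gap))


def qf1(observed_ext, predicted_ext, observed_train):
    ytr_mean = sum(observed_train) / len(observed_train)
    num = sum((o - p) ** 2 for o, p in zip(observed_ext, predicted_ext))
    den = sum((o - ytr_mean) ** 2 for o in observed_ext)
    return 1.0 - num / den


def qf2(observed_ext, predicted_ext):
    ym = sum(observed_ext) / len(observed_ext)
    num = sum((o - p) ** 2 for o, p in zip(observed_ext, predicted_ext))
    den = sum((o - ym) ** 2 for o in observed_ext)
    return 1.0 - num / den


def qf3(observed_ext, predicted_ext, observed_train):
    n_ext, n_tr = len(observed_ext), len(observed_train)
    ytr_mean = sum(observed_train) / n_tr
    num = sum((o - p) ** 2 for o, p in zip(observed_ext, predicted_ext)) / n_ext
    den = sum((o - ytr_mean) ** 2 for o in observed_train) / n_tr
    return 1.0 - num / den


def ccc(observed, predicted):
    n = len(observed)
    ym = sum(observed) / n
    pm = sum(predicted) / n
    num = 2.0 * sum((observed[i] - ym) * (predicted[i] - pm) for i in range(n))
    den = (
        sum((o - ym) ** 2 for o in observed)
        + sum((p - pm) ** 2 for p in predicted)
        + n * (ym - pm) ** 2
    )
    return num / den


def kennard_stone_order(points, n_train):
    """Exhaustive greedy max-min selection on a list of coordinate
    tuples; returns the pick order as indices."""

    def dist(a, b):
        return math.sqrt(sum((ai - bi) ** 2 for ai, bi in zip(a, b)))

    n = len(points)
    best = (-1.0, None)
    for i in range(n):
        for j in range(i + 1, n):
            d = dist(points[i], points[j])
            if d > best[0]:
                best = (d, (i, j))
    selected = list(best[1])
    while len(selected) < n_train:
        cand_best = (-1.0, None)
        for i in range(n):
            if i in selected:
                continue
            min_d = min(dist(points[i], points[j]) for j in selected)
            if min_d > cand_best[0]:
                cand_best = (min_d, i)
        selected.append(cand_best[1])
    return selected
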