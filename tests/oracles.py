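"""Brute-force reference implementations used only as test oracles.

Each function re-derives a quantity by exhaustive enumeration, independent
of the library code paths it checks.
"""

from __future__ import annotations

import numpy as np


def auc_pairwise(p, y) -> float:
    p, y = np.asarray(p, float), np.asarray(y, float)
    cases, controls = p[y == 1], p[y == 0]
    total = wins = 0.0
    for a in cases:
        for b in controls:
            total += 1
            if a > b:
                wins += 1
            elif a == b:
                wins += 0.5
    return wins / total


def harrell_pairwise(lp, time, event) -> float:
    lp, time, event = (np.asarray(a, float) for a in (lp, time, event))
    n = len(lp)
    comparable = concordant = 0.0
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i] == 1:
                comparable += 1
                if lp[i] > lp[j]:
                    concordant += 1
                elif lp[i] == lp[j]:
                    concordant += 0.5
    return concordant / comparable


def youden_exhaustive(values, y) -> float:
    values, y = np.asarray(values, float), np.asarray(y, float)
    best_j, best_t = -np.inf, None
    for t in np.sort(np.unique(values)):
        pred = values >= t
        sens = np.sum(pred & (y == 1)) / np.sum(y == 1)
        spec = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        j = sens + spec - 1
        if j > best_j + 1e-9:  # first (lowest) threshold wins ties
            best_j, best_t = j, t
    return float(best_t)


def net_benefit_counts(p, y, p_t) -> float:
    p, y = np.asarray(p, float), np.asarray(y, float)
    n = len(y)
    tp = sum(1 for pi, yi in zip(p, y) if pi >= p_t and yi == 1)
    fp = sum(1 for pi, yi in zip(p, y) if pi >= p_t and yi == 0)
    return tp / n - (fp / n) * p_t / (1 - p_t)


def onset_exhaustive(pairs, code_days, rule="main"):
    """Enumerate every (i, j) measurement pair / singleton for the onset
    rules; pairs are (day, value). Same-day duplicates keep the lowest."""
    by_day = {}
    for day, value in pairs:
        by_day[day] = min(value, by_day.get(day, np.inf))
    days = sorted(by_day)
    values = [by_day[d] for d in days]
    candidates = []
    if rule == "single":
        for d, v in zip(days, values):
            if v < 60:
                candidates.append(d)
                break
    else:
        m = len(days)
        for i in range(m):
            for j in range(i + 1, m):
                if days[j] - days[i] >= 90 and all(v < 60 for v in values[i:j + 1]):
                    candidates.append(days[j])
    if code_days:
        candidates.append(min(code_days))
    return min(candidates) if candidates else None
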