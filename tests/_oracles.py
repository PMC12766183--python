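"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive (pure-python loops, exhaustive pair
enumeration, grid searches) and shares no code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def harrell_c_brute(time, event, risk):
    """Exhaustive O(n^2) concordance enumeration.

    Usable pairs: earlier time is an event, or tied times with exactly one
    event; tied risks score 0.5.
    """
    n = len(time)
    num = 0.0
    den = 0.0
    for i, j in combinations(range(n), 2):
        if time[i] == time[j]:
            if event[i] == event[j]:
                continue
            ev, other = (i, j) if event[i] else (j, i)
        elif time[i] < time[j]:
            if not event[i]:
                continue
            ev, other = i, j
        else:
            if not event[j]:
                continue
            ev, other = j, i
        den += 1
        if risk[ev] > risk[other]:
            num += 1
        elif risk[ev] == risk[other]:
            num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def auc_brute(labels, risk):
    """Binary AUC by pair counting (ties get half credit)."""
    pos = [r for r, y in zip(risk, labels) if y]
    neg = [r for r, y in zip(risk, labels) if not y]
    num = 0.0
    for rp in pos:
        for rn in neg:
            if rp > rn:
                num += 1.0
            elif rp == rn:
                num += 0.5
    return num / (len(pos) * len(neg))


def nri_brute(risk_base, risk_new, labels, cuts=(0.05, 0.10)):
    """Categorical NRI on known (uncensored) event labels."""
    def cat(r):
        c = 0
        for cut in cuts:
            if r > cut:
                c += 1
        return c
    up_e = down_e = n_e = 0
    up_ne = down_ne = n_ne = 0
    for rb, rn, y in zip(risk_base, risk_new, labels):
        cb, cn = cat(rb), cat(rn)
        if y:
            n_e += 1
            up_e += cn > cb
            down_e += cn < cb
        else:
            n_ne += 1
            up_ne += cn > cb
            down_ne += cn < cb
    nri_e = (up_e - down_e) / n_e
    nri_ne = (down_ne - up_ne) / n_ne
    return nri_e + nri_ne, nri_e, nri_ne


def idi_brute(risk_base, risk_new, labels):
    e = [i for i, y in enumerate(labels) if y]
    ne = [i for i, y in enumerate(labels) if not y]
    def slope(r):
        return (sum(r[i] for i in e) / len(e)) - (sum(r[i] for i in ne) / len(ne))
    return slope(risk_new) - slope(risk_base)


def reclassification_brute(risk_base, risk_new, labels, cuts=(0.05, 0.10)):
    """3x3 counts among events and non-events (uncensored)."""
    def cat(r):
        c = 0
        for cut in cuts:
            if r > cut:
                c += 1
        return c
    k = len(cuts) + 1
    tab_e = [[0] * k for _ in range(k)]
    tab_ne = [[0] * k for _ in range(k)]
    for rb, rn, y in zip(risk_base, risk_new, labels):
        tab = tab_e if y else tab_ne
        tab[cat(rb)][cat(rn)] += 1
    return np.array(tab_e, dtype=float), np.array(tab_ne, dtype=float)


def cox_partial_loglik_brute(X, time, event, beta):
    """Breslow partial log-likelihood by direct risk-set enumeration."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(time):
        X = X.T
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    eta = X @ beta
    ll = 0.0
    event_times = sorted({t for t, d in zip(time, event) if d})
    for tk in event_times:
        deaths = [i for i in range(len(time)) if time[i] == tk and event[i]]
        risk_set = [i for i in range(len(time)) if time[i] >= tk]
        s = sum(math.exp(eta[i]) for i in risk_set)
        for i in deaths:
            ll += eta[i]
        ll -= len(deaths) * math.log(s)
    return ll


def lasso_cox_1d_grid(x, time, event, lam, grid):
    """Argmin over a 1-D beta grid of -partial_loglik + lam * |beta|."""
    best_b, best_obj = None, np.inf
    for b in grid:
        obj = -cox_partial_loglik_brute(x, time, event, [b]) + lam * abs(b)
        if obj < best_obj:
            best_b, best_obj = b, obj
    return best_b
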