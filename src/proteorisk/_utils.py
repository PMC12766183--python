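"""Shared numeric helpers: deterministic sub-seeding and Kaplan-Meier."""

from __future__ import annotations

import numpy as np

__all__ = ["child_rng", "child_seed", "km_survival", "km_survival_at"]


def child_seed(master_seed: int, *tags: int | str) -> np.random.SeedSequence:
    """Derive a deterministic child seed sequence from a master seed and tags.

    String tags are mapped to integers so stage names can be used directly;
    the mapping is stable across runs and platforms.
    """
    ints = []
    for t in tags:
        if isinstance(t, str):
            # stable 64-bit FNV-1a of the utf-8 bytes
            h = 0xCBF29CE484222325
            for b in t.encode("utf-8"):
                h = ((h ^ b) * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
            ints.append(h)
        else:
            ints.append(int(t) & 0xFFFFFFFFFFFFFFFF)
    return np.random.SeedSequence(entropy=int(master_seed) & 0xFFFFFFFFFFFFFFFF, spawn_key=tuple(ints))


def child_rng(master_seed: int, *tags: int | str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, *tags))


def km_survival(time: np.ndarray, event: np.ndarray):
    """Kaplan-Meier estimate of the event-free probability.

    Returns ``(times, surv)`` where ``times`` are the distinct event times in
    increasing order and ``surv[k]`` is S(times[k]).  S(t) for arbitrary t is
    a right-continuous step function; see :func:`km_survival_at`.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if time.size == 0:
        return np.empty(0), np.empty(0)
    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    n = t.size
    # at-risk count just before each row; ties share the risk set
    uniq, first = np.unique(t, return_index=True)
    deaths = np.add.reduceat(d.astype(float), first)
    at_risk = n - first
    keep = deaths > 0
    factors = 1.0 - deaths[keep] / at_risk[keep]
    return uniq[keep], np.cumprod(factors)


def km_survival_at(times: np.ndarray, surv: np.ndarray, query) -> np.ndarray:
    """Evaluate a KM step function at query times (right-continuous)."""
    query = np.atleast_1d(np.asarray(query, dtype=float))
    if times.size == 0:
        return np.ones_like(query)
    idx = np.searchsorted(times, query, side="right") - 1
    out = np.ones_like(query)
    has = idx >= 0
    out[has] = surv[idx[has]]
    return out
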