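"""Independent oracles for the test suite.

Everything here is written as a literal, self-contained transcription of
the clinical rules and textbook definitions, deliberately sharing no
code with the package: brute-force pair counting for AUC, a
plain-prose truth table for the two-step algorithm and its LA-strain
variants, and a paired bootstrap for the AUC-difference standard error.
"""

from __future__ import annotations

import numpy as np

LASR_DEFAULT = 18.0


def tri(value, cutoff, op):
    """True/False/None criterion state."""
    if value is None:
        return None
    if op == "<":
        return value < cutoff
    if op == ">":
        return value > cutoff
    if op == ">=":
        return value >= cutoff
    raise ValueError(op)


# ---------------------------------------------------------------------------
# Rule oracles (echo passed as a plain dict of raw values)

def _e_prime_vote(e):
    sep = tri(e.get("septal_e_prime"), 7.0, "<")
    lat = tri(e.get("lateral_e_prime"), 10.0, "<")
    if sep is None and lat is None:
        return None
    if sep or lat:
        return True
    return False


def _step1_votes(e, with_lasr=False, lasr_cutoff=LASR_DEFAULT):
    votes = [
        _e_prime_vote(e),
        tri(e.get("e_over_e_prime_mean"), 14.0, ">"),
        tri(e.get("tr_peak_vel"), 2.8, ">"),
        tri(e.get("la_volume_index"), 34.0, ">"),
    ]
    if with_lasr:
        votes.append(tri(e.get("las_r"), lasr_cutoff, "<"))
    return votes


def oracle_step1(e, with_lasr=False, lasr_cutoff=LASR_DEFAULT):
    votes = _step1_votes(e, with_lasr, lasr_cutoff)
    if any(v is None for v in votes):
        return "not_assessable"
    frac = sum(votes) / len(votes)
    if frac < 0.5:
        return "normal"
    if frac == 0.5:
        return "indeterminate"
    return "dysfunction"


def _gate(e):
    """Returns a class string, or None when additional criteria decide."""
    ea = e.get("e_a_ratio")
    if ea is None:
        return "not_assessable"
    if ea >= 2.0:
        return "elevated"
    ev = e.get("mitral_e_vel")
    if ea <= 0.8 and ev is not None and ev <= 50.0:
        return "normal"
    return None

# the three conventional additional criteria, in order
_BASE3 = (
    ("e_over_e_prime_mean", 14.0, ">"),
    ("tr_peak_vel", 2.8, ">"),
    ("la_volume_index", 34.0, ">"),
)


def _majority(states):
    avail = [s for s in states if s is not None]
    if len(avail) <= 1:
        return "indeterminate"
    pos = sum(avail)
    if 2 * pos > len(avail):
        return "elevated"
    if 2 * pos < len(avail):
        return "normal"
    return "indeterminate"


def oracle_step2(e):
    g = _gate(e)
    if g is not None:
        return g
    return _majority([tri(e.get(k), c, op) for k, c, op in _BASE3])


def oracle_model1(e, lasr_cutoff=LASR_DEFAULT):
    g = _gate(e)
    if g is not None:
        return g
    crits = (
        ("e_over_e_prime_mean", 14.0, ">"),
        ("las_r", lasr_cutoff, "<"),
        ("la_volume_index", 34.0, ">"),
    )
    return _majority([tri(e.get(k), c, op) for k, c, op in crits])


def oracle_model2(e, lasr_cutoff=LASR_DEFAULT):
    g = _gate(e)
    if g is not None:
        return g
    states = [tri(e.get(k), c, op) for k, c, op in _BASE3]
    known = [s for s in states if s is not None]
    if states.count(None) == 1 and sorted(known) == [False, True]:
        las = tri(e.get("las_r"), lasr_cutoff, "<")
        if las is None:
            return "indeterminate"
        filled = known + [las]
        return "elevated" if sum(filled) >= 2 else "normal"
    return _majority(states)


def oracle_model3(e, lasr_cutoff=LASR_DEFAULT):
    g = _gate(e)
    if g is not None:
        return g
    crits = _BASE3 + (("las_r", lasr_cutoff, "<"),)
    states = [tri(e.get(k), c, op) for k, c, op in crits]
    avail = [s for s in states if s is not None]
    if len(avail) < 3:
        return "indeterminate"
    return "elevated" if sum(avail) >= 3 else "normal"


def oracle_step1_lasr(e, lasr_cutoff=LASR_DEFAULT):
    votes = _step1_votes(e, with_lasr=True, lasr_cutoff=lasr_cutoff)
    if any(v is None for v in votes):
        return "not_assessable"
    return "dysfunction" if sum(votes) >= 3 else "normal"


# ---------------------------------------------------------------------------
# Probe grid

#: canonical probe values: missing / below / at / above each cutoff.
PROBE_VALUES = {
    "e_a_ratio": (None, 0.7, 1.2, 2.0),
    "septal_e_prime": (None, 6.0, 7.0, 8.0),
    "lateral_e_prime": (None, 9.0, 10.0, 11.0),
    "e_over_e_prime_mean": (None, 13.0, 14.0, 15.0),
    "tr_peak_vel": (None, 2.7, 2.8, 3.0),
    "la_volume_index": (None, 30.0, 34.0, 40.0),
    "las_r": (None, 15.0, 18.0, 20.0),
}

#: transmitral E tied to the E/A probe so the low-E/A branch is reachable
E_FOR_EA = {None: None, 0.7: 45.0, 1.2: 80.0, 2.0: 120.0}


def probe_grid():
    """All 4^7 combinations of probe states, plus gate variants where
    E/A is low but E is above 50 cm/s or missing."""
    keys = list(PROBE_VALUES)
    combos = [{}]
    for k in keys:
        combos = [dict(c, **{k: v}) for c in combos for v in PROBE_VALUES[k]]
    for c in combos:
        c["mitral_e_vel"] = E_FOR_EA[c["e_a_ratio"]]
        yield c
    # low-E/A gate variants over the remaining 4^6 grid
    sub = [{}]
    for k in keys[1:]:
        sub = [dict(c, **{k: v}) for c in sub for v in PROBE_VALUES[k]]
    for e_val in (60.0, None):
        for c in sub:
            yield dict(c, e_a_ratio=0.7, mitral_e_vel=e_val)


# ---------------------------------------------------------------------------
# Statistical oracles

def auc_pair_counting(marker, truth):
    """O(n^2) Mann-Whitney pair statistic: 1 correct, 0.5 tie."""
    pos = [m for m, t in zip(marker, truth) if t]
    neg = [m for m, t in zip(marker, truth) if not t]
    total = 0.0
    for a in pos:
        for b in neg:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(pos) * len(neg))


def _auc_rank(x, y):
    # internal fast AUC for the bootstrap (rank formula, midranks)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    sx = x[order]
    i = 0
    while i < len(sx):
        j = i
        while j + 1 < len(sx) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    m = int(y.sum())
    n = len(y) - m
    return (ranks[y].sum() - m * (m + 1) / 2.0) / (m * n)


def bootstrap_se_auc_diff(a, b, truth, n_boot=2000, seed=0):
    """Paired bootstrap SE of AUC(a) - AUC(b).

    Cases and controls resampled separately, each subject keeping both
    markers (the pairing).
    """
    rng = np.random.default_rng(seed)
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    y = np.asarray(truth, bool)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    diffs = np.empty(n_boot)
    for k in range(n_boot):
        pi = rng.choice(pos_idx, size=len(pos_idx), replace=True)
        ni = rng.choice(neg_idx, size=len(neg_idx), replace=True)
        idx = np.concatenate([pi, ni])
        yy = np.concatenate([np.ones(len(pi), bool), np.zeros(len(ni), bool)])
        diffs[k] = _auc_rank(a[idx], yy) - _auc_rank(b[idx], yy)
    return float(np.std(diffs, ddof=1))
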