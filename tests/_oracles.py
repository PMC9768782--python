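"""Independent brute-force oracles used only by tests.

These deliberately avoid the package's implementations: staging scans every
observation pair and every candidate span without shortcuts, and AUROC
counts every positive-negative pair explicitly.
"""

from __future__ import annotations

import numpy as np


def brute_auroc(scores, labels) -> float:
    """Exhaustive O(n^2) pairwise concordance with 0.5 credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (pos.size * neg.size)


def brute_kdigo(creat_t, creat_v, urine_t=None, urine_v=None, weight=None):
    """Stage, onset and criterion by unoptimized full scans.

    Returns (stage, onset, criterion); onset None iff stage 0.
    """
    creat_t = np.asarray(creat_t, dtype=float)
    creat_v = np.asarray(creat_v, dtype=float)
    keep = creat_t <= 168.0
    creat_t, creat_v = creat_t[keep], creat_v[keep]
    baseline = creat_v[creat_t <= 24.0].min()

    events = []  # (time, stage, preference_rank, criterion)
    for j in range(creat_t.size):
        t, v = creat_t[j], creat_v[j]
        r = v / baseline
        if r >= 3.0:
            events.append((t, 3, 0, "creatinine_ratio"))
        elif r >= 2.0:
            events.append((t, 2, 0, "creatinine_ratio"))
        elif r >= 1.5:
            events.append((t, 1, 0, "creatinine_ratio"))
        if v >= 4.0:
            events.append((t, 3, 1, "creatinine_absolute"))
        for i in range(j + 1):
            if creat_t[j] - creat_t[i] <= 48.0 and v - creat_v[i] >= 0.3:
                events.append((t, 1, 2, "creatinine_delta48"))
                break

    arms = []
    if events:
        stage = max(e[1] for e in events)
        t0, _, rank, crit = min((e for e in events if e[1] == stage),
                                key=lambda e: (e[0], e[2]))
        arms.append((stage, t0, crit, 0))
    else:
        arms.append((0, None, None, 0))

    if urine_t is not None and len(urine_t):
        urine_t = np.asarray(urine_t, dtype=float)
        urine_v = np.asarray(urine_v, dtype=float)
        keep = urine_t <= 168.0
        urine_t, urine_v = urine_t[keep], urine_v[keep]
        if urine_t.size:
            rates = urine_v / weight
            starts = np.concatenate([[0.0], urine_t[:-1]])
            best = None
            for stage, thr, dur, crit in ((3, 1e-9, 12.0, "anuria"),
                                          (3, 0.3, 24.0, "urine_rate"),
                                          (2, 0.5, 12.0, "urine_rate"),
                                          (1, 0.5, 6.0, "urine_rate")):
                onset = None
                for i in range(urine_t.size):
                    for j in range(i, urine_t.size):
                        run = range(i, j + 1)
                        if any(urine_t[k] - starts[k] > 2.0 for k in run):
                            continue
                        if any(rates[k] >= thr for k in run):
                            continue
                        if urine_t[j] - starts[i] >= dur:
                            q = starts[i] + dur
                            onset = q if onset is None else min(onset, q)
                if onset is not None and (best is None or stage > best[0]
                                          or (stage == best[0] and onset < best[1])):
                    best = (stage, onset, crit)
            if best is not None:
                arms.append((*best, 1))

    stage = max(a[0] for a in arms)
    if stage == 0:
        return 0, None, None
    _, onset, crit, _ = min((a for a in arms if a[0] == stage),
                            key=lambda a: (a[1], a[3]))
    return stage, onset, crit


def window_labels_oracle(gap_h, before_hospital_discharge):
    """Hand application of the readmission windowing rules to one gap."""
    if gap_h is None:
        return {w: 0 for w in ("24h", "48h", "72h", "24_72h", "7d", "30d",
                               "bounce_back")}
    return {
        "24h": int(gap_h <= 24), "48h": int(gap_h <= 48),
        "72h": int(gap_h <= 72), "24_72h": int(24 < gap_h <= 72),
        "7d": int(gap_h <= 168), "30d": int(gap_h <= 720),
        "bounce_back": int(before_hospital_discharge),
    }


def random_trajectory(rng):
    """A random creatinine/urine pair exercising thresholds and borders."""
    n_c = rng.integers(3, 16)
    creat_t = np.sort(rng.uniform(0.5, 180.0, n_c))
    creat_t[0] = rng.uniform(0.5, 23.0)  # keep a baseline computable
    creat_t = np.sort(creat_t)
    base = rng.uniform(0.5, 1.4)
    creat_v = base * rng.uniform(0.7, rng.choice([1.2, 2.1, 3.3, 4.6]), n_c)
    with_urine = rng.random() < 0.8
    if not with_urine:
        return creat_t, np.round(creat_v, 3), None, None, None
    weight = rng.uniform(55.0, 115.0)
    n_u = rng.integers(5, 60)
    gaps = rng.uniform(0.3, rng.choice([1.5, 2.6]), n_u)
    urine_t = np.cumsum(gaps) + rng.uniform(0, 2)
    rate = rng.choice([0.0, 0.1, 0.25, 0.35, 0.45, 0.55, 1.0], n_u,
                      p=[0.05, 0.15, 0.15, 0.2, 0.15, 0.15, 0.15])
    rate = np.where(rate == 0.0, 0.0, rate + rng.uniform(0, 0.04, n_u))
    return (creat_t, np.round(creat_v, 3), np.round(urine_t, 3),
            np.round(rate * weight, 3), weight)
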