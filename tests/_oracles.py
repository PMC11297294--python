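"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (exhaustive window search, per-sample
tallies, Monte-Carlo simulation) and shares no code with the package paths
it validates.
"""

from __future__ import annotations

import numpy as np


def idt_oracle(t, x, y, conf, thr, min_dur, min_conf):
    """Exhaustive-window dispersion-threshold fixation search.

    Greedy left-to-right over each maximal confident run: at each start,
    the longest window whose dispersion (x-range + y-range) stays within
    the threshold is a fixation iff its span reaches the minimum duration.
    Returns (start_idx, end_idx) inclusive pairs.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    good = np.asarray(conf, float) >= min_conf
    events = []
    # maximal confident runs
    runs = []
    s = None
    for i in range(len(t) + 1):
        if i < len(t) and good[i]:
            if s is None:
                s = i
        elif s is not None:
            runs.append((s, i - 1))
            s = None
    for lo, hi in runs:
        s = lo
        while s <= hi:
            best = None
            for e in range(s, hi + 1):
                xs = x[s:e + 1]
                ys = y[s:e + 1]
                if (xs.max() - xs.min()) + (ys.max() - ys.min()) > thr:
                    break
                best = e
            if best is not None and t[best] - t[s] >= min_dur:
                events.append((s, best))
                s = best + 1
            else:
                s += 1
    return events


def blink_oracle(t, conf, thr, min_dur, max_dur, merge_gap):
    """Brute-force low-confidence run scan returning (onset, end) pairs."""
    t = np.asarray(t, float)
    low = np.asarray(conf, float) < thr
    n = len(t)
    period = float(np.median(np.diff(t))) if n > 1 else 0.0
    raw = []
    i = 0
    while i < n:
        if low[i]:
            j = i
            while j + 1 < n and low[j + 1]:
                j += 1
            end = t[j + 1] if j + 1 < n else t[j] + period
            raw.append([t[i], end])
            i = j + 1
        else:
            i += 1
    merged = []
    for onset, end in raw:
        if merged and onset - merged[-1][1] < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([onset, end])
    return [(a, b) for a, b in merged if min_dur <= b - a <= max_dur]


def tally_attention_oracle(samples, tracks, hierarchy, period_cap):
    """Per-sample gaze-time tally with an independent zero-order-hold lookup.

    Returns ``{roi_id: gaze_time_ms}`` including ancestors and "elsewhere".
    """
    obs = {}
    for rec in tracks.itertuples(index=False):
        obs.setdefault(rec.roi_id, []).append(
            (rec.t_ms, rec.visible, (rec.x_min, rec.y_min, rec.x_max, rec.y_max)))
    for v in obs.values():
        v.sort(key=lambda r: r[0])

    def box_at(rid, t):
        cur = None
        for tt, vis, box in obs[rid]:
            if tt <= t:
                cur = (vis, box)
            else:
                break
        if cur is None or not cur[0]:
            return None
        return cur[1]

    t = samples["t_ms"].to_numpy(float)
    x = samples["x"].to_numpy(float)
    y = samples["y"].to_numpy(float)
    dts = np.diff(t)
    med = float(np.median(dts)) if len(dts) else 0.0
    dts = np.append(np.minimum(dts, period_cap if period_cap else 2 * med), med)

    gaze = {rid: 0.0 for rid in hierarchy.roi_ids}
    gaze["elsewhere"] = 0.0
    for i in range(len(t)):
        candidates = []
        for rid in obs:
            b = box_at(rid, t[i])
            if b and b[0] <= x[i] < b[2] and b[1] <= y[i] < b[3]:
                area = (b[2] - b[0]) * (b[3] - b[1])
                candidates.append((area, rid))
        if not candidates:
            gaze["elsewhere"] += dts[i]
            continue
        candidates.sort()
        rid = candidates[0][1]
        gaze[rid] += dts[i]
        for anc in hierarchy.ancestors(rid):
            gaze[anc] += dts[i]
    return gaze


def permutation_t_pvalue(g1, g2, n_perm, seed):
    """Two-sided permutation p-value for the difference of means."""
    rng = np.random.default_rng(seed)
    g1 = np.asarray(g1, float)
    g2 = np.asarray(g2, float)
    pooled = np.concatenate([g1, g2])
    obs = abs(g1.mean() - g2.mean())
    n1 = len(g1)
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[:n1].mean() - pooled[n1:].mean()) >= obs - 1e-12:
            hits += 1
    return hits / n_perm


def mc_power_oracle(d, n1, n2, alpha, n_rep, seed):
    """Monte-Carlo power of the two-sided pooled t-test at effect size d."""
    from scipy import stats as sps
    rng = np.random.default_rng(seed)
    g1 = rng.normal(d, 1.0, size=(n_rep, n1))
    g2 = rng.normal(0.0, 1.0, size=(n_rep, n2))
    m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
    v1, v2 = g1.var(axis=1, ddof=1), g2.var(axis=1, ddof=1)
    dof = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * v1 + (n2 - 1) * v2) / dof)
    tstat = (m1 - m2) / (sp * np.sqrt(1 / n1 + 1 / n2))
    tcrit = sps.t.ppf(1 - alpha / 2, dof)
    return float(np.mean(np.abs(tstat) > tcrit))
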