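"""Independent brute-force reference implementations used as test oracles.

Deliberately written as plain scalar loops, separate from the package's
vectorized code paths.
"""

import math


def ref_beam_gain(tmi, tma, beamwidth):
    d = beamwidth / 2.0
    x = (tmi / d) ** 2
    y = (tma / d) ** 2
    return -6.0206 * (x + y - 0.18 * x * y)


def ref_detect(ping, params):
    """Exhaustive single-target detector: every sample checked as a candidate
    peak, every criterion evaluated with scalar arithmetic."""
    ts = [float(v) for v in ping.ts_uncomp_db]
    r = [float(v) for v in ping.range_grid_m]
    ami = [float(v) for v in ping.angle_minor_deg]
    ama = [float(v) for v in ping.angle_major_deg]
    exc = list(ping.excluded) if ping.excluded is not None else [False] * len(ts)
    n = len(ts)
    plm = params.sound_speed_m_s * params.pulse_duration_ms * 1e-3 / 2.0
    floor = params.ts_threshold_db - params.max_beam_comp_db

    cands = []
    for i in range(n):
        if exc[i] or ts[i] < floor:
            continue
        left = ts[i - 1] if i > 0 else -math.inf
        right = ts[i + 1] if i < n - 1 else -math.inf
        if not (ts[i] > left and ts[i] >= right):
            continue
        level = ts[i] - params.pldl_db
        j = i - 1
        while j >= 0 and not exc[j] and ts[j] >= level:
            j -= 1
        if j < 0 or exc[j]:
            continue
        rl = r[j] + (r[j + 1] - r[j]) * (ts[j] - level) / (ts[j] - ts[j + 1])
        k = i + 1
        while k < n and not exc[k] and ts[k] >= level:
            k += 1
        if k >= n or exc[k]:
            continue
        rr = r[k - 1] + (r[k] - r[k - 1]) * (ts[k - 1] - level) / (ts[k - 1] - ts[k])
        norm = (rr - rl) / plm
        if norm < params.min_norm_pulse_len or norm > params.max_norm_pulse_len:
            continue
        seg_mi = ami[j + 1 : k]
        seg_ma = ama[j + 1 : k]
        m_mi = sum(seg_mi) / len(seg_mi)
        m_ma = sum(seg_ma) / len(seg_ma)
        sd_mi = math.sqrt(sum((a - m_mi) ** 2 for a in seg_mi) / len(seg_mi))
        sd_ma = math.sqrt(sum((a - m_ma) ** 2 for a in seg_ma) / len(seg_ma))
        if sd_mi > params.max_sd_minor_deg or sd_ma > params.max_sd_major_deg:
            continue
        if abs(m_mi) >= params.beamwidth_deg or abs(m_ma) >= params.beamwidth_deg:
            continue
        comp = -ref_beam_gain(m_mi, m_ma, params.beamwidth_deg)
        if comp > params.max_beam_comp_db:
            continue
        if ts[i] + comp < params.ts_threshold_db:
            continue
        cands.append({"peak": i, "lo": j + 1, "hi": k - 1, "comp": comp, "ts_comp": ts[i] + comp,
                      "norm": norm})

    out = []
    for a in cands:
        if not any(
            b is not a and not (a["hi"] < b["lo"] or a["lo"] > b["hi"]) for b in cands
        ):
            out.append(a)
    return out


def ref_tracks(targets, params):
    """Greedy gated association, scalar reimplementation. Returns a list of
    member-index tuples partitioning the input."""
    order = sorted(
        range(len(targets)),
        key=lambda i: (
            targets[i].survey_id,
            targets[i].transect_id,
            targets[i].ping_index,
            targets[i].range_m,
        ),
    )
    open_tr, done = [], []
    cur = None
    for i in order:
        t = targets[i]
        key = (t.survey_id, t.transect_id)
        if key != cur:
            done += open_tr
            open_tr = []
            cur = key
        nxt = []
        for tr in open_tr:
            if t.ping_index - targets[tr[-1]].ping_index > params.max_ping_gap:
                done.append(tr)
            else:
                nxt.append(tr)
        open_tr = nxt
        best, bd = None, None
        for tr in open_tr:
            last = targets[tr[-1]]
            if last.ping_index == t.ping_index:
                continue
            d = abs(t.range_m - last.range_m)
            if d <= params.range_gate_m and (best is None or d < bd):
                best, bd = tr, d
        if best is None:
            best = []
            open_tr.append(best)
        best.append(i)
    done += open_tr
    return [tuple(tr) for tr in done]


def ref_ols(x, y):
    """Closed-form simple linear regression with slope t-test."""
    from scipy.stats import t as tdist

    n = len(x)
    xb = sum(x) / n
    yb = sum(y) / n
    sxx = sum((xi - xb) ** 2 for xi in x)
    sxy = sum((xi - xb) * (yi - yb) for xi, yi in zip(x, y))
    slope = sxy / sxx
    intercept = yb - slope * xb
    resid = [yi - intercept - slope * xi for xi, yi in zip(x, y)]
    sse = sum(e**2 for e in resid)
    sst = sum((yi - yb) ** 2 for yi in y)
    r2 = 1.0 - sse / sst if sst > 0 else 0.0
    se = math.sqrt(sse / (n - 2) / sxx) if n > 2 else float("nan")
    tstat = slope / se if se > 0 else float("inf")
    p = 2.0 * tdist.sf(abs(tstat), n - 2)
    return slope, intercept, r2, se, p
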