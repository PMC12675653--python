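"""Independent naive/brute-force oracles used by unit and acceptance tests.

These deliberately use explicit Python loops and textbook formulas, never the
package's own vectorized code paths.
"""

import math


def _valid_points(rec):
    pts = []
    for i in range(rec.n):
        if rec.valid[i] and math.isfinite(rec.x[i]) and math.isfinite(rec.y[i]):
            pts.append((rec.x[i], rec.y[i]))
    return pts


def naive_accuracy(rec, target):
    pts = _valid_points(rec)
    return sum(math.hypot(x - target[0], y - target[1]) for x, y in pts) / len(pts)


def naive_std(rec):
    pts = _valid_points(rec)
    mx = sum(p[0] for p in pts) / len(pts)
    my = sum(p[1] for p in pts) / len(pts)
    ss = sum((x - mx) ** 2 + (y - my) ** 2 for x, y in pts)
    return math.sqrt(ss / len(pts))


def naive_rms_s2s(rec):
    total, pairs = 0.0, 0
    for i in range(rec.n - 1):
        a_ok = rec.valid[i] and math.isfinite(rec.x[i]) and math.isfinite(rec.y[i])
        b_ok = rec.valid[i + 1] and math.isfinite(rec.x[i + 1]) and math.isfinite(rec.y[i + 1])
        if a_ok and b_ok:
            total += (rec.x[i + 1] - rec.x[i]) ** 2 + (rec.y[i + 1] - rec.y[i]) ** 2
            pairs += 1
    return math.sqrt(total / pairs)


def naive_data_loss(rec):
    bad = 0
    for i in range(rec.n):
        if not (rec.valid[i] and math.isfinite(rec.x[i]) and math.isfinite(rec.y[i])):
            bad += 1
    return 100.0 * bad / rec.n


def naive_shift(pairs):
    shifts = []
    for bright, dark in pairs:
        bp = _valid_points(bright)
        dp = _valid_points(dark)
        bx = sum(p[0] for p in bp) / len(bp)
        by = sum(p[1] for p in bp) / len(bp)
        dx = sum(p[0] for p in dp) / len(dp)
        dy = sum(p[1] for p in dp) / len(dp)
        shifts.append(math.hypot(bx - dx, by - dy))
    return sum(shifts) / len(shifts)


def naive_sd_removals(rec, k=3.0):
    """Indices the single-pass SD filter should remove, by brute force."""
    pts = [(i, rec.x[i], rec.y[i]) for i in range(rec.n)
           if rec.valid[i] and math.isfinite(rec.x[i]) and math.isfinite(rec.y[i])]
    n = len(pts)
    mx = sum(p[1] for p in pts) / n
    my = sum(p[2] for p in pts) / n
    sx = math.sqrt(sum((p[1] - mx) ** 2 for p in pts) / n)
    sy = math.sqrt(sum((p[2] - my) ** 2 for p in pts) / n)
    removed = set()
    for i, x, y in pts:
        if (sx > 0 and abs(x - mx) > k * sx) or (sy > 0 and abs(y - my) > k * sy):
            removed.add(i)
    return removed


def distort_point_oracle(xn, yn, k1=0.0, k2=0.0, p1=0.0, p2=0.0, k3=0.0):
    """Closed-form Brown-Conrady forward model, written out independently."""
    r2 = xn * xn + yn * yn
    rad = 1 + k1 * r2 + k2 * r2 ** 2 + k3 * r2 ** 3
    xd = xn * rad + 2 * p1 * xn * yn + p2 * (r2 + 2 * xn * xn)
    yd = yn * rad + p1 * (r2 + 2 * yn * yn) + 2 * p2 * xn * yn
    return xd, yd
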