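"""Independent brute-force oracles the implementation is checked against.

Each oracle is written as directly as possible from the defining rule —
scalar loops, explicit state machines, two-pass formulas — and shares no
code with the package.
"""

import numpy as np


def zncc(a: np.ndarray, b: np.ndarray) -> float:
    """Zero-normalized cross-correlation of two equal-shape patches."""
    a = a.astype(float).ravel()
    b = b.astype(float).ravel()
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return float("-inf")
    return float((a * b).sum() / denom)


def brute_force_register(stack, template_region, search_radius, reference_frame=0):
    """Exhaustive-search ZNCC registration: every displacement in the window.

    Returns (shifts, scores) with the same tie-break as the contract:
    highest score, then smallest displacement magnitude, then (dy, dx)
    row-major order.
    """
    stack = np.asarray(stack)
    n, h, w = stack.shape
    x, y, tw, th = template_region
    template = stack[reference_frame, y:y + th, x:x + tw]
    shifts = np.zeros((n, 2), dtype=int)
    scores = np.ones(n, dtype=float)
    for t in range(n):
        if t == reference_frame:
            continue
        best = None
        for dy in range(-search_radius, search_radius + 1):
            for dx in range(-search_radius, search_radius + 1):
                yy, xx = y + dy, x + dx
                if yy < 0 or xx < 0 or yy + th > h or xx + tw > w:
                    continue
                s = zncc(stack[t, yy:yy + th, xx:xx + tw], template)
                key = (-s, dy * dy + dx * dx, dy, dx)
                if best is None or key < best[0]:
                    best = (key, dy, dx, s)
        shifts[t] = (best[1], best[2])
        scores[t] = min(max(best[3], -1.0), 1.0)
    return shifts, scores


def hysteresis_fsm(values, threshold):
    """Direct finite-state simulation of the turning-point rule.

    States: SEEK (direction unknown), UP (awaiting a peak), DOWN (awaiting
    a valley). Returns [(kind, index), ...]. The initial extremum and the
    first/last samples are never emitted; a pending interior candidate at
    stream end is. The unconfirmable final sample never takes over a
    pending candidate (a truncated excursion commits at its best interior
    sample).
    """
    x = [float(v) for v in values]
    n = len(x)
    out = []
    state = "SEEK"
    hi = lo = 0  # candidate indices
    for i in range(1, n):
        if state == "SEEK":
            if x[i] > x[hi]:
                hi = i
            if x[i] < x[lo]:
                lo = i
            if x[hi] - x[i] >= threshold:
                state, lo = "DOWN", i
            elif x[i] - x[lo] >= threshold:
                state, hi = "UP", i
        elif state == "UP":
            if x[i] > x[hi] and i != n - 1:
                hi = i
            elif x[hi] - x[i] >= threshold:
                if hi not in (0, n - 1):
                    out.append(("peak", hi))
                state, lo = "DOWN", i
        elif state == "DOWN":
            if x[i] < x[lo] and i != n - 1:
                lo = i
            elif x[i] - x[lo] >= threshold:
                if lo not in (0, n - 1):
                    out.append(("valley", lo))
                state, hi = "UP", i
    if state == "UP" and hi not in (0, n - 1):
        out.append(("peak", hi))
    elif state == "DOWN" and lo not in (0, n - 1):
        out.append(("valley", lo))
    return out


def bh_step_up(p_values):
    """Benjamini-Hochberg adjusted p-values from the step-up definition:
    adj(i) = min over j with p(j) >= p(i) of m * p(j) / rank(j), capped at 1.
    """
    p = list(map(float, p_values))
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj_sorted = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        running = min(running, m * p[order[pos]] / (pos + 1))
        adj_sorted[pos] = running
    adj = [0.0] * m
    for pos, i in enumerate(order):
        adj[i] = adj_sorted[pos]
    return np.array(adj)


def point_in_polygon(px, py, vertices):
    """Scalar even-odd (ray crossing) point-in-polygon test."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        if (y1 > py) != (y2 > py):
            x_int = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < x_int:
                inside = not inside
    return inside


def pearson_two_pass(a, b):
    """Textbook two-pass covariance formula for the Pearson coefficient."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    am, bm = a.mean(), b.mean()
    cov = ((a - am) * (b - bm)).sum()
    return cov / np.sqrt(((a - am) ** 2).sum() * ((b - bm) ** 2).sum())
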