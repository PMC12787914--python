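"""Shared test utilities: exact circle samplers and brute-force oracles."""

import numpy as np


def circle_points(n, r=0.25, cx=0.0, cy=0.0, arc=360.0, phase=0.0):
    th = np.radians(np.linspace(phase, phase + arc, n, endpoint=False))
    return np.column_stack((cx + r * np.cos(th), cy + r * np.sin(th)))


def grid_search_circle(pts, guess, span=0.01, levels=4):
    """Brute-force least-squares circle: nested grid over the centre,
    radius = mean distance (the exact conditional optimum)."""
    cx, cy = guess
    for level in range(levels):
        step = span / 10**level
        xs = cx + np.linspace(-step * 5, step * 5, 11)
        ys = cy + np.linspace(-step * 5, step * 5, 11)
        best = (np.inf, cx, cy)
        for x in xs:
            for y in ys:
                d = np.hypot(pts[:, 0] - x, pts[:, 1] - y)
                r = d.mean()
                sse = np.sum((d - r) ** 2)
                if sse < best[0]:
                    best = (sse, x, y)
        _, cx, cy = best
    d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return (cx, cy), d.mean()
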