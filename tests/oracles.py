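"""Independent oracles used by the test suite.

These deliberately share no code with the package: the broken-stick oracle is
an exhaustive minimax search over all interior point pairs, and the drift
oracle is a straight-line transcription of the five filter rules.
"""

from __future__ import annotations

import numpy as np

from divekit.abstraction import DiveSegment, DiveSummary


def exhaustive_broken_stick(depth: np.ndarray) -> tuple[tuple[int, int], float]:
    """Best (i, j) interior pair minimizing the max vertical deviation of the
    3-segment piecewise-linear reconstruction; exhaustive over all pairs."""
    depth = np.asarray(depth, dtype=float)
    n = len(depth)
    t = np.arange(n, dtype=float)

    # A[i] = max deviation on [0, i] from the chord (0,d0)-(i,di)
    A = np.zeros(n)
    B = np.zeros(n)
    for i in range(1, n):
        line = depth[0] + (depth[i] - depth[0]) * t[: i + 1] / i
        A[i] = np.max(np.abs(depth[: i + 1] - line))
        j = n - 1 - i
        span = t[j:] - j
        line = depth[j] + (depth[-1] - depth[j]) * span / (n - 1 - j)
        B[j] = np.max(np.abs(depth[j:] - line))

    best_pair, best_val = None, np.inf
    for i in range(1, n - 2):
        js = np.arange(i + 1, n - 1)
        # middle-span deviations for all j at once
        rel_t = t[None, :] - i                           # (1, n)
        span_len = (js - i).astype(float)[:, None]       # (nj, 1)
        line = depth[i] + (depth[js][:, None] - depth[i]) * rel_t / span_len
        dev = np.abs(depth[None, :] - line)
        mask = (t[None, :] >= i) & (t[None, :] <= js[:, None])
        mid = np.where(mask, dev, 0.0).max(axis=1)
        total = np.maximum(np.maximum(A[i], mid), B[js])
        k = int(np.argmin(total))
        if total[k] < best_val:
            best_val = float(total[k])
            best_pair = (i, int(js[k]))
    return best_pair, best_val


def drift_filter_oracle(dive: DiveSummary, effort_max: float = 4.0,
                        speed_min: float = -0.3, speed_max: float = 0.6,
                        min_fraction: float = 0.40, null_tol: float = 1e-6):
    """Straight-line re-implementation of the five drift-filter rules.

    Returns the drift rate (duration-weighted over surviving segments) or
    None.
    """
    if len(dive.segments) < 3:
        return None
    segs = dive.segments[1:-1]                                     # rule 1
    segs = [s for s in segs if s.prca_fraction <= 0.0]             # rule 2
    segs = [s for s in segs if s.effort_rate <= effort_max]        # rule 3
    keep = []
    for s in segs:                                                 # rule 4
        r = (s.depth_start - s.depth_end) / (s.t_end - s.t_start)
        if r < speed_min or r > speed_max or abs(r) < null_tol:
            continue
        keep.append(s)
    keep = [s for s in keep                                        # rule 5
            if (s.t_end - s.t_start) >= min_fraction * dive.duration]
    if not keep:
        return None
    w = sum(s.t_end - s.t_start for s in keep)
    return sum(s.vertical_rate * (s.t_end - s.t_start) for s in keep) / w


def random_trapezoid(rng: np.random.Generator, n: int = 200) -> np.ndarray:
    """Noise-free random 3-segment dive profile on integer samples: random
    corner positions, depths and a possibly sloped bottom."""
    while True:
        b1 = int(rng.integers(5, n // 2 - 5))
        b2 = int(rng.integers(n // 2 + 5, n - 5))
        d1 = rng.uniform(60, 500)
        d2 = d1 + rng.uniform(-0.25, 0.25) * (b2 - b1)
        if d2 > 30:
            break
    t = np.arange(n, dtype=float)
    return np.interp(t, [0, b1, b2, n - 1], [0.0, d1, d2, 0.0])


def random_summary(rng: np.random.Generator, n_segments: int | None = None) -> DiveSummary:
    """Random abstracted dive with adversarial segment properties spanning
    every filter boundary."""
    k = int(n_segments or rng.integers(3, 6))
    edges = np.sort(rng.choice(np.arange(1, 900), size=k - 1, replace=False))
    edges = np.concatenate([[0], edges, [900 + rng.integers(1, 100)]]).astype(float)
    depths = np.concatenate([[rng.uniform(0, 4)],
                             rng.uniform(0, 600, k - 1),
                             [rng.uniform(0, 4)]])
    segs = []
    for i in range(k):
        dur = edges[i + 1] - edges[i]
        rate = (depths[i] - depths[i + 1]) / dur
        # sprinkle exact boundary values to exercise tie handling
        u = rng.random()
        if u < 0.08:
            rate = float(rng.choice([-0.3, 0.6, 0.0, -0.3 - 1e-9, 0.6 + 1e-9]))
            depths[i + 1] = depths[i] - rate * dur
        effort_rate = float(rng.choice([rng.uniform(0, 4), rng.uniform(4, 9), 4.0]))
        prca = float(rng.choice([0.0, rng.uniform(0.0, 0.5)]))
        segs.append(DiveSegment(
            segment_idx=i, t_start=float(edges[i]), t_end=float(edges[i + 1]),
            depth_start=float(depths[i]), depth_end=float(depths[i + 1]),
            vertical_rate=float((depths[i] - depths[i + 1]) / dur),
            effort_sum=effort_rate * dur, effort_rate=effort_rate,
            prca_fraction=prca, role="bottom"))
    segs[0].role, segs[-1].role = "descent", "ascent"
    return DiveSummary(dive_id="r", individual_id="r", day=0.0,
                       max_depth=float(depths.max()), duration=float(edges[-1]),
                       surface_duration=60.0, segments=segs)
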