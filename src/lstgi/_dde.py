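"""Internal machinery for delay-differential integration by the method of steps.

The tumor models have right-hand sides that are discontinuous at every
multiple of the cell lifespan T (propagated from the t = 0 history junction),
at dose times, and at those points shifted by the apoptosis lifespan T_A.
The integrator therefore works on a mesh whose nodes include the closure of
{0} and the dose times under addition of the active delays, and every lagged
signal is stored with duplicated abscissae at the jumps so that left- and
right-limits can be looked up exactly.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right

__all__ = ["JumpSignal", "HermiteDense", "build_mesh"]

_SNAP = 1e-9  # relative snapping tolerance for jump-node lookups


class JumpSignal:
    """Piecewise-linear signal in t with jump discontinuities.

    Jumps are represented by appending the same abscissa twice: first with
    the left-limit value, then with the right-limit value.  Queries left of
    the first node return ``history_value`` (the constant pre-experiment
    segment).
    """

    __slots__ = ("ts", "vs", "history_value")

    def __init__(self, history_value: float, t0: float = 0.0):
        self.history_value = float(history_value)
        self.ts: list[float] = [float(t0)]
        self.vs: list[float] = [float(history_value)]

    def append(self, t: float, v: float) -> None:
        self.ts.append(float(t))
        self.vs.append(float(v))

    def _snap(self, t: float) -> float:
        ts = self.ts
        i = bisect_left(ts, t)
        tol = _SNAP * max(1.0, abs(t))
        if i < len(ts) and abs(ts[i] - t) <= tol:
            return ts[i]
        if i > 0 and abs(ts[i - 1] - t) <= tol:
            return ts[i - 1]
        return t

    def left(self, t: float) -> float:
        """Left-continuous lookup (value of the segment ending at t)."""
        t = self._snap(t)
        ts = self.ts
        if t <= ts[0]:
            return self.history_value
        i = bisect_left(ts, t)
        if i < len(ts) and ts[i] == t:
            return self.vs[i]  # first (left-limit) entry at a duplicated node
        return self._interp(i - 1, t)

    def right(self, t: float) -> float:
        """Right-continuous lookup (value of the segment starting at t)."""
        t = self._snap(t)
        ts = self.ts
        if t < ts[0]:
            return self.history_value
        i = bisect_right(ts, t)
        if i > 0 and ts[i - 1] == t:
            return self.vs[i - 1]  # last (right-limit) entry at the node
        return self._interp(i - 1, t)

    def _interp(self, i: int, t: float) -> float:
        ts, vs = self.ts, self.vs
        if i >= len(ts) - 1:
            return vs[-1]
        t0, t1 = ts[i], ts[i + 1]
        if t1 == t0:
            return vs[i + 1]
        u = (t - t0) / (t1 - t0)
        return vs[i] * (1.0 - u) + vs[i + 1] * u


class HermiteDense:
    """Dense cubic-Hermite output accumulated step by step.

    Each accepted step stores (t0, t1, y0, y1, d0, d1) per state component,
    giving O(h^4)-accurate off-grid evaluation consistent with RK4.
    """

    __slots__ = ("t0s", "t1s", "y0s", "y1s", "d0s", "d1s")

    def __init__(self):
        self.t0s: list[float] = []
        self.t1s: list[float] = []
        self.y0s: list[tuple] = []
        self.y1s: list[tuple] = []
        self.d0s: list[tuple] = []
        self.d1s: list[tuple] = []

    def add_step(self, t0, t1, y0, y1, d0, d1) -> None:
        self.t0s.append(t0)
        self.t1s.append(t1)
        self.y0s.append(tuple(y0))
        self.y1s.append(tuple(y1))
        self.d0s.append(tuple(d0))
        self.d1s.append(tuple(d1))

    def __call__(self, t: float) -> tuple:
        t0s = self.t0s
        if not t0s:
            raise ValueError("empty dense output")
        i = bisect_right(t0s, t) - 1
        if i < 0:
            i = 0
        h = self.t1s[i] - t0s[i]
        u = (t - t0s[i]) / h
        u = min(max(u, 0.0), 1.0)
        h00 = (1 + 2 * u) * (1 - u) ** 2
        h10 = u * (1 - u) ** 2
        h01 = u * u * (3 - 2 * u)
        h11 = u * u * (u - 1)
        y0, y1, d0, d1 = self.y0s[i], self.y1s[i], self.d0s[i], self.d1s[i]
        return tuple(
            h00 * a + h * h10 * da + h01 * b + h * h11 * db
            for a, b, da, db in zip(y0, y1, d0, d1)
        )


def build_mesh(
    t_last: float,
    delays: tuple[float, ...],
    event_times: tuple[float, ...] = (),
    pps: int = 200,
    max_nodes: int = 400_000,
) -> list[float]:
    """Integration mesh on [0, t_last].

    Nodes include the closure of {0} plus ``event_times`` (dose times) under
    addition of the positive ``delays``, so that every lag lookup from a mesh
    node lands on a mesh node of an earlier interval; between breakpoints the
    mesh is refined so that no step exceeds min(delays)/pps.
    """
    if t_last <= 0:
        raise ValueError(f"t_last must be positive, got {t_last}")
    delays = tuple(d for d in delays if d > 0)
    seeds = {0.0}
    seeds.update(float(t) for t in event_times if 0.0 < t < t_last)
    points: set[float] = set()
    frontier = list(seeds)
    while frontier:
        t = frontier.pop()
        key = round(t, 10)
        if key in points or t > t_last:
            continue
        points.add(key)
        if len(points) > max_nodes:
            raise RuntimeError("breakpoint closure exceeded the node budget")
        for d in delays:
            nxt = t + d
            if nxt <= t_last and round(nxt, 10) not in points:
                frontier.append(nxt)
    bps = sorted(points | {0.0, float(t_last)})
    h_max = (min(delays) if delays else t_last) / max(pps, 1)
    mesh = [0.0]
    for a, b in zip(bps[:-1], bps[1:]):
        gap = b - a
        if gap <= 0:
            continue
        n = max(1, int(gap / h_max - 1e-12) + 1)
        step = gap / n
        for k in range(1, n):
            mesh.append(a + k * step)
        mesh.append(b)
    return mesh
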