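"""Multi-scale trajectory simplification.

Two per-vertex complexity measures drive the simplification:

* the *turning* complexity ``c(x)``: for every consecutive segment pair
  (u, v) lying entirely within arc-length ``nu`` of vertex x along the
  polyline, add ``(|u| + |v|)^2 * alpha(u, v)`` with ``alpha`` the angle
  between segment directions in radians.  Collinear paths score exactly 0;
  the value carries units of radians * A^2.
* the *stretch* complexity ``c_DP(x)``: total segment length inside the
  neighborhood divided by the chord between the neighborhood's first and
  last vertex; >= 1 wherever the chord is non-degenerate.

Two back ends realize a "simplification level" on a contiguous interval:

* smoothing: level k = k successive Savitzky-Golay passes (window/order
  fixed), endpoints pinned so the interval partition stays continuous;
* non-smoothing (vertex-preserving): Douglas-Peucker with tolerance
  ``base * 2**(k-1)``, keeping a subset of original vertices.

The interactive scheme updates one interval of a cached multi-level state,
incrementally when possible; the automatic scheme iterates: threshold the
complexity, drop simple points from the complex set, raise the level on
what remains, and stop when the total-complexity improvement falls below
``eps``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .model import (
    LigandTrajectory,
    SimplificationState,
    ValidationError,
)

#: Sentinel assigned to c_DP at degenerate (closed-loop) neighborhoods.
DEGENERATE_SENTINEL = 1.0e6
_CHORD_EPS = 1.0e-9


@dataclass
class ComplexityProfile:
    """Per-vertex complexity values for one trajectory and neighborhood
    radius ``nu`` (arc length, Angstrom)."""

    values: np.ndarray
    nu: float
    measure: str  # "turning" | "stretch"
    degenerate: np.ndarray | None = None  # flags sentinel vertices (stretch)

    @property
    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class AutoSimplifyConfig:
    """Parameters of the automatic simplification loop."""

    tau: float = 1.0  # complexity threshold (radians*A^2 / dimensionless)
    eps: float | None = None  # absolute improvement threshold
    eps_frac: float = 0.01  # eps as a fraction of initial total complexity
    nu: float = 2.0  # neighborhood arc-length radius, Angstrom
    backend: str = "smooth"  # "smooth" | "dp"
    window: int = 9  # Savitzky-Golay window (odd)
    order: int = 2  # Savitzky-Golay polynomial order
    dp_base_tol: float = 0.5  # DP tolerance at level 1, doubling per level
    max_iter: int = 50

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if self.eps is not None and self.eps <= 0:
            raise ValidationError("eps must be > 0")
        if self.eps_frac <= 0:
            raise ValidationError("eps_frac must be > 0")
        if self.nu <= 0:
            raise ValidationError("nu must be > 0")
        if self.backend not in ("smooth", "dp"):
            raise ValidationError(f"unknown backend {self.backend!r}")
        if self.window % 2 == 0 or self.window <= self.order:
            raise ValidationError("window must be odd and greater than order")
        if self.dp_base_tol <= 0:
            raise ValidationError("dp_base_tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")


@dataclass
class AutoSimplifyTrace:
    """Per-iteration record of the automatic simplification loop."""

    iterations: list[dict] = field(default_factory=list)
    converged: bool = True
    hit_cap: bool = False

    def to_dict(self) -> dict:
        return {
            "iterations": self.iterations,
            "converged": self.converged,
            "hit_cap": self.hit_cap,
        }


# ---------------------------------------------------------------------------
# complexity measures


def _neighborhood_bounds(arc: np.ndarray, nu: float) -> tuple[np.ndarray, np.ndarray]:
    """For each vertex x: index range [lo, hi] of vertices with arc-length
    distance to x strictly below nu."""
    lo = np.searchsorted(arc, arc - nu, side="right")
    hi = np.searchsorted(arc, arc + nu, side="left") - 1
    return lo, hi


def complexity(traj: LigandTrajectory | np.ndarray, nu: float = 2.0) -> ComplexityProfile:
    """Turning complexity c(x) at every vertex.

    Sums ``(|u|+|v|)^2 * alpha(u, v)`` over consecutive segment pairs whose
    segments both lie entirely within arc-length ``nu`` of x; vertices whose
    neighborhood holds fewer than two segments score 0.
    """
    pts = _as_points(traj)
    if len(pts) < 3:
        raise ValidationError("complexity needs at least 3 points")
    if nu <= 0:
        raise ValidationError("nu must be > 0")
    seg = np.diff(pts, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])

    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = seg / seg_len[:, None]
    dots = np.einsum("ij,ij->i", dirs[:-1], dirs[1:])
    angles = np.arccos(np.clip(dots, -1.0, 1.0))
    # zero-length segments have no direction: their pairs contribute nothing
    angles = np.where((seg_len[:-1] < 1e-12) | (seg_len[1:] < 1e-12), 0.0, angles)
    pair_w = (seg_len[:-1] + seg_len[1:]) ** 2 * angles
    cum_w = np.concatenate([[0.0], np.cumsum(pair_w)])

    lo, hi = _neighborhood_bounds(arc, nu)
    # segment i spans vertices i..i+1; pair i needs segments i and i+1,
    # i.e. vertices i..i+2 inside the neighborhood => i in [lo, hi-2]
    first = lo
    last = hi - 2
    top = len(cum_w) - 1
    values = np.where(
        last >= first,
        cum_w[np.clip(last + 1, 0, top)] - cum_w[np.clip(first, 0, top)],
        0.0,
    )
    return ComplexityProfile(values=values, nu=nu, measure="turning")


def complexity_dp(
    traj: LigandTrajectory | np.ndarray, nu: float = 2.0
) -> ComplexityProfile:
    """Stretch complexity c_DP(x): neighborhood path length over chord
    length between neighborhood endpoints; degenerate chords (< 1e-9 A) get
    a sentinel value of 1e6 and a flag."""
    pts = _as_points(traj)
    if len(pts) < 3:
        raise ValidationError("complexity needs at least 3 points")
    if nu <= 0:
        raise ValidationError("nu must be > 0")
    seg_len = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    lo, hi = _neighborhood_bounds(arc, nu)

    path = arc[np.maximum(hi, lo)] - arc[lo]
    chord = np.linalg.norm(pts[np.maximum(hi, lo)] - pts[lo], axis=1)
    has_segment = hi > lo
    degenerate = has_segment & (chord < _CHORD_EPS)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(has_segment, path / np.where(chord < _CHORD_EPS, np.nan, chord), 0.0)
    values = np.where(degenerate, DEGENERATE_SENTINEL, values)
    values = np.nan_to_num(values, nan=0.0)
    return ComplexityProfile(values=values, nu=nu, measure="stretch", degenerate=degenerate)


def _as_points(traj) -> np.ndarray:
    if isinstance(traj, LigandTrajectory):
        return traj.positions
    return np.asarray(traj, dtype=float)


# ---------------------------------------------------------------------------
# back ends


def smooth_segment(points: np.ndarray, window: int = 9, order: int = 2) -> np.ndarray:
    """One Savitzky-Golay pass over a 3D (or 1D) point segment.

    Endpoints are returned unchanged so adjacent intervals stay connected.
    Segments shorter than the window shrink it to the largest valid odd
    size; below 3 points the segment is returned unchanged.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if window % 2 == 0 or window <= order:
        raise ValidationError("window must be odd and greater than order")
    if n < 3:
        return pts.copy()
    w = min(window, n if n % 2 == 1 else n - 1)
    if w < 3:
        return pts.copy()
    o = min(order, w - 1)
    out = savgol_filter(pts, window_length=w, polyorder=o, axis=0, mode="interp")
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def decimate_segment(
    points: np.ndarray, tolerance: float
) -> tuple[np.ndarray, np.ndarray]:
    """Douglas-Peucker decimation.

    Returns the kept points and their indices into the input.  Output is a
    subset of input vertices including both endpoints; every discarded
    vertex lies within ``tolerance`` of the output polyline.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        raise ValidationError("decimation needs at least 2 points")
    if tolerance < 0:
        raise ValidationError("tolerance must be >= 0")
    n = len(pts)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        inner = pts[a + 1 : b]
        dists = _point_segment_distance(inner, pts[a], pts[b])
        k = int(np.argmax(dists))
        if dists[k] > tolerance:
            m = a + 1 + k
            keep[m] = True
            stack.append((a, m))
            stack.append((m, b))
    idx = np.flatnonzero(keep)
    return pts[idx], idx


def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points ``p`` (m, 3) to the segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-24:
        return np.linalg.norm(p - a, axis=-1)
    t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[..., None] * ab
    return np.linalg.norm(p - proj, axis=-1)


def dp_tolerance(level: int, base: float) -> float:
    """Level-k Douglas-Peucker tolerance: ``base * 2**(k-1)``; level 0 is raw."""
    if level <= 0:
        return 0.0
    return base * 2.0 ** (level - 1)


def _smooth_passes(points: np.ndarray, n_passes: int, window: int, order: int) -> np.ndarray:
    out = np.asarray(points, dtype=float)
    for _ in range(n_passes):
        out = smooth_segment(out, window=window, order=order)
    return out


# ---------------------------------------------------------------------------
# canonical (from-scratch) recomputation


def recompute(
    traj_in: LigandTrajectory, state: SimplificationState, config: AutoSimplifyConfig
) -> LigandTrajectory:
    """Apply ``state`` to the raw trajectory from scratch.

    Intervals are processed in ascending level order; each maximal interval
    is simplified independently at its own level (disjoint intervals make
    the order immaterial for the result, but it mirrors the multi-level
    bookkeeping of the interactive scheme).
    """
    raw = traj_in.positions
    if state.n != len(raw):
        raise ValidationError("state length does not match trajectory")
    by_level = sorted(state.intervals, key=lambda iv: iv[2])
    if config.backend == "smooth":
        out = raw.copy()
        for s, e, lv in by_level:
            if lv > 0:
                out[s:e] = _smooth_passes(raw[s:e], lv, config.window, config.order)
        return LigandTrajectory(
            positions=out, provenance="simplified", state=state
        )
    # vertex-preserving back end: concatenate per-interval kept vertices
    kept: list[np.ndarray] = []
    for s, e, lv in by_level:
        if lv == 0 or e - s < 2:
            kept.append(np.arange(s, e))
        else:
            _, idx = decimate_segment(raw[s:e], dp_tolerance(lv, config.dp_base_tol))
            kept.append(idx + s)
    kept_idx = np.concatenate(kept)
    kept_idx.sort()
    return LigandTrajectory(
        positions=raw[kept_idx],
        provenance="simplified",
        indices=kept_idx,
        state=state,
    )


# ---------------------------------------------------------------------------
# cache + interactive scheme


def trajectory_key(traj: LigandTrajectory) -> str:
    """Stable content hash identifying a raw trajectory."""
    return hashlib.sha256(np.ascontiguousarray(traj.positions).tobytes()).hexdigest()


@dataclass
class _CacheEntry:
    trajectory: LigandTrajectory
    state: SimplificationState


class SimplificationCache:
    """Stores the last simplified trajectory and its state per (trajectory,
    back-end parameters) key, enabling incremental interval updates."""

    def __init__(self) -> None:
        self._entries: dict[tuple, _CacheEntry] = {}
        self.last_incremental: bool = False

    def _key(self, traj: LigandTrajectory, config: AutoSimplifyConfig) -> tuple:
        return (
            trajectory_key(traj),
            config.backend,
            config.window,
            config.order,
            config.dp_base_tol,
        )

    def get(self, traj: LigandTrajectory, config: AutoSimplifyConfig) -> _CacheEntry | None:
        return self._entries.get(self._key(traj, config))

    def store(
        self,
        traj: LigandTrajectory,
        config: AutoSimplifyConfig,
        result: LigandTrajectory,
        state: SimplificationState,
    ) -> None:
        self._entries[self._key(traj, config)] = _CacheEntry(result, state)


def incremental_applicable(
    cached_state: SimplificationState, start: int, end: int, level: int
) -> bool:
    """Whether the interval edit can reuse the cached trajectory.

    The edit must coincide exactly with one maximal interval of the cached
    state, at a uniform current level <= the target, and must not merge
    with an equal-level neighbor afterwards (per-interval simplification is
    range-sensitive, so a merge forces recomputation).
    """
    ivs = cached_state.intervals
    for i, (s, e, lv) in enumerate(ivs):
        if (s, e) == (start, end):
            if lv > level:
                return False
            if i > 0 and ivs[i - 1][2] == level:
                return False
            if i < len(ivs) - 1 and ivs[i + 1][2] == level:
                return False
            return True
    return False


def simplify_interactive(
    traj_in: LigandTrajectory,
    interval: tuple[int, int, int],
    cache: SimplificationCache | None = None,
    config: AutoSimplifyConfig | None = None,
) -> tuple[LigandTrajectory, SimplificationState]:
    """Set one interval of the multi-level simplification state.

    ``interval`` is ``(start, end, target_level)`` over raw step indices.
    With a warm cache whose state allows it, the result is produced
    incrementally from the cached trajectory; otherwise it is recomputed
    from the raw input.  The result is stored back into the cache.
    """
    config = config or AutoSimplifyConfig()
    start, end, level = interval
    n = len(traj_in)
    if not (0 <= start < end <= n):
        raise ValidationError(f"interval [{start}, {end}) out of bounds for n={n}")
    if level < 0:
        raise ValidationError("target level must be >= 0")

    entry = cache.get(traj_in, config) if cache is not None else None
    prev_state = entry.state if entry is not None else SimplificationState.raw(n)
    new_state = prev_state.with_interval(start, end, level)

    incremental = False
    if (
        entry is not None
        and config.backend == "smooth"
        and level > 0
        and incremental_applicable(prev_state, start, end, level)
    ):
        cur_level = prev_state.level_at(start)
        out = entry.trajectory.positions.copy()
        out[start:end] = _smooth_passes(
            out[start:end], level - cur_level, config.window, config.order
        )
        result = LigandTrajectory(
            positions=out, provenance="simplified", state=new_state
        )
        incremental = True
    elif (
        entry is not None
        and config.backend == "dp"
        and level > 0
        and incremental_applicable(prev_state, start, end, level)
        and entry.trajectory.indices is not None
    ):
        # re-run DP on the cached kept vertices with the larger tolerance:
        # keeps the subset-of-original-vertices guarantee
        raw = traj_in.positions
        old_idx = entry.trajectory.indices
        in_iv = old_idx[(old_idx >= start) & (old_idx < end)]
        if len(in_iv) >= 2:
            _, sub = decimate_segment(
                raw[in_iv], dp_tolerance(level, config.dp_base_tol)
            )
            new_in_iv = in_iv[sub]
        else:
            new_in_iv = in_iv
        kept_idx = np.concatenate(
            [old_idx[old_idx < start], new_in_iv, old_idx[old_idx >= end]]
        )
        kept_idx.sort()
        result = LigandTrajectory(
            positions=raw[kept_idx],
            provenance="simplified",
            indices=kept_idx,
            state=new_state,
        )
        incremental = True
    else:
        result = recompute(traj_in, new_state, config)

    if cache is not None:
        cache.store(traj_in, config, result, new_state)
        cache.last_incremental = incremental
    return result, new_state


# ---------------------------------------------------------------------------
# automatic scheme


def _complexity_for(config: AutoSimplifyConfig, traj) -> ComplexityProfile:
    if config.backend == "dp":
        return complexity_dp(traj, nu=config.nu)
    return complexity(traj, nu=config.nu)


def _subtract_points(
    intervals: list[tuple[int, int]], simple_idx: np.ndarray
) -> list[tuple[int, int]]:
    """Remove simple step indices from the complex interval set, splitting
    intervals; fragments too short to simplify (< 3 steps) are dropped."""
    if len(simple_idx) == 0:
        return [iv for iv in intervals if iv[1] - iv[0] >= 3]
    simple = np.zeros(max(e for _, e in intervals) if intervals else 0, dtype=bool)
    simple[simple_idx[simple_idx < len(simple)]] = True
    out: list[tuple[int, int]] = []
    for a, b in intervals:
        run_start = None
        for i in range(a, b):
            if not simple[i]:
                if run_start is None:
                    run_start = i
            else:
                if run_start is not None and i - run_start >= 3:
                    out.append((run_start, i))
                run_start = None
        if run_start is not None and b - run_start >= 3:
            out.append((run_start, b))
    return out


def simplify_auto(
    traj_in: LigandTrajectory, config: AutoSimplifyConfig | None = None
) -> tuple[LigandTrajectory, SimplificationState, AutoSimplifyTrace]:
    """Automatic multi-scale simplification.

    Iterates: evaluate the complexity of the current trajectory; mark
    vertices below ``tau`` simple and remove them from the complex set C
    (splitting its intervals); raise the simplification level by one on
    every remaining complex interval; stop when C is empty, the improvement
    drops below ``eps``, or the iteration cap is hit.
    """
    config = config or AutoSimplifyConfig()
    n = len(traj_in)
    if n < 3:
        raise ValidationError("automatic simplification needs >= 3 points")

    cache = SimplificationCache()
    state = SimplificationState.raw(n)
    current = traj_in
    complex_set: list[tuple[int, int]] = [(0, n)]
    trace = AutoSimplifyTrace()

    profile = _complexity_for(config, current)
    total = profile.total
    eps = config.eps if config.eps is not None else config.eps_frac * total

    for iteration in range(config.max_iter):
        # map vertex complexities to raw step indices (identity for the
        # smoothing back end; kept-index mapping after decimation)
        raw_idx = (
            current.indices
            if current.indices is not None
            else np.arange(len(profile.values))
        )
        simple_raw = raw_idx[profile.values < config.tau]
        complex_set = _subtract_points(complex_set, simple_raw)
        record = {
            "iteration": iteration,
            "n_complex_intervals": len(complex_set),
            "complex_steps": int(sum(e - s for s, e in complex_set)),
            "total_complexity": total,
        }
        if not complex_set:
            record["delta_c"] = 0.0
            trace.iterations.append(record)
            break
        levels = state.levels_array()
        for a, b in complex_set:
            lv = int(levels[a:b].max()) + 1
            current, state = simplify_interactive(
                traj_in, (a, b, lv), cache=cache, config=config
            )
        profile = _complexity_for(config, current)
        new_total = profile.total
        delta = total - new_total
        total = new_total
        record["delta_c"] = delta
        record["total_complexity_after"] = new_total
        trace.iterations.append(record)
        if delta < eps:
            break
    else:
        trace.converged = False
        trace.hit_cap = True

    result = LigandTrajectory(
        positions=current.positions,
        provenance="simplified",
        indices=current.indices,
        state=state,
    )
    return result, state, trace
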