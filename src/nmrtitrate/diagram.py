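"""δ-diagram stage: paired-probe trajectories and pH-independent ΔK.

Plotting one probe's shift against another's over the course of a
titration removes the pH axis entirely: a single two-state process traces
a straight chord, two sequential processes trace two chords meeting at a
vertex, and the *shape* of the trajectory — not the pH readings — carries
the ratio of the equilibrium constants.  Two classical readings of that
shape are implemented:

* Perrin linearization — for two coupled sites titrating together, the
  bilinear transform u = (δ_x − δ_x°)(δ_y^e − δ_y),
  v = (δ_y − δ_y°)(δ_x^e − δ_x) is exactly proportional, and the
  least-squares slope of v on u equals K_y/K_x (the site-constant
  quotient of the probe-y site over the probe-x site);
* Polster–Lachmann Gibbs-triangle analysis — for sequential two-step
  systems, distance ratios among the initial state A, the vertex B, the
  final state C and an experimental point on the curve give the quotient
  of the stepwise constants.

Both need no pH values at all, which is their point: pH metering in
deuterated solvents is the least reliable part of the experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import DegenerateDataError, TitrationError, TitrationSeries
from .hh import FitError

__all__ = [
    "DeltaDiagram",
    "SegmentFit",
    "PiecewiseModel",
    "LinearityResult",
    "PerrinFit",
    "GibbsTriangle",
    "PLResult",
    "DegenerateTriangleError",
    "build_diagram",
    "linearity_check",
    "perrin_fit",
    "polster_lachmann",
    "estimate_vertices",
]

# ---------------------------------------------------------------------------
# model-selection constants (see docs/methods.md for the rationale)

#: Residual slack for choosing among corner-valid piecewise models.
TOL_MODEL = 0.05
#: Perrin slopes within this distance of 1 raise the near-unity flag.
TOL_UNITY = 0.005
#: Half-width (in points) of the turning window attributed to one vertex.
CORNER_WINDOW = 2
#: A vertex is a corner only if its window holds this fraction of the turn.
CORNER_FRAC = 0.8
#: Total trajectory turning below this is treated as collinear (radians).
MIN_TOTAL_TURN = math.radians(5.0)
#: Adjacent fitted segments must differ by at least this angle (radians).
MIN_SEGMENT_ANGLE = math.radians(10.0)


class DegenerateTriangleError(TitrationError):
    """The Gibbs-triangle construction collapsed (collinear or parallel)."""


@dataclass(frozen=True)
class DeltaDiagram:
    """Ordered (δ_x, δ_y) trajectory of a probe pair.

    Only points where both probes were observed are included;
    ``source_index`` maps each diagram point back to its position in the
    originating series.  Anchors default to the first/last included point
    and may be overridden for truncated titrations.
    """

    points: np.ndarray           # shape (n, 2)
    start_anchor: tuple[float, float]
    end_anchor: tuple[float, float]
    probe_x: str
    probe_y: str
    source_index: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return int(self.points.shape[0])

    @property
    def scale(self) -> float:
        """Diagonal length of the bounding box (ppm)."""
        span = self.points.max(axis=0) - self.points.min(axis=0)
        return float(np.hypot(*span))

    def reversed(self) -> "DeltaDiagram":
        """Same trajectory walked in the opposite titration direction."""
        return DeltaDiagram(
            self.points[::-1].copy(),
            self.end_anchor,
            self.start_anchor,
            self.probe_x,
            self.probe_y,
            self.source_index[::-1].copy(),
        )

    def swapped(self) -> "DeltaDiagram":
        """Probe roles exchanged (x ↔ y)."""
        return DeltaDiagram(
            self.points[:, ::-1].copy(),
            self.start_anchor[::-1],
            self.end_anchor[::-1],
            self.probe_y,
            self.probe_x,
            self.source_index.copy(),
        )


def build_diagram(
    series: TitrationSeries,
    probe_x: str,
    probe_y: str,
    start_anchor: tuple[float, float] | None = None,
    end_anchor: tuple[float, float] | None = None,
) -> DeltaDiagram:
    """Pair the two probes' shifts in titration order.

    Needs at least three points carrying both probes.
    """
    if probe_x == probe_y:
        raise ValueError("probe_x and probe_y must differ")
    pts: list[tuple[float, float]] = []
    idx: list[int] = []
    for i, p in enumerate(series.points):
        if probe_x in p.shifts and probe_y in p.shifts:
            pts.append((p.shifts[probe_x], p.shifts[probe_y]))
            idx.append(i)
    if len(pts) < 3:
        raise DegenerateDataError(
            f"only {len(pts)} points carry both {probe_x!r} and {probe_y!r}"
        )
    points = np.asarray(pts, dtype=float)
    return DeltaDiagram(
        points=points,
        start_anchor=start_anchor or tuple(points[0]),
        end_anchor=end_anchor or tuple(points[-1]),
        probe_x=probe_x,
        probe_y=probe_y,
        source_index=np.asarray(idx, dtype=int),
    )


# ---------------------------------------------------------------------------
# piecewise-linear fitting (orthogonal residuals, vertices at data points)


@dataclass(frozen=True)
class SegmentFit:
    """One fitted straight branch over an inclusive index range."""

    start: int
    stop: int
    centroid: np.ndarray
    direction: np.ndarray        # unit vector, oriented along data order
    rss: float                   # sum of squared orthogonal distances

    def line_point(self) -> np.ndarray:
        return self.centroid

    def endpoints(self, points: np.ndarray) -> np.ndarray:
        """Projections of the range's first/last data point onto the line."""
        rel = points[[self.start, self.stop]] - self.centroid
        t = rel @ self.direction
        return self.centroid + np.outer(t, self.direction)


@dataclass(frozen=True)
class PiecewiseModel:
    """A 0-, 1- or 2-vertex piecewise-linear description of a diagram."""

    n_breaks: int
    vertices: tuple[int, ...]    # data-point indices of the interior vertices
    segments: tuple[SegmentFit, ...]
    rss: float


class _Cumulants:
    """O(1) orthogonal line fits over index ranges via prefix sums."""

    def __init__(self, points: np.ndarray) -> None:
        self.P = points
        z = np.zeros((1, 2))
        self.s1 = np.vstack([z, np.cumsum(points, axis=0)])
        sq = np.einsum("ni,nj->nij", points, points)
        self.s2 = np.concatenate([np.zeros((1, 2, 2)), np.cumsum(sq, axis=0)])

    def fit(self, i: int, j: int) -> SegmentFit:
        """Fit indices i..j inclusive (j > i)."""
        m = j - i + 1
        s1 = self.s1[j + 1] - self.s1[i]
        s2 = self.s2[j + 1] - self.s2[i]
        centroid = s1 / m
        scatter = s2 - np.outer(s1, s1) / m
        # symmetric 2x2 eigendecomposition in closed form
        a, b, c = scatter[0, 0], scatter[0, 1], scatter[1, 1]
        tr, det = a + c, a * c - b * b
        disc = math.sqrt(max(tr * tr / 4 - det, 0.0))
        lam_max, lam_min = tr / 2 + disc, tr / 2 - disc
        if abs(b) > 1e-300:
            direction = np.array([lam_max - c, b])
        elif a >= c:
            direction = np.array([1.0, 0.0])
        else:
            direction = np.array([0.0, 1.0])
        norm = np.hypot(*direction)
        direction = direction / norm if norm > 0 else np.array([1.0, 0.0])
        chord = self.P[j] - self.P[i]
        if chord @ direction < 0:
            direction = -direction
        return SegmentFit(i, j, centroid, direction, max(lam_min, 0.0))


def _best_model(cum: _Cumulants, n: int, k: int) -> PiecewiseModel:
    """Exhaustive search over vertex placements for k interior vertices."""
    if k == 0:
        seg = cum.fit(0, n - 1)
        return PiecewiseModel(0, (), (seg,), seg.rss)
    if k == 1:
        best = None
        for v in range(1, n - 1):
            s1, s2 = cum.fit(0, v), cum.fit(v, n - 1)
            rss = s1.rss + s2.rss
            if best is None or rss < best.rss:
                best = PiecewiseModel(1, (v,), (s1, s2), rss)
        return best
    if k == 2:
        best = None
        for v1 in range(1, n - 2):
            s1 = cum.fit(0, v1)
            for v2 in range(v1 + 1, n - 1):
                s2, s3 = cum.fit(v1, v2), cum.fit(v2, n - 1)
                rss = s1.rss + s2.rss + s3.rss
                if best is None or rss < best.rss:
                    best = PiecewiseModel(2, (v1, v2), (s1, s2, s3), rss)
        return best
    raise ValueError("at most 2 interior vertices are supported")


def _turning_profile(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Unsigned turning angle attributed to each data point, and the total.

    Near-duplicate consecutive points (plateau repeats) are merged before
    measuring directions, so plateaus do not register spurious turning.
    """
    n = points.shape[0]
    span = points.max(axis=0) - points.min(axis=0)
    floor = 1e-9 * max(float(np.hypot(*span)), 1e-300)
    kept = [0]
    for i in range(1, n):
        if np.hypot(*(points[i] - points[kept[-1]])) > floor:
            kept.append(i)
    phi = np.zeros(n)
    for a, b, c in zip(kept, kept[1:], kept[2:]):
        v1, v2 = points[b] - points[a], points[c] - points[b]
        ang = abs(math.atan2(v1[0] * v2[1] - v1[1] * v2[0], float(v1 @ v2)))
        phi[b] = ang
    return phi, float(phi.sum())


@dataclass(frozen=True)
class LinearityResult:
    """All candidate piecewise models plus the selected breakpoint count."""

    models: dict[int, PiecewiseModel]
    selected: int
    total_turn: float
    corner_ok: dict[int, bool]   # per candidate k: all vertices are corners

    @property
    def n_breaks(self) -> int:
        return self.selected

    @property
    def model(self) -> PiecewiseModel:
        return self.models[self.selected]

    @property
    def segments(self) -> tuple[SegmentFit, ...]:
        return self.model.segments


def _segment_angle(s1: SegmentFit, s2: SegmentFit) -> float:
    d1, d2 = s1.direction, s2.direction
    return abs(math.atan2(d1[0] * d2[1] - d1[1] * d2[0], float(d1 @ d2)))


def _vertices_are_corners(
    model: PiecewiseModel, phi: np.ndarray, total: float
) -> bool:
    """True genuine kinks: concentrated turning plus distinct branch angles.

    A smoothly curved trajectory (two strongly overlapping equilibria)
    turns gradually along its whole length; a stepwise system turns almost
    entirely at its vertices.  Requiring each candidate vertex to hold at
    least :data:`CORNER_FRAC` of its share of the total turning inside a
    ±:data:`CORNER_WINDOW`-point window separates the two regimes.
    """
    if total < MIN_TOTAL_TURN:
        return False
    # vertices must be resolved from each other
    for a, b in zip(model.vertices, model.vertices[1:]):
        if b - a <= 2 * CORNER_WINDOW:
            return False
    n = phi.size
    for v, s1, s2 in zip(model.vertices, model.segments, model.segments[1:]):
        # the bend this vertex is responsible for: all turning between the
        # midpoints of its two flanking segments
        mid1 = (s1.start + s1.stop) // 2
        mid2 = (s2.start + s2.stop) // 2
        bend = float(phi[mid1 : mid2 + 1].sum())
        lo, hi = max(v - CORNER_WINDOW, 0), min(v + CORNER_WINDOW, n - 1)
        mass = float(phi[lo : hi + 1].sum())
        if bend <= 0 or mass < CORNER_FRAC * bend:
            return False
        if _segment_angle(s1, s2) < MIN_SEGMENT_ANGLE:
            return False
    return True


def linearity_check(
    diagram: DeltaDiagram, max_breaks: int = 2, tol_model: float = TOL_MODEL
) -> LinearityResult:
    """Classify a diagram as linear, one-vertex or two-vertex piecewise.

    Candidate models with 0..max_breaks interior vertices (vertices at
    data points, exhaustive placement, orthogonal residuals) are fitted.
    Models whose vertices are not genuine corners (see
    :func:`_vertices_are_corners`) are vetoed; among the survivors the
    smallest vertex count whose residual sum is within a factor
    ``1 + tol_model`` of the best is selected.
    """
    n = len(diagram)
    if max_breaks not in (0, 1, 2):
        raise ValueError("max_breaks must be 0, 1 or 2")
    if max_breaks >= 1 and n < 4:
        raise ValueError("need at least 4 points to consider 1 breakpoint")
    if max_breaks >= 2 and n < 6:
        raise ValueError("need at least 6 points to consider 2 breakpoints")

    cum = _Cumulants(diagram.points)
    models = {k: _best_model(cum, n, k) for k in range(max_breaks + 1)}
    phi, total = _turning_profile(diagram.points)
    corner_ok = {
        k: (k == 0) or _vertices_are_corners(m, phi, total)
        for k, m in models.items()
    }
    valid = [k for k in models if corner_ok[k]]
    floor = (1e-9 * max(diagram.scale, 1e-300)) ** 2 * n
    best_rss = min(models[k].rss for k in valid)
    selected = min(
        k for k in valid if models[k].rss <= (1.0 + tol_model) * best_rss + floor
    )
    return LinearityResult(models, selected, total, corner_ok)


# ---------------------------------------------------------------------------
# Perrin bilinear linearization


@dataclass(frozen=True)
class PerrinFit:
    """Slope of the bilinear transform: the site-constant quotient K_y/K_x."""

    delta_K: float
    intercept: float             # ppm^2
    slope_stderr: float
    r: float
    n_used: int
    near_unity: bool


def perrin_fit(diagram: DeltaDiagram) -> PerrinFit:
    """Least-squares slope of v on u over the interior points.

    u = (δ_x − δ_x°)(δ_y^e − δ_y), v = (δ_y − δ_y°)(δ_x^e − δ_x); both
    vanish at the anchors by construction, so the first and last points are
    excluded from the regression.  The free intercept absorbs imperfect
    anchor estimates and is reported in ppm².
    """
    x0, y0 = diagram.start_anchor
    xe, ye = diagram.end_anchor
    if x0 == xe or y0 == ye:
        raise DegenerateDataError(
            "anchors must differ in both coordinates for the bilinear transform"
        )
    if len(diagram) < 4:
        raise DegenerateDataError("need at least 2 interior points")
    inner = diagram.points[1:-1]
    dx, dy = inner[:, 0], inner[:, 1]
    u = (dx - x0) * (ye - dy)
    v = (dy - y0) * (xe - dx)
    n = u.size
    su = float(np.sum((u - u.mean()) ** 2))
    if su == 0.0:
        raise FitError("all transformed abscissae identical: singular fit")
    slope = float(np.sum((u - u.mean()) * (v - v.mean())) / su)
    intercept = float(v.mean() - slope * u.mean())
    resid = v - (intercept + slope * u)
    ss_res = float(resid @ resid)
    sv = float(np.sum((v - v.mean()) ** 2))
    r = math.copysign(math.sqrt(max(1.0 - ss_res / sv, 0.0)), slope) if sv > 0 else 0.0
    sigma2 = ss_res / (n - 2) if n > 2 else 0.0
    slope_stderr = math.sqrt(sigma2 / su)
    if slope <= 0.0:
        raise FitError(
            f"non-positive bilinear slope {slope:.3g}: probes do not report "
            "a common deprotonation process"
        )
    return PerrinFit(
        delta_K=slope,
        intercept=intercept,
        slope_stderr=slope_stderr,
        r=r,
        n_used=int(n),
        near_unity=abs(slope - 1.0) <= TOL_UNITY,
    )


# ---------------------------------------------------------------------------
# Polster–Lachmann Gibbs-triangle analysis


@dataclass(frozen=True)
class GibbsTriangle:
    """Characteristic points of the two-step construction.

    A — initial state; B — the neutralization vertex (intersection of the
    first and last branch lines); C — final state; BC — the experimental
    point on the curve used for the distance reading.
    """

    A: tuple[float, float]
    B: tuple[float, float]
    C: tuple[float, float]
    BC: tuple[float, float]


@dataclass(frozen=True)
class PLResult:
    """Gibbs-triangle estimate of the stepwise-constant quotient K1/K2.

    ``distance_ratio`` is the single cevian reading |B→X| / |X→C| (X = the
    intersection of the ray A→BC with side B–C); ``delta_K`` is the
    pH-independent product of the two cevian ratios, which equals
    [HA]² / ([H₂A][A²⁻]) = K1/K2 for any experimental point BC.
    """

    delta_K: float
    triangle: GibbsTriangle
    distance_ratio: float


def _intersect(p1: np.ndarray, d1: np.ndarray, p2: np.ndarray, d2: np.ndarray,
               scale: float) -> np.ndarray:
    det = d1[0] * d2[1] - d1[1] * d2[0]
    norm = np.hypot(*d1) * np.hypot(*d2)
    if abs(det) < 1e-9 * norm:
        raise DegenerateTriangleError("lines are (nearly) parallel")
    t = ((p2[0] - p1[0]) * d2[1] - (p2[1] - p1[1]) * d2[0]) / det
    return p1 + t * d1


def _refit_outer(cum: _Cumulants, seg: SegmentFit, points: np.ndarray,
                 from_start: bool) -> SegmentFit:
    """Re-fit a terminal branch on its anchor-side half (by arc length).

    Near the vertex the trajectory bends away from the asymptotic branch
    line; the half of the branch next to its anchor is the part least
    contaminated by the other equilibrium.
    """
    i, j = seg.start, seg.stop
    if j - i < 4:
        return seg
    steps = np.hypot(*np.diff(points[i : j + 1], axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(steps)])
    half = arc[-1] / 2.0
    if from_start:
        stop = i + int(np.searchsorted(arc, half, side="right"))
        stop = min(max(stop, i + 2), j)
        return cum.fit(i, stop)
    start = i + int(np.searchsorted(arc, half, side="left"))
    start = max(min(start, j - 2), i)
    return cum.fit(start, j)


def _barycentric(
    P: np.ndarray, A: np.ndarray, B: np.ndarray, C: np.ndarray
) -> np.ndarray:
    """Barycentric coordinates (x_A, x_B, x_C) of rows of P in triangle ABC."""
    M = np.column_stack([B - A, C - A])
    sol = np.linalg.solve(M, (np.atleast_2d(P) - A).T).T
    x1, x2 = sol[:, 0], sol[:, 1]
    return np.column_stack([1.0 - x1 - x2, x1, x2])


def _consistency_vertex(
    points: np.ndarray, A: np.ndarray, C: np.ndarray, B0: np.ndarray,
    scale: float,
) -> np.ndarray:
    """Locate the neutralization vertex by distance-ratio self-consistency.

    For the true vertex the Gibbs-triangle reading x_B²/(x_A·x_C) is the
    same at every experimental point (it equals K1/K2 independently of
    pH); a misplaced vertex makes the reading drift along the curve.  The
    vertex is therefore taken as the point minimising the variance of the
    log-reading over the interior of the curve, starting from the
    intersection of the fitted terminal branches.  Falls back to ``B0``
    if the optimisation cannot improve on it.
    """
    from scipy.optimize import minimize

    # Fix the evaluation set once.  The data curve bulges beyond the
    # triangle of the (biased) initial vertex, so membership is judged in
    # a triangle enlarged away from the A–C chord; points hugging the
    # sides are dropped as ill-conditioned.
    try:
        mid = (A + C) / 2.0
        B_init = mid + 1.6 * (B0 - mid)
        x_sel = _barycentric(points[1:-1], A, B_init, C)
    except np.linalg.LinAlgError:
        return B0
    interior = points[1:-1][(x_sel > 0.04).all(axis=1)]
    if interior.shape[0] < 4:
        return B0

    def objective(b: np.ndarray) -> float:
        try:
            x = _barycentric(interior, A, b, C)
        except np.linalg.LinAlgError:
            return 1e9
        bad = x <= 1e-6
        if bad.any():
            # soft barrier: finite, decreasing as points re-enter the triangle
            return 1e3 + float(np.where(bad, 1e-6 - x, 0.0).sum()) * 1e3
        g = np.log(x[:, 1] ** 2 / (x[:, 0] * x[:, 2]))
        return float(np.var(g))

    # start inside the valid region: every evaluation point is interior to
    # the enlarged triangle by construction
    res = minimize(
        objective, B_init, method="Nelder-Mead",
        options={"xatol": 1e-10 * scale, "fatol": 1e-20, "maxiter": 4000},
    )
    B = np.asarray(res.x)
    if (
        np.isfinite(res.fun)
        and res.fun < min(objective(B_init), 1e2)
        and np.hypot(*(B - B0)) < 0.5 * scale
    ):
        return B
    return B0


def estimate_vertices(
    diagram: DeltaDiagram,
    model: PiecewiseModel,
    consistency_fit: bool = True,
) -> list[np.ndarray]:
    """Intermediate-state coordinate estimates, one per interior vertex.

    Each vertex is the intersection of its flanking segment lines, with
    terminal segments re-fitted on their anchor-side halves; a single
    vertex is additionally refined by distance-ratio self-consistency
    (see :func:`_consistency_vertex`).  Falls back to the vertex data
    point when the flanking lines are parallel.
    """
    P = diagram.points
    cum = _Cumulants(P)
    scale = max(diagram.scale, 1e-300)
    out: list[np.ndarray] = []
    last = len(model.vertices) - 1
    for i, (v, s1, s2) in enumerate(
        zip(model.vertices, model.segments, model.segments[1:])
    ):
        l1 = _refit_outer(cum, s1, P, from_start=True) if i == 0 else s1
        l2 = _refit_outer(cum, s2, P, from_start=False) if i == last else s2
        try:
            B = _intersect(l1.centroid, l1.direction, l2.centroid, l2.direction,
                           scale)
        except DegenerateTriangleError:
            B = P[v].copy()
        out.append(B)
    if consistency_fit and model.n_breaks == 1:
        A = np.asarray(diagram.start_anchor, dtype=float)
        C = np.asarray(diagram.end_anchor, dtype=float)
        out[0] = _consistency_vertex(P, A, C, out[0], scale)
    return out


def polster_lachmann(
    diagram: DeltaDiagram,
    linearity: LinearityResult | PiecewiseModel,
    refine_branches: bool = True,
    consistency_fit: bool = True,
) -> PLResult:
    """Distance-ratio estimate of K1/K2 from the Gibbs triangle.

    ``linearity`` must provide a model with at least one interior vertex:
    either a :class:`LinearityResult` whose selected model has ≥ 1
    breakpoint, or an explicit :class:`PiecewiseModel` (e.g.
    ``linearity_check(d).models[1]`` when the analyst posits a two-step
    system whose steps overlap too much to raise a corner).

    The vertex B is initialised from the intersection of the terminal
    branch lines and, when ``consistency_fit`` is on (default), refined
    so that the distance-ratio reading is constant along the curve — the
    defining property of the true vertex, and the only unbiased choice
    when the two steps overlap appreciably.
    """
    if isinstance(linearity, LinearityResult):
        if linearity.selected < 1:
            raise DegenerateTriangleError(
                "no breakpoint detected: the diagram offers no usable triangle"
            )
        model = linearity.model
    else:
        model = linearity
    if model.n_breaks < 1:
        raise DegenerateTriangleError("a model with ≥ 1 vertex is required")

    P = diagram.points
    scale = max(diagram.scale, 1e-300)
    cum = _Cumulants(P)
    first, last = model.segments[0], model.segments[-1]
    if refine_branches:
        first = _refit_outer(cum, first, P, from_start=True)
        last = _refit_outer(cum, last, P, from_start=False)

    A = np.asarray(diagram.start_anchor, dtype=float)
    C = np.asarray(diagram.end_anchor, dtype=float)
    B = _intersect(first.centroid, first.direction, last.centroid, last.direction,
                   scale)
    if consistency_fit:
        B = _consistency_vertex(P, A, C, B, scale)

    # experimental point: the data point at the breakpoint vertex nearest B
    v = min(model.vertices, key=lambda i: float(np.hypot(*(P[i] - B))))
    BC = P[v]

    area2 = abs(
        (B[0] - A[0]) * (C[1] - A[1]) - (B[1] - A[1]) * (C[0] - A[0])
    )
    if area2 < 1e-9 * scale**2:
        raise DegenerateTriangleError("A, B, C are (nearly) collinear")
    for corner, name in ((A, "A"), (C, "C")):
        if np.hypot(*(BC - corner)) < 1e-9 * scale:
            raise DegenerateTriangleError(f"experimental point coincides with {name}")

    X = _intersect(A, BC - A, B, C - B, scale)       # cevian A→BC on side B–C
    Y = _intersect(C, BC - C, A, B - A, scale)       # cevian C→BC on side A–B
    bx, xc = np.hypot(*(B - X)), np.hypot(*(X - C))
    ay, yb = np.hypot(*(A - Y)), np.hypot(*(Y - B))
    if min(xc, yb) < 1e-12 * scale:
        raise DegenerateTriangleError("cevian foot collapsed onto a triangle corner")
    # interior check: the feet must lie inside their sides
    if (X - B) @ (C - B) < 0 or (X - C) @ (B - C) < 0:
        raise DegenerateTriangleError("experimental point lies outside the triangle")
    ratio1 = bx / xc                                  # = x(A2-)/x(HA-)
    ratio2 = ay / yb                                  # = x(HA-)/x(H2A)
    if ratio1 <= 0:
        raise DegenerateTriangleError("degenerate cevian ratio")
    delta_K = ratio2 / ratio1
    triangle = GibbsTriangle(tuple(A), tuple(B), tuple(C), tuple(BC))
    return PLResult(delta_K=delta_K, triangle=triangle, distance_ratio=ratio1)
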