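"""Constraint-matched dot-array stimuli for the connectedness numerosity illusion.

Stimuli are arrays of 18 or 24 dots on a gray background, shown either
*connected* (pairs of dots joined by a line into dumbbell shapes, which
reduces perceived numerosity) or *isolated* (the lines displaced to random
positions, experiment 1, or removed and their ink absorbed into enlarged
dots, experiment 2).  Across the four cells of an experiment the total ink
(union area of all dots and lines, in deg^2) and the convex hull of the
array are iteratively matched, so that mean luminance and covered area
cannot explain condition differences.

All geometry is expressed in visual degrees.  Shapes are represented with
shapely; ink is the area of the union (junction overlap is never counted
twice), and the convex hull is taken over the outer ink extents (dot edges
and connector corners), not over dot centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

__all__ = [
    "Dot",
    "Connector",
    "DotArrayStimulus",
    "GeometryConfig",
    "SpectrumProfile",
    "PlacementError",
    "PairingError",
    "MatchingError",
    "place_items",
    "connect_pairs",
    "isolate_by_displacement",
    "isolate_by_removal",
    "match_constraints",
    "generate_condition_set",
    "rasterize",
    "ink_area",
    "convex_hull_area",
    "radial_fourier_amplitude",
]

Connectedness = Literal["connected", "isolated-displaced", "isolated-removed"]


class PlacementError(RuntimeError):
    """No admissible position found for an item under the separation rule."""


class PairingError(RuntimeError):
    """No dot pairing exists with connector lengths in the configured range."""


class MatchingError(RuntimeError):
    """Iterative ink/hull matching failed to converge."""


@dataclass(frozen=True)
class Dot:
    center_x: float
    center_y: float
    diameter: float

    def __post_init__(self):
        if not self.diameter > 0:
            raise ValueError("dot diameter must be > 0")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0

    def shape(self, quad_segs: int = 64):
        return Point(self.center_x, self.center_y).buffer(self.radius, quad_segs=quad_segs)


@dataclass(frozen=True)
class Connector:
    x1: float
    y1: float
    x2: float
    y2: float
    width: float

    def __post_init__(self):
        if not self.width > 0:
            raise ValueError("connector width must be > 0")
        if not self.length > 0:
            raise ValueError("connector length must be > 0")

    @property
    def length(self) -> float:
        return math.hypot(self.x2 - self.x1, self.y2 - self.y1)

    @property
    def center(self) -> tuple[float, float]:
        return ((self.x1 + self.x2) / 2.0, (self.y1 + self.y2) / 2.0)

    def shape(self):
        # flat caps -> exact rectangle of length x width
        return LineString([(self.x1, self.y1), (self.x2, self.y2)]).buffer(
            self.width / 2.0, cap_style="flat"
        )


@dataclass(frozen=True)
class DotArrayStimulus:
    dots: tuple[Dot, ...]
    connectors: tuple[Connector, ...]
    connectedness: Connectedness
    polarity: Literal["black", "white"] = "white"
    experiment: Literal["exp1", "exp2"] = "exp1"
    # for connected stimuli: pairs[i] = (dot index a, dot index b) joined by connectors[i]
    pairs: tuple[tuple[int, int], ...] = ()

    @property
    def numerosity(self) -> int:
        return len(self.dots)

    def shapes(self):
        return [d.shape() for d in self.dots] + [c.shape() for c in self.connectors]

    def items(self):
        """Separation units: dumbbells count as one item when connected."""
        if self.connectedness == "connected":
            out = []
            for k, (i, j) in enumerate(self.pairs):
                out.append(
                    unary_union(
                        [self.dots[i].shape(), self.dots[j].shape(), self.connectors[k].shape()]
                    )
                )
            return out
        return self.shapes()

    def to_dict(self) -> dict:
        return {
            "numerosity": self.numerosity,
            "connectedness": self.connectedness,
            "polarity": self.polarity,
            "experiment": self.experiment,
            "dots": [[d.center_x, d.center_y, d.diameter] for d in self.dots],
            "connectors": [[c.x1, c.y1, c.x2, c.y2, c.width] for c in self.connectors],
            "pairs": [list(p) for p in self.pairs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DotArrayStimulus":
        return cls(
            dots=tuple(Dot(*row) for row in d["dots"]),
            connectors=tuple(Connector(*row) for row in d["connectors"]),
            connectedness=d["connectedness"],
            polarity=d.get("polarity", "white"),
            experiment=d.get("experiment", "exp1"),
            pairs=tuple(tuple(p) for p in d.get("pairs", ())),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "DotArrayStimulus":
        return cls.from_dict(json.loads(s))


@dataclass(frozen=True)
class GeometryConfig:
    """Geometry of one experiment's stimulus set.

    Dot diameters, connector width and length ranges follow the published
    display parameters; ``target_ink`` and ``target_hull`` are the matched
    ink and convex-hull areas all four conditions converge to.
    """

    experiment: Literal["exp1", "exp2"] = "exp1"
    min_separation: float = 0.5
    dot_diameter_by_n: dict = field(default_factory=lambda: {18: 2.2, 24: 1.9})
    connector_width: float = 1.03
    connector_length_range: tuple[float, float] = (2.0, 3.0)
    target_ink: float = 92.7
    target_hull: float = 513.0
    field_radius: float = 13.5
    pixels_per_degree: float = 20.0
    ink_tolerance: float = 0.005
    hull_tolerance: float = 0.005
    max_iterations: int = 500
    luminance_min: float = 12.6
    luminance_max: float = 256.0
    luminance_background: float = 129.3

    def __post_init__(self):
        if self.ink_tolerance <= 0 or self.hull_tolerance <= 0:
            raise ValueError("tolerances must be > 0")
        if self.target_ink <= 0 or self.target_hull <= 0:
            raise ValueError("target areas must be > 0")

    @classmethod
    def for_experiment(cls, experiment: int | str) -> "GeometryConfig":
        exp = str(experiment).lstrip("exp") or str(experiment)
        if exp in ("1", "exp1"):
            return cls(experiment="exp1")
        if exp in ("2", "exp2"):
            return cls(
                experiment="exp2",
                connector_width=0.6,
                connector_length_range=(1.6, 2.8),
                target_ink=82.3,
            )
        raise ValueError(f"unknown experiment: {experiment!r}")

    def dot_diameter(self, numerosity: int) -> float:
        if numerosity in self.dot_diameter_by_n:
            return self.dot_diameter_by_n[numerosity]
        # fall back to the nearest configured numerosity (small test layouts)
        nearest = min(self.dot_diameter_by_n, key=lambda k: abs(k - numerosity))
        return self.dot_diameter_by_n[nearest]


@dataclass(frozen=True)
class SpectrumProfile:
    spatial_frequency: np.ndarray  # cycles/degree, strictly increasing
    amplitude: np.ndarray  # arbitrary units, >= 0

    def __post_init__(self):
        f = np.asarray(self.spatial_frequency, float)
        a = np.asarray(self.amplitude, float)
        if not np.all(np.diff(f) > 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(a < -1e-12):
            raise ValueError("amplitudes must be non-negative")


# ---------------------------------------------------------------------------
# placement and pairing


def _sample_in_disc(rng: np.random.Generator, radius: float) -> tuple[float, float]:
    r = radius * math.sqrt(rng.random())
    th = rng.random() * 2 * math.pi
    return r * math.cos(th), r * math.sin(th)


def _inside_field(shape, field_radius: float) -> bool:
    minx, miny, maxx, maxy = shape.bounds
    corners = [(minx, miny), (minx, maxy), (maxx, miny), (maxx, maxy)]
    return all(math.hypot(x, y) <= field_radius for x, y in corners)


def place_items(
    n_dots: int,
    config: GeometryConfig,
    rng_seed: int | np.random.Generator = 0,
    max_attempts: int = 5000,
) -> DotArrayStimulus:
    """Random unconnected layout: ``n_dots`` dots plus ``n_dots/2`` free lines.

    Coordinates are drawn uniformly in a circular field; every item must
    clear every other by at least ``config.min_separation`` and lie inside
    the field.  Raises :class:`PlacementError` when no admissible position
    is found within ``max_attempts`` draws for some item.
    """
    if n_dots % 2:
        raise ValueError("n_dots must be even")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    diam = config.dot_diameter(n_dots)
    lo, hi = config.connector_length_range

    placed_shapes: list = []
    dots: list[Dot] = []
    for k in range(n_dots):
        for _ in range(max_attempts):
            x, y = _sample_in_disc(rng, config.field_radius - diam / 2)
            cand = Dot(x, y, diam)
            sh = cand.shape(quad_segs=16)
            if all(sh.distance(p) >= config.min_separation for p in placed_shapes):
                dots.append(cand)
                placed_shapes.append(sh)
                break
        else:
            raise PlacementError(
                f"could not place dot {k + 1}/{n_dots}: min_separation="
                f"{config.min_separation} deg violated in field_radius={config.field_radius} deg"
            )

    connectors: list[Connector] = []
    for k in range(n_dots // 2):
        for _ in range(max_attempts):
            length = rng.uniform(lo, hi)
            theta = rng.random() * 2 * math.pi
            cx, cy = _sample_in_disc(rng, config.field_radius - length / 2)
            dx, dy = math.cos(theta) * length / 2, math.sin(theta) * length / 2
            cand = Connector(cx - dx, cy - dy, cx + dx, cy + dy, config.connector_width)
            sh = cand.shape()
            if _inside_field(sh, config.field_radius) and all(
                sh.distance(p) >= config.min_separation for p in placed_shapes
            ):
                connectors.append(cand)
                placed_shapes.append(sh)
                break
        else:
            raise PlacementError(
                f"could not place line {k + 1}/{n_dots // 2}: min_separation="
                f"{config.min_separation} deg violated in field_radius={config.field_radius} deg"
            )

    return DotArrayStimulus(
        dots=tuple(dots),
        connectors=tuple(connectors),
        connectedness="isolated-displaced",
        experiment=config.experiment,
    )


def _edge_connector(a: Dot, b: Dot, width: float) -> Connector:
    """Rectangle spanning the gap between the two dot boundaries."""
    dx, dy = b.center_x - a.center_x, b.center_y - a.center_y
    d = math.hypot(dx, dy)
    ux, uy = dx / d, dy / d
    return Connector(
        a.center_x + ux * a.radius,
        a.center_y + uy * a.radius,
        b.center_x - ux * b.radius,
        b.center_y - uy * b.radius,
        width,
    )


def connect_pairs(
    layout: DotArrayStimulus,
    rng_seed: int | np.random.Generator = 0,
    config: GeometryConfig | None = None,
    move_dots: bool = True,
    max_attempts: int = 2000,
) -> DotArrayStimulus:
    """Join randomly chosen couples of dots into dumbbells.

    With ``move_dots=True`` (default) the second dot of each couple is
    relocated next to its partner so the connecting line's length falls in
    the configured range; with ``move_dots=False`` dots stay put and a
    pairing with admissible gaps must already exist, else
    :class:`PairingError`.
    """
    if layout.numerosity % 2:
        raise ValueError("numerosity must be even")
    config = config or GeometryConfig.for_experiment(layout.experiment)
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    lo, hi = config.connector_length_range
    w = config.connector_width
    dots = list(layout.dots)
    order = list(rng.permutation(len(dots)))

    if not move_dots:
        # greedy search over random pairing orders for gaps within [lo, hi]
        for _ in range(200):
            perm = list(rng.permutation(len(dots)))
            pairs: list[tuple[int, int]] = []
            free = perm.copy()
            ok = True
            while free:
                i = free.pop(0)
                match = None
                for j in free:
                    gap = (
                        math.hypot(dots[i].center_x - dots[j].center_x,
                                   dots[i].center_y - dots[j].center_y)
                        - dots[i].radius - dots[j].radius
                    )
                    if lo <= gap <= hi:
                        match = j
                        break
                if match is None:
                    ok = False
                    break
                free.remove(match)
                pairs.append((i, match))
            if ok:
                connectors = tuple(
                    _edge_connector(dots[i], dots[j], w) for i, j in pairs
                )
                return DotArrayStimulus(
                    dots=tuple(dots), connectors=connectors, connectedness="connected",
                    polarity=layout.polarity, experiment=layout.experiment,
                    pairs=tuple(pairs),
                )
        raise PairingError(
            f"no dot pairing with gaps in [{lo}, {hi}] deg exists for the fixed layout"
        )

    new_dots: dict[int, Dot] = {}
    placed_items: list = []
    pairs = []
    connectors = []
    for k in range(0, len(order), 2):
        i, j = order[k], order[k + 1]
        a = dots[i]
        for attempt in range(max_attempts):
            if attempt >= max_attempts // 2 and attempt % 50 == 0:
                # anchor unplaceable: relocate the whole dumbbell
                x, y = _sample_in_disc(rng, config.field_radius - a.radius)
                a = Dot(x, y, a.diameter)
            length = rng.uniform(lo, hi)
            theta = rng.random() * 2 * math.pi
            d = a.radius + dots[j].radius + length
            b = Dot(a.center_x + d * math.cos(theta), a.center_y + d * math.sin(theta),
                    dots[j].diameter)
            conn = _edge_connector(a, b, w)
            item = unary_union([a.shape(quad_segs=16), b.shape(quad_segs=16), conn.shape()])
            if _inside_field(b.shape(quad_segs=4), config.field_radius) and all(
                item.distance(p) >= config.min_separation for p in placed_items
            ):
                new_dots[i], new_dots[j] = a, b
                placed_items.append(item)
                pairs.append((i, j))
                connectors.append(conn)
                break
        else:
            raise PlacementError("could not place dumbbell under separation constraint")

    out_dots = tuple(new_dots[idx] for idx in sorted(new_dots))
    index_map = {old: new for new, old in enumerate(sorted(new_dots))}
    pairs = tuple((index_map[i], index_map[j]) for i, j in pairs)
    return DotArrayStimulus(
        dots=out_dots, connectors=tuple(connectors), connectedness="connected",
        polarity=layout.polarity, experiment=layout.experiment, pairs=pairs,
    )


def isolate_by_displacement(
    connected: DotArrayStimulus,
    rng_seed: int | np.random.Generator = 0,
    config: GeometryConfig | None = None,
    max_attempts: int = 5000,
) -> DotArrayStimulus:
    """Experiment-1 isolated condition: same dots, lines displaced to random
    free positions (clearance >= min_separation from everything)."""
    if connected.connectedness != "connected" and connected.connectors:
        raise ValueError("input must be a connected stimulus")
    if not connected.connectors:
        return replace(connected, connectedness="isolated-displaced", pairs=())
    config = config or GeometryConfig.for_experiment(connected.experiment)
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed

    placed = [d.shape(quad_segs=16) for d in connected.dots]
    new_conns: list[Connector] = []
    for k, c in enumerate(connected.connectors):
        length = c.length
        for _ in range(max_attempts):
            theta = rng.random() * 2 * math.pi
            cx, cy = _sample_in_disc(rng, config.field_radius - length / 2)
            dx, dy = math.cos(theta) * length / 2, math.sin(theta) * length / 2
            cand = Connector(cx - dx, cy - dy, cx + dx, cy + dy, c.width)
            sh = cand.shape()
            if _inside_field(sh, config.field_radius) and all(
                sh.distance(p) >= config.min_separation for p in placed
            ):
                new_conns.append(cand)
                placed.append(sh)
                break
        else:
            raise PlacementError(f"could not displace line {k + 1} under separation constraint")

    return DotArrayStimulus(
        dots=connected.dots, connectors=tuple(new_conns),
        connectedness="isolated-displaced", polarity=connected.polarity,
        experiment=connected.experiment,
    )


def isolate_by_removal(
    connected: DotArrayStimulus,
    config: GeometryConfig | None = None,
) -> DotArrayStimulus:
    """Experiment-2 isolated condition: lines removed, dots uniformly enlarged
    so total ink matches the connected stimulus."""
    if connected.connectedness != "connected" and connected.connectors:
        raise ValueError("input must be a connected stimulus")
    target = ink_area(connected)
    n = connected.numerosity
    new_diam = 2.0 * math.sqrt(target / (n * math.pi))
    old_diam = connected.dots[0].diameter
    if new_diam <= old_diam:  # nothing to absorb (e.g. zero-ink connectors)
        new_diam = old_diam
    dots = tuple(Dot(d.center_x, d.center_y, new_diam) for d in connected.dots)
    out = DotArrayStimulus(
        dots=dots, connectors=(), connectedness="isolated-removed",
        polarity=connected.polarity, experiment=connected.experiment,
    )
    cfg = config or GeometryConfig.for_experiment(connected.experiment)
    return _repair_separation(out, cfg)


# ---------------------------------------------------------------------------
# measurement


def ink_area(stimulus: DotArrayStimulus) -> float:
    """Exact union area (deg^2) of all dots and connectors; overlap counted once."""
    return unary_union(stimulus.shapes()).area


def _support_points(stimulus: DotArrayStimulus, n_boundary: int = 64) -> np.ndarray:
    """Outer ink extents: sampled dot boundaries plus connector corners."""
    pts = []
    th = np.linspace(0, 2 * np.pi, n_boundary, endpoint=False)
    for d in stimulus.dots:
        pts.append(np.column_stack([d.center_x + d.radius * np.cos(th),
                                    d.center_y + d.radius * np.sin(th)]))
    for c in stimulus.connectors:
        pts.append(np.asarray(c.shape().exterior.coords))
    return np.vstack(pts) if pts else np.empty((0, 2))


def convex_hull_area(stimulus: DotArrayStimulus) -> float:
    """Area (deg^2) of the convex hull of the outer ink extents."""
    from scipy.spatial import ConvexHull, QhullError

    pts = _support_points(stimulus)
    if len(pts) < 3:
        raise ValueError("need at least 3 support points")
    try:
        hull = ConvexHull(pts)
    except QhullError as exc:
        raise ValueError("degenerate (collinear) stimulus: hull has zero area") from exc
    area = float(hull.volume)  # 2-D: volume is the area
    if area < 1e-9:
        raise ValueError("degenerate (collinear) stimulus: hull has zero area")
    return area


def rasterize(
    stimulus: DotArrayStimulus,
    config: GeometryConfig,
    extent: float | None = None,
) -> tuple[np.ndarray, float]:
    """Render a square luminance image (cd/m^2) and measure the raster ink area.

    Ink pixels take the polarity's luminance (white=max, black=min) on the
    gray background; the ink area is the union pixel count / ppd^2, so
    overlapping items are never double-counted.
    """
    ppd = config.pixels_per_degree
    if ppd <= 0:
        raise ValueError("pixels_per_degree must be > 0")
    if extent is None:
        extent = config.field_radius * 1.4 + 2.0
    n = int(round(2 * extent * ppd))
    # pixel centers
    coords = (np.arange(n) + 0.5) / ppd - extent
    X, Y = np.meshgrid(coords, coords)
    mask = np.zeros((n, n), dtype=bool)
    for d in stimulus.dots:
        mask |= (X - d.center_x) ** 2 + (Y - d.center_y) ** 2 <= d.radius**2
    for c in stimulus.connectors:
        dx, dy = c.x2 - c.x1, c.y2 - c.y1
        L = c.length
        ux, uy = dx / L, dy / L
        relx, rely = X - c.center[0], Y - c.center[1]
        u = relx * ux + rely * uy
        v = -relx * uy + rely * ux
        mask |= (np.abs(u) <= L / 2) & (np.abs(v) <= c.width / 2)
    ink_level = config.luminance_max if stimulus.polarity == "white" else config.luminance_min
    img = np.full((n, n), config.luminance_background, dtype=float)
    img[mask] = ink_level
    return img, float(mask.sum()) / ppd**2


def radial_fourier_amplitude(
    image: np.ndarray,
    config: GeometryConfig,
    f_min: float = 0.3,
    f_max: float = 10.0,
    bin_width: float = 0.1,
) -> SpectrumProfile:
    """Radially averaged 2-D Fourier amplitude over 0.3-10 cycles/degree.

    The background luminance is subtracted before the transform; amplitudes
    are in arbitrary units (profile shape, not absolute level, is the
    contract).
    """
    img = np.asarray(image, float)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("image must be square")
    amp = np.abs(np.fft.fftshift(np.fft.fft2(img - config.luminance_background)))
    n = img.shape[0]
    f1 = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / config.pixels_per_degree))
    FX, FY = np.meshgrid(f1, f1)
    fr = np.hypot(FX, FY).ravel()
    a = amp.ravel()
    edges = np.arange(f_min, f_max + bin_width, bin_width)
    idx = np.digitize(fr, edges) - 1
    nbin = len(edges) - 1
    sums = np.bincount(idx[(idx >= 0) & (idx < nbin)],
                       weights=a[(idx >= 0) & (idx < nbin)], minlength=nbin)
    counts = np.bincount(idx[(idx >= 0) & (idx < nbin)], minlength=nbin)
    with np.errstate(invalid="ignore"):
        prof = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    centers = edges[:-1] + bin_width / 2
    keep = counts > 0
    return SpectrumProfile(spatial_frequency=centers[keep], amplitude=prof[keep])


# ---------------------------------------------------------------------------
# iterative ink / hull matching


def _min_item_clearance(stimulus: DotArrayStimulus) -> float:
    items = stimulus.items()
    best = math.inf
    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            best = min(best, items[i].distance(items[j]))
    return best


def _item_centers(stimulus: DotArrayStimulus) -> list[tuple[str, int, float, float]]:
    """(kind, index, cx, cy) per separation item."""
    out = []
    if stimulus.connectedness == "connected":
        for k, (i, j) in enumerate(stimulus.pairs):
            a, b = stimulus.dots[i], stimulus.dots[j]
            out.append(("pair", k, (a.center_x + b.center_x) / 2, (a.center_y + b.center_y) / 2))
    else:
        for i, d in enumerate(stimulus.dots):
            out.append(("dot", i, d.center_x, d.center_y))
        for k, c in enumerate(stimulus.connectors):
            out.append(("line", k, *c.center))
    return out


def _apply_centers(stimulus: DotArrayStimulus, centers: dict) -> DotArrayStimulus:
    """Rebuild the stimulus with items translated to new centers."""
    dots = list(stimulus.dots)
    conns = list(stimulus.connectors)
    if stimulus.connectedness == "connected":
        for k, (i, j) in enumerate(stimulus.pairs):
            a, b = dots[i], dots[j]
            ocx, ocy = (a.center_x + b.center_x) / 2, (a.center_y + b.center_y) / 2
            ncx, ncy = centers[("pair", k)]
            dx, dy = ncx - ocx, ncy - ocy
            dots[i] = Dot(a.center_x + dx, a.center_y + dy, a.diameter)
            dots[j] = Dot(b.center_x + dx, b.center_y + dy, b.diameter)
            conns[k] = _edge_connector(dots[i], dots[j], conns[k].width)
    else:
        for i, d in enumerate(dots):
            ncx, ncy = centers[("dot", i)]
            dots[i] = Dot(ncx, ncy, d.diameter)
        for k, c in enumerate(conns):
            ncx, ncy = centers[("line", k)]
            dx, dy = ncx - c.center[0], ncy - c.center[1]
            conns[k] = Connector(c.x1 + dx, c.y1 + dy, c.x2 + dx, c.y2 + dy, c.width)
    return replace(stimulus, dots=tuple(dots), connectors=tuple(conns))


def _scale_positions(stimulus: DotArrayStimulus, s: float) -> DotArrayStimulus:
    cents = _item_centers(stimulus)
    cx0 = float(np.mean([c[2] for c in cents]))
    cy0 = float(np.mean([c[3] for c in cents]))
    new = {(k, i): (cx0 + s * (x - cx0), cy0 + s * (y - cy0)) for k, i, x, y in cents}
    return _apply_centers(stimulus, new)


def _repair_separation(
    stimulus: DotArrayStimulus, config: GeometryConfig, rounds: int = 50
) -> DotArrayStimulus:
    """Push violating item pairs apart until min_separation holds."""
    stim = stimulus
    for _ in range(rounds):
        items = stim.items()
        cents = _item_centers(stim)
        moved = False
        new = {(k, i): (x, y) for k, i, x, y in cents}
        for a in range(len(items)):
            for b in range(a + 1, len(items)):
                dist = items[a].distance(items[b])
                if dist < config.min_separation:
                    deficit = config.min_separation - dist + 0.02
                    ka, ia, xa, ya = cents[a]
                    kb, ib, xb, yb = cents[b]
                    dx, dy = xb - xa, yb - ya
                    norm = math.hypot(dx, dy) or 1.0
                    ux, uy = dx / norm, dy / norm
                    new[(ka, ia)] = (new[(ka, ia)][0] - ux * deficit / 2,
                                     new[(ka, ia)][1] - uy * deficit / 2)
                    new[(kb, ib)] = (new[(kb, ib)][0] + ux * deficit / 2,
                                     new[(kb, ib)][1] + uy * deficit / 2)
                    moved = True
        if not moved:
            return stim
        stim = _apply_centers(stim, new)
    raise MatchingError("could not restore min_separation after position adjustment")


def _adjust_ink(stimulus: DotArrayStimulus, target: float, config: GeometryConfig) -> DotArrayStimulus:
    """Move ink toward target with the condition's knob."""
    current = ink_area(stimulus)
    delta = target - current
    if stimulus.connectedness == "isolated-removed" or not stimulus.connectors:
        # dot diameter absorbs the residual (dots do not overlap)
        n = stimulus.numerosity
        area_per = max(current + delta, 1e-6) / n
        new_diam = 2.0 * math.sqrt(area_per / math.pi)
        dots = tuple(Dot(d.center_x, d.center_y, new_diam) for d in stimulus.dots)
        return replace(stimulus, dots=dots)
    w = stimulus.connectors[0].width
    d_len = delta / (len(stimulus.connectors) * w)
    if stimulus.connectedness == "connected":
        # lengthen the gap: move dot b of each pair outward along the axis
        dots = list(stimulus.dots)
        conns = list(stimulus.connectors)
        for k, (i, j) in enumerate(stimulus.pairs):
            a, b = dots[i], dots[j]
            dx, dy = b.center_x - a.center_x, b.center_y - a.center_y
            norm = math.hypot(dx, dy)
            ux, uy = dx / norm, dy / norm
            dots[j] = Dot(b.center_x + ux * d_len, b.center_y + uy * d_len, b.diameter)
            conns[k] = _edge_connector(dots[i], dots[j], conns[k].width)
        return replace(stimulus, dots=tuple(dots), connectors=tuple(conns))
    # displaced lines: stretch each line about its center
    conns = []
    for c in stimulus.connectors:
        L = c.length
        newL = max(L + d_len, 0.2)
        cx, cy = c.center
        ux, uy = (c.x2 - c.x1) / L, (c.y2 - c.y1) / L
        conns.append(Connector(cx - ux * newL / 2, cy - uy * newL / 2,
                               cx + ux * newL / 2, cy + uy * newL / 2, c.width))
    return replace(stimulus, connectors=tuple(conns))


def match_constraints(
    stimulus: DotArrayStimulus,
    reference: DotArrayStimulus | None,
    config: GeometryConfig,
) -> DotArrayStimulus:
    """Iteratively adjust a stimulus until its ink and convex hull match the
    reference (or the configured targets when ``reference`` is None).

    Alternates an ink step (line length for displaced/connected stimuli, dot
    diameter for removed-line stimuli) with a hull step (radial scaling of
    item positions about the array centroid), repairing any separation
    violations, until both relative residuals fall below the configured
    tolerances.  Raises :class:`MatchingError` with the residuals on
    non-convergence.
    """
    target_ink = ink_area(reference) if reference is not None else config.target_ink
    target_hull = convex_hull_area(reference) if reference is not None else config.target_hull
    if reference is not None and (
        reference.numerosity != stimulus.numerosity or reference.experiment != stimulus.experiment
    ):
        raise ValueError("stimulus and reference must share numerosity and experiment")

    stim = stimulus
    ink_res = hull_res = math.inf
    for _ in range(config.max_iterations):
        ink = ink_area(stim)
        hull = convex_hull_area(stim)
        ink_res = abs(ink - target_ink) / target_ink
        hull_res = abs(hull - target_hull) / target_hull
        if ink_res <= config.ink_tolerance and hull_res <= config.hull_tolerance:
            return stim
        if ink_res > config.ink_tolerance:
            stim = _adjust_ink(stim, target_ink, config)
            stim = _repair_separation(stim, config)
        hull = convex_hull_area(stim)
        hull_res = abs(hull - target_hull) / target_hull
        if hull_res > config.hull_tolerance:
            s = math.sqrt(target_hull / hull)
            stim = _scale_positions(stim, 1.0 + 0.8 * (s - 1.0))
            stim = _repair_separation(stim, config)
    raise MatchingError(
        f"no convergence after {config.max_iterations} iterations: "
        f"ink residual {ink_res:.4f}, hull residual {hull_res:.4f}"
    )


def generate_condition_set(
    config: GeometryConfig,
    rng_seed: int = 0,
    numerosities: Sequence[int] = (18, 24),
    polarity: Literal["black", "white"] = "white",
) -> dict[tuple[int, str], DotArrayStimulus]:
    """One full constraint-matched condition set for an experiment.

    Returns the four cells {(18, connected), (18, isolated), (24, connected),
    (24, isolated)} with ink matched to ``config.target_ink`` and hull to
    ``config.target_hull``, all within the configured tolerances.
    """
    rng = np.random.default_rng(rng_seed)
    out: dict[tuple[int, str], DotArrayStimulus] = {}
    for n in numerosities:
        layout = place_items(n, config, rng)
        connected = connect_pairs(layout, rng, config)
        connected = match_constraints(connected, None, config)
        if config.experiment == "exp1":
            isolated = isolate_by_displacement(connected, rng, config)
        else:
            isolated = isolate_by_removal(connected, config)
        isolated = match_constraints(isolated, None, config)
        out[(n, "connected")] = replace(connected, polarity=polarity)
        out[(n, "isolated")] = replace(isolated, polarity=polarity)
    return out
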