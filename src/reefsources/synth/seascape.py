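"""Synthetic reef seascapes.

A seascape is a planar Cartesian domain (km) holding convex reef polygons
arranged in shelf-parallel bands (inner / mid / outer) and partitioned
alongshore into management regions.  The alongshore axis is x (the jet in
the companion current generator flows toward +x), the cross-shelf axis is
y (the outer band sits at high y, where oceanic inflow enters).

In *planted* mode a designed cluster of outer-band reefs is placed at the
upstream edge of the domain, staggered across the jet and kept clear of
all other reefs.  By construction these reefs supply long downstream
chains while receiving almost nothing themselves, and the climate
generator can carve thermal-refuge holes around them -- so the planted set
satisfies all three robust-source criteria by design and recovery can be
measured.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Point, Polygon

__all__ = [
    "Reef",
    "Seascape",
    "SeascapeConfig",
    "PlantedConfig",
    "PlantedTruth",
    "build_reefs",
]

BAND_NAMES = ("inner", "mid", "outer")


class ConfigError(ValueError):
    """Invalid generator or pipeline configuration."""


@dataclass(frozen=True)
class Reef:
    """One convex reef polygon with its management metadata."""

    id: str
    polygon: Polygon
    region: int
    band: str
    no_take: bool = False

    @property
    def area(self) -> float:
        return self.polygon.area

    @property
    def centroid(self) -> tuple[float, float]:
        c = self.polygon.centroid
        return (c.x, c.y)


@dataclass
class Seascape:
    """Reef polygons plus the planar domain they live in.

    domain is (xmin, ymin, xmax, ymax) in km; grid_spacing is the raster
    resolution (km) used by the velocity field built on top of it.
    """

    reefs: list[Reef]
    domain: tuple[float, float, float, float]
    grid_spacing: float

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reefs]
        if len(set(ids)) != len(ids):
            raise ValueError("reef ids must be unique")

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.reefs]

    @property
    def regions(self) -> dict[str, int]:
        return {r.id: r.region for r in self.reefs}

    @property
    def polygons(self) -> list[Polygon]:
        return [r.polygon for r in self.reefs]

    def reef(self, reef_id: str) -> Reef:
        for r in self.reefs:
            if r.id == reef_id:
                return r
        raise KeyError(reef_id)

    def strtree(self) -> shapely.STRtree:
        return shapely.STRtree(self.polygons)


@dataclass(frozen=True)
class PlantedConfig:
    """Parameters of the planted ground-truth mode."""

    n_planted: int = 8
    #: radius (km) of the thermal-refuge hole carved around each planted reef
    refuge_radius_km: float = 8.0
    #: minimum distance (km) from any planted centroid to any other reef
    clearance_km: float = 11.0
    #: larval-supply percentile the survey generator plants the outbreak link at
    supply_percentile: float = 30.0


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded by the generators in planted mode."""

    robust_ids: frozenset[str]
    supply_percentile: float
    tweedie_power: float
    tweedie_dispersion: float
    mean_link: tuple[float, float]  # (intercept, slope/contrast) of the log mean

    def __post_init__(self) -> None:
        if not self.robust_ids:
            raise ValueError("planted robust set must be non-empty")
        if not 1.0 < self.tweedie_power < 2.0:
            raise ValueError("Tweedie power must lie in (1, 2)")
        if self.tweedie_dispersion <= 0:
            raise ValueError("Tweedie dispersion must be positive")


@dataclass(frozen=True)
class SeascapeConfig:
    n_reefs: int = 50
    domain: tuple[float, float, float, float] = (0.0, 0.0, 320.0, 120.0)
    n_regions: int = 3
    mean_reef_area_km2: float = 3.0
    grid_spacing_km: float = 4.0
    #: fraction of reefs per shelf band, (inner, mid, outer)
    band_fractions: tuple[float, float, float] = (0.25, 0.35, 0.40)
    #: cross-shelf centre of each band as a fraction of domain height
    band_positions: tuple[float, float, float] = (0.20, 0.50, 0.80)
    #: half-width of each band (fraction of domain height) for jitter
    band_halfwidth: float = 0.06
    no_take_fraction: float = 0.27
    n_vertices: int = 8
    planted: PlantedConfig | None = None

    def validate(self) -> None:
        xmin, ymin, xmax, ymax = self.domain
        if self.n_reefs < 1:
            raise ConfigError("n_reefs must be >= 1")
        if self.n_regions < 1:
            raise ConfigError("n_regions must be >= 1")
        if xmax <= xmin or ymax <= ymin:
            raise ConfigError("domain must have positive extent")
        if self.mean_reef_area_km2 <= 0:
            raise ConfigError("mean_reef_area_km2 must be positive")
        if abs(sum(self.band_fractions) - 1.0) > 1e-9:
            raise ConfigError("band_fractions must sum to 1")


def _convex_reef(rng: np.random.Generator, cx: float, cy: float,
                 mean_area: float, n_vertices: int) -> Polygon:
    """Convex polygon around (cx, cy) with area of order mean_area.

    Vertices are sampled on a radius-jittered ellipse and closed with a
    convex hull, which guarantees convexity for any jitter.
    """
    r0 = np.sqrt(mean_area / np.pi) * rng.uniform(0.85, 1.15)
    aspect = rng.uniform(0.6, 1.0)
    theta0 = rng.uniform(0, 2 * np.pi)
    ang = np.sort(rng.uniform(0, 2 * np.pi, size=n_vertices))
    rad = r0 * rng.uniform(0.75, 1.25, size=n_vertices)
    ex = rad * np.cos(ang)
    ey = rad * np.sin(ang) * aspect
    # rotate by theta0
    xs = cx + ex * np.cos(theta0) - ey * np.sin(theta0)
    ys = cy + ex * np.sin(theta0) + ey * np.cos(theta0)
    hull = Polygon(zip(xs, ys)).convex_hull
    if not isinstance(hull, Polygon) or hull.area <= 0:  # degenerate jitter draw
        hull = Point(cx, cy).buffer(r0, quad_segs=2)
    return hull


def _band_centres(config: SeascapeConfig, rng: np.random.Generator
                  ) -> list[tuple[float, float, str]]:
    """Jittered (x, y, band) centres along the three shelf bands."""
    xmin, ymin, xmax, ymax = config.domain
    height = ymax - ymin
    width = xmax - xmin
    counts = np.floor(np.asarray(config.band_fractions) * config.n_reefs).astype(int)
    # distribute the remainder to the largest bands
    for i in np.argsort(counts)[::-1][: config.n_reefs - counts.sum()]:
        counts[i] += 1
    centres: list[tuple[float, float, str]] = []
    margin = 0.04 * width
    for band, count, pos in zip(BAND_NAMES, counts, config.band_positions):
        if count == 0:
            continue
        slots = np.linspace(xmin + margin, xmax - margin, count)
        dx = (slots[1] - slots[0]) if count > 1 else width
        xs = slots + rng.uniform(-0.25, 0.25, size=count) * min(dx, 20.0)
        ys = ymin + height * (pos + rng.uniform(-1, 1, size=count) * config.band_halfwidth)
        centres.extend((x, y, band) for x, y in zip(xs, ys))
    return centres


def build_reefs(config: SeascapeConfig, seed: int) -> tuple[Seascape, PlantedTruth | None]:
    """Generate a seeded synthetic seascape.

    Returns the seascape and, in planted mode, the recorded ground truth
    (otherwise None).  Deterministic for a fixed (config, seed).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = config.domain
    width = xmax - xmin

    centres = _band_centres(config, rng)

    planted_centres: list[tuple[float, float]] = []
    if config.planted is not None:
        pc = config.planted
        # Planted reefs: a cross-shelf staggered line at the upstream (low-x)
        # edge of the outer band, inside the jet core.
        # staggered against the flow drift: x increases with y while the
        # jet+inflow plume descends in y, so no planted reef supplies another
        x0 = xmin + 0.03 * width
        ys = np.linspace(0.82, 0.93, pc.n_planted) * (ymax - ymin) + ymin
        xs = x0 + np.linspace(0.0, 0.09 * width, pc.n_planted)
        planted_centres = list(zip(xs, ys))
        # enforce clearance: drop ordinary centres too close to planted reefs
        kept = []
        for (x, y, band) in centres:
            d2 = min((x - px) ** 2 + (y - py) ** 2 for px, py in planted_centres)
            if d2 >= pc.clearance_km**2:
                kept.append((x, y, band))
        centres = kept

    reefs: list[Reef] = []
    region_edges = np.linspace(xmin, xmax, config.n_regions + 1)

    def region_of(x: float) -> int:
        return int(min(np.searchsorted(region_edges, x, side="right") - 1,
                       config.n_regions - 1))

    all_centres = [(x, y, band, False) for x, y, band in centres]
    all_centres += [(x, y, "outer", True) for x, y in planted_centres]
    # sort by x then y for stable ids independent of construction order
    all_centres.sort(key=lambda c: (c[0], c[1]))

    occupied: list[Polygon] = []
    planted_ids: set[str] = set()
    idx = 0
    for (x, y, band, is_planted) in all_centres:
        poly = _convex_reef(rng, x, y, config.mean_reef_area_km2, config.n_vertices)
        # resolve overlaps by shrinking toward the centre (rare at default spacing)
        tries = 0
        while occupied and shapely.STRtree(occupied).query(poly, "intersects").size and tries < 8:
            poly = shapely.affinity.scale(poly, 0.7, 0.7, origin=(x, y))
            tries += 1
        if tries >= 8:
            continue  # unplaceable centre; skip rather than overlap
        rid = f"R{idx:03d}"
        idx += 1
        occupied.append(poly)
        reefs.append(Reef(id=rid, polygon=poly, region=region_of(x), band=band,
                          no_take=bool(rng.random() < config.no_take_fraction)))
        if is_planted:
            planted_ids.add(rid)

    truth = None
    if config.planted is not None:
        truth = PlantedTruth(
            robust_ids=frozenset(planted_ids),
            supply_percentile=config.planted.supply_percentile,
            tweedie_power=1.6,
            tweedie_dispersion=3.58,
            mean_link=(float(np.log(40.0)), float(np.log(3200.0 / 40.0))),
        )
    scape = Seascape(reefs=reefs, domain=config.domain,
                     grid_spacing=config.grid_spacing_km)
    return scape, truth


def planted_centroids(seascape: Seascape, truth: PlantedTruth) -> list[tuple[float, float]]:
    """Centroids of the planted robust reefs (used by the climate generator)."""
    return [r.centroid for r in seascape.reefs if r.id in truth.robust_ids]
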