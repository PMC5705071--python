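"""Synthetic weekly sea-surface temperature records.

The cube emulates a multi-decadal satellite SST record over the seascape:
a seasonal climatological cycle with a weak cross-shelf gradient, bounded
weekly weather noise, and *planted warming events* -- summers in which a
spatial hotspot footprint is pushed several degrees above the
climatological maximum for several consecutive weeks, so the downstream
degree-heating-week machinery has real events to find.

The noise amplitude is kept strictly below the 1 deg C hotspot threshold
used by the DHW accumulation, so in non-event years every pixel
accumulates exactly zero thermal stress and the significant-event
detector recovers the planted years, and only those.

In planted-truth mode the event footprint excludes circular refuge holes
around the planted robust reefs, making exactly those reefs thermal
refugia.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from reefsources.synth.seascape import ConfigError, Seascape

__all__ = ["ClimateConfig", "ThermalEvent", "SSTCube", "build_sst"]

WEEKS_PER_YEAR = 52


@dataclass(frozen=True)
class ThermalEvent:
    """One planted warming event."""

    year: int                 # 0-based year index within the record
    intensity: float = 3.0    # deg C added on top of climatology
    n_weeks: int = 4          # consecutive weeks at the seasonal peak
    #: (x, y, radius) km circles excluded from the hotspot footprint
    refuge_holes: tuple[tuple[float, float, float], ...] = ()


@dataclass(frozen=True)
class ClimateConfig:
    n_years: int = 36
    pixel_spacing_km: float = 2.0
    mean_sst: float = 26.0           # deg C annual mean at the coast
    seasonal_amplitude: float = 2.5  # deg C
    #: deg C change across the full domain height (cooler offshore)
    cross_shelf_gradient: float = -0.8
    #: uniform weekly noise half-width; must stay < 1 so that non-event
    #: years never cross the DHW hotspot threshold
    noise_amplitude: float = 0.6
    peak_week: int = 5               # austral summer peak within the year
    events: tuple[ThermalEvent, ...] = ()

    def validate(self) -> None:
        if self.n_years < 1:
            raise ConfigError("record must span at least one year")
        if not 0 <= self.noise_amplitude < 1.0:
            raise ConfigError("noise amplitude must lie in [0, 1) deg C")
        for ev in self.events:
            if not 0 <= ev.year < self.n_years:
                raise ConfigError(f"planted event year {ev.year} outside record")


@dataclass
class SSTCube:
    """Weekly SST on a pixel grid with a pixel->reef mapping.

    values has shape (n_weeks, ny, nx); mmm is the per-pixel maximum of
    the climatological cycle (the baseline hotspots are measured against);
    reef_pixels maps reef id -> array of flat pixel indices.
    """

    x: np.ndarray
    y: np.ndarray
    year: np.ndarray        # (n_weeks,) 0-based year index
    week: np.ndarray        # (n_weeks,) week-of-year 0..51
    values: np.ndarray      # (n_weeks, ny, nx) deg C
    mmm: np.ndarray         # (ny, nx) deg C
    reef_pixels: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if np.isnan(self.values).any():
            raise ValueError("SST cube must not contain missing values")
        for rid, px in self.reef_pixels.items():
            if len(px) == 0:
                raise ValueError(f"reef {rid} has no SST pixels")

    @property
    def n_pixels(self) -> int:
        return self.values.shape[1] * self.values.shape[2]

    def flat_values(self) -> np.ndarray:
        """(n_weeks, n_pixels) view of the cube."""
        return self.values.reshape(self.values.shape[0], -1)

    def to_xarray(self) -> xr.Dataset:
        npx = self.n_pixels
        owner = np.full(npx, "", dtype=object)
        for rid, px in self.reef_pixels.items():
            owner[px] = rid
        ds = xr.Dataset(
            {
                "sst": (("week_index", "y", "x"), self.values, {"units": "degC"}),
                "mmm": (("y", "x"), self.mmm, {"units": "degC"}),
                "reef_id": (("pixel",), owner.astype(str)),
            },
            coords={
                "x": ("x", self.x, {"units": "km"}),
                "y": ("y", self.y, {"units": "km"}),
                "year": ("week_index", self.year),
                "week": ("week_index", self.week),
                "pixel": ("pixel", np.arange(npx)),
            },
        )
        return ds

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "SSTCube":
        owner = np.asarray(ds["reef_id"].values, dtype=str)
        reef_pixels: dict[str, np.ndarray] = {}
        for rid in np.unique(owner):
            if rid:
                reef_pixels[str(rid)] = np.flatnonzero(owner == rid)
        return cls(x=ds["x"].values.astype(float), y=ds["y"].values.astype(float),
                   year=ds["year"].values.astype(int),
                   week=ds["week"].values.astype(int),
                   values=ds["sst"].values.astype(float),
                   mmm=ds["mmm"].values.astype(float),
                   reef_pixels=reef_pixels)


def _map_reef_pixels(seascape: Seascape, x: np.ndarray, y: np.ndarray
                     ) -> dict[str, np.ndarray]:
    """Assign pixels whose centres fall inside each reef polygon; reefs
    smaller than a pixel get the pixel nearest their centroid."""
    import shapely
    X, Y = np.meshgrid(x, y)
    pts = shapely.points(X.ravel(), Y.ravel())
    taken: dict[str, list[int]] = {}
    tree = shapely.STRtree(pts)
    for reef in seascape.reefs:
        inside = tree.query(reef.polygon, predicate="contains")
        if inside.size == 0:
            cx, cy = reef.centroid
            d2 = (X.ravel() - cx) ** 2 + (Y.ravel() - cy) ** 2
            inside = np.array([int(np.argmin(d2))])
        taken[reef.id] = sorted(int(i) for i in inside)
    # a pixel may sit inside at most one reef (polygons do not overlap);
    # nearest-centroid fallbacks could collide, keep first-come ownership
    seen: set[int] = set()
    out: dict[str, np.ndarray] = {}
    for rid, px in taken.items():
        keep = [i for i in px if i not in seen] or px[:1]
        seen.update(keep)
        out[rid] = np.asarray(keep, dtype=np.intp)
    return out


def build_sst(seascape: Seascape, config: ClimateConfig, seed: int) -> SSTCube:
    """Generate the weekly SST cube with planted warming events."""
    config.validate()
    rng = np.random.default_rng(seed)
    h = config.pixel_spacing_km
    xmin, ymin, xmax, ymax = seascape.domain
    x = np.arange(xmin + h / 2, xmax, h)
    y = np.arange(ymin + h / 2, ymax, h)
    ny, nx = y.size, x.size
    n_weeks = config.n_years * WEEKS_PER_YEAR
    week = np.tile(np.arange(WEEKS_PER_YEAR), config.n_years)
    year = np.repeat(np.arange(config.n_years), WEEKS_PER_YEAR)

    # climatology: seasonal cosine + linear cross-shelf gradient
    shelf = (y - ymin) / (ymax - ymin)
    spatial = config.mean_sst + config.cross_shelf_gradient * shelf[:, None]
    spatial = np.broadcast_to(spatial, (ny, nx))
    seasonal = config.seasonal_amplitude * np.cos(
        2 * np.pi * (np.arange(WEEKS_PER_YEAR) - config.peak_week) / WEEKS_PER_YEAR)
    mmm = spatial + seasonal.max()

    values = spatial[None, :, :] + seasonal[week][:, None, None]
    if config.noise_amplitude > 0:
        values = values + rng.uniform(-config.noise_amplitude,
                                      config.noise_amplitude,
                                      size=(n_weeks, ny, nx))

    # events plant a uniform *hotspot* of +intensity relative to MMM (the
    # baseline hotspots are measured against), so a noise-free event of
    # intensity I over n weeks accumulates exactly n * I degC-weeks
    X, Y = np.meshgrid(x, y)
    for ev in config.events:
        mask = np.ones((ny, nx), dtype=bool)
        for (hx, hy, hr) in ev.refuge_holes:
            mask &= (X - hx) ** 2 + (Y - hy) ** 2 > hr**2
        wk0 = ev.year * WEEKS_PER_YEAR + config.peak_week
        for w in range(wk0, min(wk0 + ev.n_weeks, n_weeks)):
            noise = values[w] - (spatial + seasonal[week[w]])
            values[w][mask] = (mmm + ev.intensity + noise)[mask]

    reef_pixels = _map_reef_pixels(seascape, x, y)
    return SSTCube(x=x, y=y, year=year, week=week, values=values,
                   mmm=np.asarray(mmm, dtype=float).copy(),
                   reef_pixels=reef_pixels)
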