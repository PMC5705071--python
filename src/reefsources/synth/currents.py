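"""Synthetic surface-current fields.

The field is built from a scalar streamfunction

    psi(x, y, t) = jet + cross-shelf inflow + drifting Gaussian eddies

and the velocity components are obtained as the *discrete* curl of psi on
the raster grid (centred differences), so the centred-difference
divergence of (u, v) vanishes identically in the grid interior -- the
kinematic analogue of an incompressible surface layer.  Temporal
variability enters through slow linear drift of the eddy centres; each
stored time slice is divergence-free on its own.

Components:

* an alongshore jet u = U sech^2((y - y_jet)/W) flowing toward +x,
* a uniform cross-shelf inflow v = v_in (negative = shoreward), feeding
  the shelf from the outer boundary the way oceanic inflow feeds a shelf,
* Gaussian eddies of amplitude A and e-folding scale sigma.

Units: grid coordinates in km, velocities in m/s, time in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from reefsources.synth.seascape import ConfigError, Seascape

__all__ = ["CurrentsConfig", "VelocityField", "build_currents"]


@dataclass(frozen=True)
class CurrentsConfig:
    jet_speed: float = 0.25          # m/s, alongshore (+x)
    jet_width_km: float = 14.0
    #: jet core position as a fraction of domain height (outer band)
    jet_position: float = 0.80
    inflow_speed: float = -0.04      # m/s; negative = toward shore (-y)
    #: weak inshore counter-current (toward -x) feeding the inner band
    coastal_jet_speed: float = 0.05  # m/s
    coastal_jet_width_km: float = 10.0
    coastal_jet_position: float = 0.18
    eddy_amplitude: float = 0.08     # m/s
    eddy_scale_km: float = 18.0
    n_eddies: int = 6
    #: cross-shelf band (fractions of domain height) eddy centres live in;
    #: mid-shelf by default so the outer jet stays coherent
    eddy_band: tuple[float, float] = (0.25, 0.70)
    #: eddy-centre drift speed, km per day (slow modulation)
    eddy_drift_km_day: float = 2.0
    #: long enough for 16 spawning events 5 days apart plus 30 days tracking
    time_span_hours: float = 24.0 * 111
    time_step_hours: float = 24.0

    def validate(self, min_span_hours: float | None = None) -> None:
        if self.time_span_hours <= 0 or self.time_step_hours <= 0:
            raise ConfigError("time span and step must be positive")
        if min_span_hours is not None and self.time_span_hours < min_span_hours:
            raise ConfigError(
                f"current record ({self.time_span_hours} h) is shorter than the "
                f"dispersal window it must cover ({min_span_hours} h)")
        if self.jet_width_km <= 0 or self.eddy_scale_km <= 0:
            raise ConfigError("jet width and eddy scale must be positive")


@dataclass
class VelocityField:
    """Gridded time-indexed velocity (u, v) in m/s on a uniform km grid."""

    x: np.ndarray          # (nx,) km
    y: np.ndarray          # (ny,) km
    times: np.ndarray      # (nt,) hours
    u: np.ndarray          # (nt, ny, nx) m/s
    v: np.ndarray          # (nt, ny, nx) m/s

    def __post_init__(self) -> None:
        if not (np.all(np.isfinite(self.u)) and np.all(np.isfinite(self.v))):
            raise ValueError("velocity components must be finite")

    @property
    def spacing(self) -> float:
        return float(self.x[1] - self.x[0]) if self.x.size > 1 else np.inf

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (float(self.x[0]), float(self.y[0]),
                float(self.x[-1]), float(self.y[-1]))

    def interp(self, pos: np.ndarray, t: float) -> np.ndarray:
        """Bilinear-in-space, linear-in-time velocity at positions (n, 2) km.

        Positions outside the grid return zero velocity; callers flag them
        as lost separately (see dispersal).
        """
        ut, vt = self._slices_at(t)
        return _bilinear_uv(self.x, self.y, ut, vt, pos)

    def _slices_at(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        tt = self.times
        if t <= tt[0]:
            return self.u[0], self.v[0]
        if t >= tt[-1]:
            return self.u[-1], self.v[-1]
        i = int(np.searchsorted(tt, t, side="right") - 1)
        w = (t - tt[i]) / (tt[i + 1] - tt[i])
        return ((1 - w) * self.u[i] + w * self.u[i + 1],
                (1 - w) * self.v[i] + w * self.v[i + 1])

    def contains(self, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: positions inside the gridded domain."""
        x0, y0, x1, y1 = self.bounds
        return ((pos[:, 0] >= x0) & (pos[:, 0] <= x1)
                & (pos[:, 1] >= y0) & (pos[:, 1] <= y1))

    def to_xarray(self) -> xr.Dataset:
        return xr.Dataset(
            {
                "u": (("time", "y", "x"), self.u, {"units": "m s-1"}),
                "v": (("time", "y", "x"), self.v, {"units": "m s-1"}),
            },
            coords={"time": ("time", self.times, {"units": "hours"}),
                    "x": ("x", self.x, {"units": "km"}),
                    "y": ("y", self.y, {"units": "km"})},
        )

    @classmethod
    def from_xarray(cls, ds: xr.Dataset) -> "VelocityField":
        return cls(x=ds["x"].values.astype(float),
                   y=ds["y"].values.astype(float),
                   times=ds["time"].values.astype(float),
                   u=ds["u"].values.astype(float),
                   v=ds["v"].values.astype(float))


def _bilinear_uv(xg: np.ndarray, yg: np.ndarray, u: np.ndarray, v: np.ndarray,
                 pos: np.ndarray) -> np.ndarray:
    """Vectorised bilinear interpolation of (u, v) at pos (n, 2) -> (n, 2) m/s."""
    dx = xg[1] - xg[0]
    dy = yg[1] - yg[0]
    fx = (pos[:, 0] - xg[0]) / dx
    fy = (pos[:, 1] - yg[0]) / dy
    inside = (fx >= 0) & (fx <= xg.size - 1) & (fy >= 0) & (fy <= yg.size - 1)
    fx = np.clip(fx, 0, xg.size - 1 - 1e-12)
    fy = np.clip(fy, 0, yg.size - 1 - 1e-12)
    ix = fx.astype(np.intp)
    iy = fy.astype(np.intp)
    wx = fx - ix
    wy = fy - iy
    out = np.empty((pos.shape[0], 2))
    for k, comp in enumerate((u, v)):
        c00 = comp[iy, ix]
        c10 = comp[iy, ix + 1]
        c01 = comp[iy + 1, ix]
        c11 = comp[iy + 1, ix + 1]
        out[:, k] = ((1 - wx) * (1 - wy) * c00 + wx * (1 - wy) * c10
                     + (1 - wx) * wy * c01 + wx * wy * c11)
    out[~inside] = 0.0
    return out


def _streamfunction(X: np.ndarray, Y: np.ndarray, cfg: CurrentsConfig,
                    domain: tuple[float, float, float, float],
                    eddy_centres: np.ndarray, eddy_signs: np.ndarray) -> np.ndarray:
    """psi in units of m/s * km (so d(psi)/d(km) is m/s)."""
    xmin, ymin, xmax, ymax = domain
    y_jet = ymin + cfg.jet_position * (ymax - ymin)
    W = cfg.jet_width_km
    psi = -cfg.jet_speed * W * np.tanh((Y - y_jet) / W)
    y_cj = ymin + cfg.coastal_jet_position * (ymax - ymin)
    Wc = cfg.coastal_jet_width_km
    psi = psi + cfg.coastal_jet_speed * Wc * np.tanh((Y - y_cj) / Wc)
    psi = psi + cfg.inflow_speed * X
    for (ex, ey), s in zip(eddy_centres, eddy_signs):
        r2 = (X - ex) ** 2 + (Y - ey) ** 2
        psi = psi + s * cfg.eddy_amplitude * cfg.eddy_scale_km * np.exp(
            -r2 / (2 * cfg.eddy_scale_km**2))
    return psi


def build_currents(seascape: Seascape, config: CurrentsConfig, seed: int,
                   min_span_hours: float | None = None) -> VelocityField:
    """Build a divergence-free velocity field over the seascape domain.

    The grid extends one spacing beyond the seascape domain on every side
    so particles near the boundary still see an interpolable field.
    """
    config.validate(min_span_hours)
    rng = np.random.default_rng(seed)
    h = seascape.grid_spacing
    xmin, ymin, xmax, ymax = seascape.domain
    x = np.arange(xmin - h, xmax + 2 * h, h)
    y = np.arange(ymin - h, ymax + 2 * h, h)
    X, Y = np.meshgrid(x, y)
    times = np.arange(0.0, config.time_span_hours + config.time_step_hours,
                      config.time_step_hours)

    b0, b1 = config.eddy_band
    centres0 = np.column_stack([
        rng.uniform(xmin, xmax, size=config.n_eddies),
        rng.uniform(ymin + b0 * (ymax - ymin), ymin + b1 * (ymax - ymin),
                    size=config.n_eddies),
    ])
    signs = rng.choice([-1.0, 1.0], size=config.n_eddies)
    drift_dir = rng.standard_normal((config.n_eddies, 2))
    norms = np.linalg.norm(drift_dir, axis=1, keepdims=True)
    drift_dir = np.divide(drift_dir, norms, out=np.zeros_like(drift_dir),
                          where=norms > 0)

    nt, ny, nx = times.size, y.size, x.size
    u = np.zeros((nt, ny, nx))
    v = np.zeros((nt, ny, nx))
    for it, t in enumerate(times):
        centres = centres0 + drift_dir * (config.eddy_drift_km_day * t / 24.0)
        psi = _streamfunction(X, Y, config, seascape.domain, centres, signs)
        # discrete curl: u = -dpsi/dy, v = +dpsi/dx (centred differences,
        # one-sided at the edges) => centred divergence vanishes in the interior
        u[it] = -np.gradient(psi, h, axis=0)
        v[it] = np.gradient(psi, h, axis=1)
    return VelocityField(x=x, y=y, times=times, u=u, v=v)


def discrete_divergence(field: VelocityField, it: int = 0) -> np.ndarray:
    """Centred-difference divergence (1/s scale: m/s per km) of slice it,
    evaluated on the grid interior."""
    h = field.spacing
    u = field.u[it]
    v = field.v[it]
    dudx = (u[1:-1, 2:] - u[1:-1, :-2]) / (2 * h)
    dvdy = (v[2:, 1:-1] - v[:-2, 1:-1]) / (2 * h)
    return dudx + dvdy
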