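"""Lagrangian larval dispersal with reef arrest.

Particles are released uniformly inside each source reef polygon and
advected hourly with a classical fourth-order Runge-Kutta step on the
bilinearly interpolated velocity field, plus an isotropic Gaussian
random-walk displacement representing unresolved turbulent diffusion
(variance 2*K*dt per axis).  Every 12 hours each particle is tested for
proximity to the reef polygons: a particle within 1 km of a reef is
*arrested* there, stops moving, and is recorded with its arrest age; the
nearest qualifying reef wins, ties break to the smaller reef id.

A particle becomes eligible for arrest by its own source reef only after
it has first been observed outside the source's 1-km arrest zone;
otherwise every particle would self-arrest at the first check.  Particles
that leave the gridded domain are lost immediately; survivors past the
maximum tracked duration (30 days by default) are lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon

from reefsources.synth.currents import VelocityField
from reefsources.synth.seascape import Reef, Seascape

__all__ = [
    "DispersalParams",
    "ArrestTable",
    "step_rk4",
    "simulate_release",
    "run_event",
]

KM_PER_HOUR_PER_MS = 3.6  # 1 m/s = 3.6 km/h


class OutOfDomainError(RuntimeError):
    """Raised by step_rk4 when a position has left the field support."""


@dataclass(frozen=True)
class DispersalParams:
    step_hours: float = 1.0
    check_interval_hours: float = 12.0
    arrest_radius_km: float = 1.0
    max_days: float = 30.0
    n_runs: int = 10
    particles_per_run: int = 1000
    diffusivity_m2_s: float = 10.0
    release_depth_m: float = 0.5  # informational; transport is 2-D surface

    def __post_init__(self) -> None:
        ratio = self.check_interval_hours / self.step_hours
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("step must divide the check interval")
        if self.max_days <= 0 or self.arrest_radius_km <= 0:
            raise ValueError("max_days and arrest_radius must be positive")

    @property
    def steps_per_check(self) -> int:
        return round(self.check_interval_hours / self.step_hours)

    @property
    def n_steps(self) -> int:
        return round(self.max_days * 24.0 / self.step_hours)


@dataclass
class ArrestTable:
    """Per-particle outcomes of one spawning event.

    records columns: source_id, particle_id, fate ('arrested'|'lost'),
    sink_id (empty for lost), arrest_age_days (NaN for lost).
    released maps source reef id -> number of particles released.
    """

    event_id: str
    release_time_hours: float
    records: pd.DataFrame
    released: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> None:
        counts = self.records.groupby("source_id").size()
        for rid, n_rel in self.released.items():
            if int(counts.get(rid, 0)) != n_rel:
                raise AssertionError(
                    f"conservation violated for reef {rid}: "
                    f"{counts.get(rid, 0)} records vs {n_rel} released")

    def arrivals(self) -> pd.DataFrame:
        return self.records[self.records["fate"] == "arrested"]


def step_rk4(pos: np.ndarray, fld: VelocityField, t: float, dt: float) -> np.ndarray:
    """One classical RK4 advection step for positions (n, 2) in km.

    Velocities are interpolated bilinearly in space and linearly in time;
    the returned positions are purely advective (diffusion is added by the
    caller).  Positions outside the field see zero velocity; domain-exit
    bookkeeping is the caller's job.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    c = KM_PER_HOUR_PER_MS
    k1 = fld.interp(pos, t) * c
    k2 = fld.interp(pos + 0.5 * dt * k1, t + 0.5 * dt) * c
    k3 = fld.interp(pos + 0.5 * dt * k2, t + 0.5 * dt) * c
    k4 = fld.interp(pos + dt * k3, t + dt) * c
    return pos + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _uniform_in_polygon(poly: Polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    """Rejection-sample n uniform points inside a (convex) polygon."""
    xmin, ymin, xmax, ymax = poly.bounds
    out = np.empty((n, 2))
    got = 0
    while got < n:
        m = max(2 * (n - got), 16)
        cand = np.column_stack([rng.uniform(xmin, xmax, m),
                                rng.uniform(ymin, ymax, m)])
        keep = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
        k = cand[keep]
        take = min(len(k), n - got)
        out[got:got + take] = k[:take]
        got += take
    return out


def _nearest_eligible(pos: np.ndarray, tree: shapely.STRtree, radius: float,
                      ineligible: np.ndarray | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Nearest reef within radius for each position (n, 2).

    ineligible, if given, is a boolean (n_pos,)-indexed exclusion of one
    reef per position encoded as an index array (n_pos,) with -1 meaning
    no exclusion.  Returns (reef_index, distance); reef_index is -1 where
    no eligible reef is within radius.  Distance ties break to the smaller
    reef index.
    """
    n = pos.shape[0]
    best_idx = np.full(n, -1, dtype=np.intp)
    best_d = np.full(n, np.inf)
    pts = shapely.points(pos[:, 0], pos[:, 1])
    pi, ri = tree.query(pts, predicate="dwithin", distance=radius)
    if pi.size:
        d = shapely.distance(pts[pi], tree.geometries[ri])
        # candidate pair counts are small (few reefs within 1 km of a point)
        for p, r, dist in zip(pi, ri, d):
            if ineligible is not None and r == ineligible[p]:
                continue
            if dist < best_d[p] - 1e-12 or (abs(dist - best_d[p]) <= 1e-12
                                            and r < best_idx[p]):
                best_d[p] = dist
                best_idx[p] = r
    return best_idx, best_d


@dataclass
class _Release:
    """One (source reef, run) slice of the particle batch."""

    src_idx: int
    offset: int
    n: int
    rng: np.random.Generator


def _simulate_batch(releases: list[_Release], seascape: Seascape,
                    fld: VelocityField, release_time_hours: float,
                    params: DispersalParams,
                    tree: shapely.STRtree) -> tuple[np.ndarray, np.ndarray]:
    """Track all releases of one event together.

    Advection is shared across the batch; initial positions and diffusion
    noise are drawn from each release's own generator (in release order
    each step), so a single release simulated alone reproduces its slice
    of the batch exactly.  Returns (sink_index, age_days) per particle;
    sink -1 = lost.
    """
    polys = seascape.polygons
    n_total = sum(r.n for r in releases)
    pos = np.empty((n_total, 2))
    src_of = np.empty(n_total, dtype=np.intp)
    for r in releases:
        pos[r.offset:r.offset + r.n] = _uniform_in_polygon(
            polys[r.src_idx], r.n, r.rng)
        src_of[r.offset:r.offset + r.n] = r.src_idx
    src_geom = np.array(polys, dtype=object)[src_of]

    active = np.ones(n_total, dtype=bool)
    exited_source = np.zeros(n_total, dtype=bool)
    sink = np.full(n_total, -1, dtype=np.intp)
    age_days = np.full(n_total, np.nan)

    dt = params.step_hours
    sigma = np.sqrt(2.0 * params.diffusivity_m2_s * dt * 3600.0) / 1000.0  # km
    t = release_time_hours
    for istep in range(1, params.n_steps + 1):
        if not active.any():
            break
        idx = np.flatnonzero(active)
        p = step_rk4(pos[idx], fld, t, dt)
        if sigma > 0:
            noise = np.empty_like(p)
            lo = 0
            for r in releases:
                seg = active[r.offset:r.offset + r.n].sum()
                if seg:
                    noise[lo:lo + seg] = r.rng.normal(0.0, sigma, size=(seg, 2))
                    lo += seg
            p = p + noise
        pos[idx] = p
        t += dt
        # immediate loss on domain exit
        inside = fld.contains(p)
        if not inside.all():
            active[idx[~inside]] = False
        if istep % params.steps_per_check == 0:
            idx = np.flatnonzero(active)
            if idx.size == 0:
                continue
            # self-arrest eligibility: the source reef only counts once the
            # particle has been observed outside the source's arrest zone
            pts = shapely.points(pos[idx, 0], pos[idx, 1])
            src_d = shapely.distance(pts, src_geom[idx])
            exited_source[idx[src_d > params.arrest_radius_km]] = True
            ineligible = np.where(exited_source[idx], -1, src_of[idx])
            hit, _ = _nearest_eligible(pos[idx], tree,
                                       params.arrest_radius_km, ineligible)
            got = hit >= 0
            sink[idx[got]] = hit[got]
            age_days[idx[got]] = istep * dt / 24.0
            active[idx[got]] = False
    return sink, age_days


def simulate_release(reef: Reef, seascape: Seascape, fld: VelocityField,
                     release_time_hours: float, params: DispersalParams,
                     seed: int, n_particles: int | None = None,
                     tree: shapely.STRtree | None = None) -> pd.DataFrame:
    """Track one release of particles from a single reef.

    Returns a records DataFrame (see ArrestTable).  n_particles defaults
    to params.particles_per_run; pass a prebuilt STRtree of the seascape
    polygons to amortise construction across releases.
    """
    n = n_particles if n_particles is not None else params.particles_per_run
    if tree is None:
        tree = shapely.STRtree(seascape.polygons)
    rel = _Release(src_idx=seascape.ids.index(reef.id), offset=0, n=n,
                   rng=np.random.default_rng(seed))
    sink, age_days = _simulate_batch([rel], seascape, fld,
                                     release_time_hours, params, tree)
    ids = seascape.ids
    return pd.DataFrame({
        "source_id": reef.id,
        "particle_id": np.arange(n),
        "fate": np.where(sink >= 0, "arrested", "lost"),
        "sink_id": [ids[s] if s >= 0 else "" for s in sink],
        "arrest_age_days": age_days,
    })


def _release_seed(seed: int, reef_index: int, run: int) -> int:
    return int(np.random.SeedSequence(
        entropy=seed, spawn_key=(reef_index, run)).generate_state(1)[0]
        % (2**31))


def run_event(seascape: Seascape, fld: VelocityField, event_id: str,
              release_time_hours: float, params: DispersalParams,
              seed: int) -> ArrestTable:
    """Simulate one spawning event: all reefs, all runs, in one batch.

    Per-release seeds are derived deterministically from (seed, reef
    index, run index), so any individual release can be reproduced in
    isolation with simulate_release.
    """
    if release_time_hours + params.max_days * 24.0 > fld.times[-1] + 1e-9:
        raise ValueError(
            "event window extends past the end of the velocity record")
    tree = seascape.strtree()
    releases = []
    offset = 0
    for ir, reef in enumerate(seascape.reefs):
        for run in range(params.n_runs):
            releases.append(_Release(
                src_idx=ir, offset=offset, n=params.particles_per_run,
                rng=np.random.default_rng(_release_seed(seed, ir, run))))
            offset += params.particles_per_run
    sink, age_days = _simulate_batch(releases, seascape, fld,
                                     release_time_hours, params, tree)
    ids = seascape.ids
    per_reef = params.n_runs * params.particles_per_run
    records = pd.DataFrame({
        "source_id": np.repeat(ids, per_reef),
        "particle_id": np.tile(np.arange(per_reef), len(ids)),
        "fate": np.where(sink >= 0, "arrested", "lost"),
        "sink_id": [ids[s] if s >= 0 else "" for s in sink],
        "arrest_age_days": age_days,
    })
    table = ArrestTable(event_id=event_id,
                        release_time_hours=release_time_hours,
                        records=records,
                        released={rid: per_reef for rid in ids})
    table.check_conservation()
    return table
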