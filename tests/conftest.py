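"""Shared fixtures: small seascapes, toy fields and toy networks."""

from __future__ import annotations

import numpy as np
import pytest
from shapely.geometry import Polygon

from reefsources.connectivity import CompetencyCurve, ConnectivityNetwork
from reefsources.synth.seascape import Reef, Seascape, SeascapeConfig, build_reefs
from reefsources.synth.currents import VelocityField


def square_reef(rid: str, cx: float, cy: float, half: float = 1.0,
                region: int = 0, no_take: bool = False) -> Reef:
    poly = Polygon([(cx - half, cy - half), (cx + half, cy - half),
                    (cx + half, cy + half), (cx - half, cy + half)])
    return Reef(id=rid, polygon=poly, region=region, band="mid",
                no_take=no_take)


def uniform_field(u_ms: float, v_ms: float, extent: float = 200.0,
                  spacing: float = 4.0, span_hours: float = 24.0 * 40
                  ) -> VelocityField:
    x = np.arange(-spacing, extent + 2 * spacing, spacing)
    y = np.arange(-spacing, extent + 2 * spacing, spacing)
    t = np.array([0.0, span_hours])
    shape = (2, y.size, x.size)
    return VelocityField(x=x, y=y, times=t,
                         u=np.full(shape, u_ms), v=np.full(shape, v_ms))


def toy_network(weights: np.ndarray, ids: list[str] | None = None,
                scenario: str = "E00|k2_m0.1") -> ConnectivityNetwork:
    n = weights.shape[0]
    ids = ids or [f"R{i:03d}" for i in range(n)]
    return ConnectivityNetwork(scenario_id=scenario, event_id=scenario.split("|")[0],
                               curve=CompetencyCurve(shape=2.0),
                               reef_ids=ids, weights=np.asarray(weights, float))


@pytest.fixture(scope="session")
def small_seascape() -> Seascape:
    scape, _ = build_reefs(SeascapeConfig(n_reefs=50, n_regions=3), seed=7)
    return scape


@pytest.fixture()
def line_seascape() -> Seascape:
    """Three square reefs in a row along x, 30 km apart."""
    reefs = [square_reef("A", 10, 50), square_reef("B", 40, 50),
             square_reef("C", 70, 50)]
    return Seascape(reefs=reefs, domain=(0, 0, 200, 100), grid_spacing=4.0)
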