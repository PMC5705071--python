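"""Degree-heating-week thermal stress and refuge classification.

DHW is the canonical cumulative coral bleaching-stress metric
(degC-weeks): a hotspot is the excess of weekly SST over the
climatological maximum (MMM), and DHW at week w is the sum of hotspots
exceeding 1 degC over the 12-week window ending at w.  Years in which a
strict majority of reef pixels accumulate any DHW are *significant
warming events*; a reef is a *thermal refuge* when, in every such year,
at least 75% of its area stayed at or below 6 DHW (the level above which
bleaching mortality is expected).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from reefsources.synth.climate import SSTCube
from reefsources.synth.seascape import Seascape

__all__ = [
    "DHWSeries",
    "ThermalClassification",
    "degree_heating_weeks",
    "significant_event_years",
    "classify_refugia",
    "dhw_rank_index",
]

HOTSPOT_THRESHOLD = 1.0   # degC; strictly greater-than accumulates
DHW_WINDOW_WEEKS = 12
MORTALITY_DHW = 6.0       # degC-weeks; strictly greater-than disqualifies
REFUGE_AREA_FRACTION = 0.75


@dataclass
class DHWSeries:
    """Per-pixel weekly DHW and annual maxima.

    weekly has shape (n_weeks, n_pixels); annual_max has shape
    (n_years, n_pixels); years lists the year index of each annual row;
    reef_pixels maps reef id -> flat pixel indices.
    """

    weekly: np.ndarray
    annual_max: np.ndarray
    years: np.ndarray
    reef_pixels: dict[str, np.ndarray]

    def reef_pixel_indices(self) -> np.ndarray:
        """Flat indices of all pixels that belong to any reef."""
        return np.unique(np.concatenate(list(self.reef_pixels.values())))


@dataclass
class ThermalClassification:
    event_years: list[int]
    refuge: pd.Series           # bool per reef id
    clean_fraction: pd.Series   # worst-year clean-area fraction per reef
    rank_index: pd.Series       # 1 (lowest stress) .. 100 (highest)


def degree_heating_weeks(sst: SSTCube,
                         climatology: np.ndarray | None = None) -> DHWSeries:
    """Accumulate DHW from a weekly SST cube.

    climatology: per-pixel MMM (ny, nx); defaults to the cube's own.
    Hotspots of exactly 1 degC contribute nothing (strict threshold).
    """
    weeks = sst.week.astype(int)
    if weeks.size >= 2 and not np.all(np.diff(weeks) % 52 == 1):
        raise ValueError("SST record must have consecutive weekly cadence")
    mmm = sst.mmm if climatology is None else np.asarray(climatology, dtype=float)
    if mmm.shape != sst.values.shape[1:]:
        raise ValueError("climatology shape must match the pixel grid")
    flat = sst.flat_values()
    hotspot = flat - mmm.reshape(1, -1)
    contrib = np.where(hotspot > HOTSPOT_THRESHOLD, hotspot, 0.0)
    # 12-week trailing sum (window shortened at the start of the record)
    csum = np.cumsum(contrib, axis=0)
    weekly = csum.copy()
    weekly[DHW_WINDOW_WEEKS:] = csum[DHW_WINDOW_WEEKS:] - csum[:-DHW_WINDOW_WEEKS]

    years = np.unique(sst.year)
    annual = np.vstack([weekly[sst.year == yr].max(axis=0) for yr in years])
    return DHWSeries(weekly=weekly, annual_max=annual, years=years,
                     reef_pixels=sst.reef_pixels)


def significant_event_years(dhw: DHWSeries) -> list[int]:
    """Years in which >50% of all reef pixels saw any accumulated stress."""
    px = dhw.reef_pixel_indices()
    frac = (dhw.annual_max[:, px] > 0).mean(axis=1)
    return [int(y) for y, f in zip(dhw.years, frac) if f > 0.5]


def classify_refugia(dhw: DHWSeries, events: list[int],
                     seascape: Seascape) -> tuple[pd.Series, pd.Series]:
    """Refuge flags and worst-event clean-area fractions per reef.

    clean fraction (per reef, per event year) = share of the reef's pixels
    with annual-max DHW <= 6; refuge iff the minimum over event years is
    >= 0.75 (inclusive at both boundaries).  With no event years every
    reef is trivially a refuge.
    """
    ids = seascape.ids
    year_rows = {int(y): i for i, y in enumerate(dhw.years)}
    clean = pd.Series(1.0, index=ids)
    for rid in ids:
        px = dhw.reef_pixels.get(rid)
        if px is None or len(px) == 0:
            raise ValueError(f"reef {rid} has no thermal pixels")
        fracs = [float((dhw.annual_max[year_rows[y]][px] <= MORTALITY_DHW).mean())
                 for y in events]
        clean[rid] = min(fracs) if fracs else 1.0
    refuge = clean >= REFUGE_AREA_FRACTION
    return refuge, clean


def dhw_rank_index(dhw: DHWSeries, events: list[int],
                   seascape: Seascape) -> pd.Series:
    """Mean-DHW stress ranking, affinely standardised to 1..100.

    Each reef's stress score is its pixel-mean annual-max DHW averaged
    over the significant event years; mid-ranks are mapped so the least
    stressed reef scores 1 and the most stressed 100 (ties share the
    mid-rank index).
    """
    ids = seascape.ids
    if len(ids) < 2:
        warnings.warn("rank index degenerate with a single reef; scoring 100")
        return pd.Series(100.0, index=ids)
    year_rows = {int(y): i for i, y in enumerate(dhw.years)}
    rows = [year_rows[y] for y in events]
    means = np.array([
        dhw.annual_max[np.ix_(rows, dhw.reef_pixels[rid])].mean() if rows else 0.0
        for rid in ids])
    ranks = rankdata(means, method="average")
    idx = 1.0 + (ranks - 1.0) * 99.0 / (len(ids) - 1)
    return pd.Series(idx, index=ids)


def classify_thermal(sst: SSTCube, seascape: Seascape) -> ThermalClassification:
    """Convenience wrapper: DHW -> events -> refugia + rank index."""
    dhw = degree_heating_weeks(sst)
    events = significant_event_years(dhw)
    refuge, clean = classify_refugia(dhw, events, seascape)
    rank = dhw_rank_index(dhw, events, seascape)
    return ThermalClassification(event_years=events, refuge=refuge,
                                 clean_fraction=clean, rank_index=rank)
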