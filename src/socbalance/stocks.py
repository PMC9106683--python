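"""Elemental stock computation per horizon and cumulative to a depth limit.

The stock of an element (C or N) held by a soil layer follows from its
content (g per kg soil), bulk density (g cm^-3) and thickness (cm):

    stock [kg ha^-1] = 100 * content * BD * thickness

which is the unit chain (g/kg) x (g/cm^3) x cm integrated over one hectare
(10^8 cm^2).  Profile stocks are accumulated horizon-wise down to a fixed
depth limit (default 30 cm); a horizon crossing the limit contributes the
prorated part of its thickness, with content and BD taken as uniform within
the horizon.  Stocks are reported in kg m^-2 at profile level, matching the
usual reporting scale for alpine pasture soils.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, DataError
from .profiles import DegradationStage, SoilProfile, StageEnsemble

__all__ = [
    "elemental_stock",
    "kg_ha_to_kg_m2",
    "som_to_soc",
    "profile_stock",
    "ensemble_stocks",
    "StockResult",
    "mean_se",
]

logger = logging.getLogger(__name__)


def elemental_stock(content: float, bulk_density: float, thickness: float) -> float:
    """Stock (kg ha^-1) of an element in one uniform soil layer.

    Parameters are content (g per kg), bulk density (g cm^-3) and layer
    thickness (cm); all must be non-negative.
    """
    if content < 0 or bulk_density < 0 or thickness < 0:
        raise DataError(
            f"elemental_stock: negative input "
            f"(content={content}, BD={bulk_density}, thickness={thickness})"
        )
    return 100.0 * content * bulk_density * thickness


def kg_ha_to_kg_m2(stock_kg_ha: float) -> float:
    """Convert a stock from kg ha^-1 to kg m^-2 (1 ha = 10^4 m^2)."""
    return stock_kg_ha * 1e-4


def som_to_soc(som_content: float, factor: float = 2.0) -> float:
    """Convert soil organic matter content to organic carbon content.

    SOM is divided by a conversion factor (default 2.0, the conventional
    value for these grassland soils).
    """
    if factor <= 0:
        raise ConfigError(f"som_to_soc: conversion factor must be > 0, got {factor}")
    if som_content < 0:
        raise DataError(f"som_to_soc: negative SOM content ({som_content})")
    return som_content / factor


@dataclass
class StockResult:
    """Per-horizon and cumulative elemental stock of one profile.

    ``per_horizon`` lists ``(horizon label, stock kg m^-2)`` for the part of
    each horizon inside ``[0, depth_limit]``; ``cumulative`` is their sum.
    """

    stage: DegradationStage
    replicate: str
    element: str
    depth_limit: float
    per_horizon: list[tuple[str, float]]
    cumulative: float


def _element_content(horizon, element: str) -> float:
    if element == "C":
        return horizon.soc_content
    if element == "N":
        if horizon.n_content is None:
            raise DataError(
                f"element unavailable: horizon {horizon.label} has no N content"
            )
        return horizon.n_content
    raise ConfigError(f"unknown element {element!r}; expected 'C' or 'N'")


def profile_stock(
    profile: SoilProfile, element: str = "C", depth_limit: float = 30.0
) -> StockResult:
    """Accumulate the elemental stock of a profile down to *depth_limit* cm.

    Horizons crossing the limit are prorated by thickness.  A profile
    shallower than the limit contributes its full depth with a logged
    warning (shallow pedons are common on eroded plots).
    """
    if depth_limit < 0:
        raise ConfigError(f"depth_limit must be >= 0, got {depth_limit}")
    per_horizon: list[tuple[str, float]] = []
    for h in profile.horizons:
        t = min(h.bottom_depth, depth_limit) - max(h.top_depth, 0.0)
        if t <= 0:
            continue
        stock = kg_ha_to_kg_m2(
            elemental_stock(_element_content(h, element), h.bulk_density, t)
        )
        per_horizon.append((h.label, stock))
    if profile.depth < depth_limit:
        logger.warning(
            "profile %s/%s is %.1f cm deep, shallower than the %.1f cm stock limit",
            profile.stage,
            profile.replicate,
            profile.depth,
            depth_limit,
        )
    return StockResult(
        stage=profile.stage,
        replicate=profile.replicate,
        element=element,
        depth_limit=depth_limit,
        per_horizon=per_horizon,
        cumulative=float(sum(s for _, s in per_horizon)),
    )


def mean_se(values) -> tuple[float, float]:
    """Arithmetic mean and standard error (sd/sqrt(n)); SE is NaN for n < 2."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("mean_se: empty sample")
    if v.size == 1:
        return float(v[0]), float("nan")
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))


def ensemble_stocks(
    ensemble: StageEnsemble, element: str = "C", depth_limit: float = 30.0
) -> tuple[np.ndarray, float, float]:
    """Cumulative stocks of every replicate plus their mean and SE (kg m^-2)."""
    values = np.array(
        [profile_stock(p, element, depth_limit).cumulative for p in ensemble.profiles]
    )
    mean, se = mean_se(values)
    return values, mean, se
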