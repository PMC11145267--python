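"""Monetization of health impacts.

Mortality risk reductions are valued with a value per statistical life (VSL)
updated from its base year for real income growth (income elasticity 1.0)
and inflation, then discounted through a 20-year cessation-lag structure:
30% of the mortality benefit accrues in the year of exposure, 50% uniformly
over years 2-5 and 20% uniformly over years 6-20.  New childhood asthma
cases are valued at a willingness-to-pay value per statistical case (VSC) in
the exposure year, with no lag — the lag describes the delay between
exposure change and *mortality* response.

Per-mile results are present values at the time the mile is driven; per-bus
results additionally spread the lifetime mileage uniformly over 13.5 years
and discount each driving year (mid-year convention by default).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping

import numpy as np
from pydantic import BaseModel, Field, model_validator

from . import params as P

Convention = Literal["mid-year", "start-of-year"]


class ValuationParams(BaseModel):
    """All monetization constants, 2022 USD unless noted.

    The income and deflator series are synthetic placeholder indexes
    calibrated so that the base-year VSL updates to the published 2022
    endpoint ($9.3M-2014 -> $12.4M-2022, a combined factor of 4/3); the
    updating formula itself is exercised against arbitrary series in tests.
    """

    model_config = {"frozen": True}

    vsl_base: float = Field(P.VSL_BASE_USD, gt=0)
    base_year: int = P.VSL_BASE_YEAR
    target_year: int = P.VSL_TARGET_YEAR
    elasticity: float = P.VSL_INCOME_ELASTICITY
    income_index: dict[int, float] = Field(
        default_factory=lambda: {2014: 1.0, 2022: 1.2}
    )
    price_deflator: dict[int, float] = Field(
        default_factory=lambda: {2014: 1.0, 2022: (P.VSL_TARGET_USD / P.VSL_BASE_USD) / 1.2}
    )
    vsc: float = Field(P.VSC_USD, gt=0)
    health_discount_rate: float = Field(P.HEALTH_DISCOUNT_RATE, ge=0)

    @model_validator(mode="after")
    def _positive_indexes(self) -> "ValuationParams":
        if any(v <= 0 for v in self.income_index.values()):
            raise ValueError("income index values must be positive")
        if any(v <= 0 for v in self.price_deflator.values()):
            raise ValueError("price deflator values must be positive")
        return self


def update_vsl(vp: ValuationParams, target_year: int | None = None) -> float:
    """VSL at the target year's price and income levels.

    vsl = vsl_base x (I_t / I_0)^elasticity x (D_t / D_0)
    with I the real income index and D the price deflator.
    """
    year = vp.target_year if target_year is None else target_year
    for series, name in ((vp.income_index, "income index"),
                         (vp.price_deflator, "price deflator")):
        if vp.base_year not in series or year not in series:
            raise KeyError(f"{name} missing year {vp.base_year} or {year}")
    income = (vp.income_index[year] / vp.income_index[vp.base_year]) ** vp.elasticity
    prices = vp.price_deflator[year] / vp.price_deflator[vp.base_year]
    return vp.vsl_base * income * prices


@dataclass(frozen=True)
class CessationLag:
    """Temporal distribution of mortality benefits after an exposure change."""

    weights: np.ndarray  # per-year fractions, year 1 first

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("lag weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("lag weights must sum to 1")
        object.__setattr__(self, "weights", w)

    @property
    def horizon_years(self) -> int:
        return self.weights.size


def lag_weights() -> CessationLag:
    """The EPA-recommended 20-year cessation-lag structure.

    30% in the first year, 50% spread uniformly over years 2-5, 20% spread
    uniformly over years 6-20.  The final weight absorbs the float residual
    so the weights sum to exactly 1.
    """
    w = np.empty(20)
    w[0] = 0.30
    w[1:5] = 0.50 / 4
    w[5:] = 0.20 / 15
    w[-1] += 1.0 - w.sum()
    return CessationLag(weights=w)


def discounted_lag_factor(lag: CessationLag, rate: float) -> float:
    """Present-value factor of a lag-distributed benefit stream.

    sum_t w_t (1+r)^-(t-1): the year-of-exposure share is undiscounted,
    later shares are discounted back to the exposure year.  Equals 1 at
    rate 0 and decreases toward the first-year share as the rate grows.
    """
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.arange(lag.horizon_years)
    return float(np.sum(lag.weights * (1.0 + rate) ** -t))


def lifetime_discount_multiplier(
    years: float = P.LIFETIME_YEARS,
    rate: float = P.HEALTH_DISCOUNT_RATE,
    convention: Convention = "mid-year",
) -> float:
    """Average discount factor of a uniform per-mile flow over the bus life.

    The horizon is ``floor(years)`` full driving years plus one fractional
    year weighted by its length.  Mid-year convention discounts year t by
    (1+r)^-(t-0.5) (the fractional final year by (1+r)^-years); the
    start-of-year convention uses (1+r)^-(t-1).
    """
    if years <= 0:
        raise ValueError("lifetime must be positive")
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    n_full = int(np.floor(years))
    frac = years - n_full
    t = np.arange(1, n_full + 1, dtype=float)
    if convention == "mid-year":
        factors = (1.0 + rate) ** -(t - 0.5)
        tail = frac * (1.0 + rate) ** -years
    elif convention == "start-of-year":
        factors = (1.0 + rate) ** -(t - 1.0)
        tail = frac * (1.0 + rate) ** -float(n_full)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float((factors.sum() + tail) / years)


def monetize_impacts(
    counts: Mapping[str, float],
    vp: ValuationParams,
    lag: CessationLag | None = None,
) -> dict[str, float]:
    """Dollar value of attributable cases by outcome.

    mortality $ = deaths x VSL(target year) x lag factor;
    asthma $ = cases x VSC (valued in the exposure year).
    """
    lag = lag if lag is not None else lag_weights()
    vsl = update_vsl(vp)
    factor = discounted_lag_factor(lag, vp.health_discount_rate)
    mortality = counts.get("mortality", 0.0) * vsl * factor
    asthma = counts.get("asthma_onset", 0.0) * vp.vsc
    return {
        "mortality": mortality,
        "asthma_onset": asthma,
        "total": mortality + asthma,
        "vsl": vsl,
        "lag_factor": factor,
    }
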