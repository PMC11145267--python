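"""Replacement scenarios: per-mile, per-bus, fleet and regional benefits.

A scenario replaces miles driven by one bus technology (an emission-factor
set, e.g. the MY2005 diesel anchor) with another (electric, or a newer
diesel) in a driving region (a county, an urbanization class, or the whole
domain).  The health side chains

    emission factors -> county population-weighted allocation -> SRM ->
    attributable cases -> VSL/VSC monetization with cessation lag

for both technologies on the same receptor set and subtracts; the climate
side values the lifetime CO2 flow difference under the social-cost-of-carbon
schedule.  Negative benefits are reported, never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import params as P
from .climate import (
    ClimateParams,
    SccSchedule,
    build_scc_schedule,
    climate_benefit_per_bus,
    lifetime_ghg_reduction,
)
from .exposure import EmissionRateField, apply_srm
from .health import (
    ConcentrationResponse,
    GridImpactParams,
    ImpactBreakdown,
    PopulationHealthTable,
    attributable_cases,
    electric_grid_impacts,
)
from .synthetic import FixtureBundle, URBANIZATION_CLASSES
from .valuation import (
    Convention,
    ValuationParams,
    lifetime_discount_multiplier,
    monetize_impacts,
)

OUTCOMES = ("mortality", "asthma_onset")


def default_crfs() -> list[ConcentrationResponse]:
    return [
        ConcentrationResponse.mortality_log_linear(),
        ConcentrationResponse.asthma_from_hazard_ratio(),
    ]


@dataclass(frozen=True)
class ReplacementScenario:
    """What is replaced, by what, and where it is driven."""

    replaced: str
    replacement: str = "electric"
    region: int | str = "all"  # county_id, urbanization class, or "all"
    toxicity_multiplier: float = 1.0
    cost_differential: float = P.COST_DIFFERENTIAL_USD
    lifetime_miles: float = P.LIFETIME_MILES
    lifetime_years: float = P.LIFETIME_YEARS

    def __post_init__(self) -> None:
        if self.lifetime_miles <= 0 or self.lifetime_years <= 0:
            raise ValueError("lifetime must be positive")
        if self.toxicity_multiplier < 0:
            raise ValueError("toxicity multiplier must be non-negative")


@dataclass
class BenefitResult:
    """Benefit of one scenario, per mile and (once extended) per bus."""

    scenario: ReplacementScenario
    per_mile_dollars: dict[str, float]          # by outcome + "total"
    per_mile_cases: dict[str, float]            # avoided cases per mile, by outcome
    replaced_cases_per_mile: pd.DataFrame       # (outcome, pollutant, cases_per_mile)
    replacement_cases_per_mile: pd.DataFrame
    replaced_dollars_per_mile: float
    replacement_dollars_per_mile: float
    per_bus_health: float | None = None
    per_bus_climate: float | None = None
    ghg_tonnes: float | None = None
    net_benefit_dollars: float | None = None
    local_share_fraction: float | None = None


# ---------------------------------------------------------------------------
# county-level marginal damages
# ---------------------------------------------------------------------------

def county_unit_impacts(
    bundle: FixtureBundle,
    county_id: int,
    crfs: Sequence[ConcentrationResponse],
    table: PopulationHealthTable | None = None,
) -> ImpactBreakdown:
    """Receptor-resolved cases caused by 1 t/yr of every pollutant emitted
    in one county, allocated within the county by population.

    Because every channel carries exactly one ton, the breakdown doubles as
    a per-ton marginal damage table.
    """
    table = table or PopulationHealthTable.from_cells(bundle.cells, bundle.rates)
    mask = (bundle.cells["county_id"] == county_id).to_numpy()
    if not mask.any():
        raise KeyError(f"county {county_id} not in domain")
    pop = bundle.cells["population"].to_numpy(float) * mask
    if pop.sum() == 0:
        raise ValueError(f"county {county_id} has zero population")
    share = pop / pop.sum()
    field_ = EmissionRateField(
        rates={p: share.copy() for p in bundle.srm.pollutants},
        cell_ids=bundle.srm.cell_ids,
    )
    return attributable_cases(apply_srm(field_, bundle.srm), list(crfs), table)


def county_damages_per_ton(
    bundle: FixtureBundle,
    crfs: Sequence[ConcentrationResponse] | None = None,
) -> pd.DataFrame:
    """Marginal damages for every county: (county_id, outcome, pollutant,
    cases_per_ton)."""
    crfs = list(crfs) if crfs is not None else default_crfs()
    table = PopulationHealthTable.from_cells(bundle.cells, bundle.rates)
    rows = []
    for county_id in bundle.counties["county_id"]:
        imp = county_unit_impacts(bundle, int(county_id), crfs, table)
        agg = imp.cases.groupby(["outcome", "pollutant"], as_index=False)["cases"].sum()
        agg["county_id"] = int(county_id)
        rows.append(agg)
    out = pd.concat(rows, ignore_index=True)
    return out.rename(columns={"cases": "cases_per_ton"})[
        ["county_id", "outcome", "pollutant", "cases_per_ton"]
    ]


def _region_counties(bundle: FixtureBundle, region: int | str) -> pd.DataFrame:
    counties = bundle.counties
    if region == "all":
        sub = counties
    elif isinstance(region, str):
        if region not in URBANIZATION_CLASSES:
            raise KeyError(f"unknown region {region!r}")
        sub = counties[counties["urbanization_class"] == region]
    else:
        sub = counties[counties["county_id"] == region]
    if sub.empty:
        raise KeyError(f"region {region!r} matches no county in the domain")
    return sub


def per_mile_cases(
    bundle: FixtureBundle,
    ef_label: str,
    region: int | str = "all",
    crfs: Sequence[ConcentrationResponse] | None = None,
    toxicity_multiplier: float = 1.0,
    damages: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Cases per mile of one bus technology in one region, by outcome and
    pollutant (VMT-weighted across the region's counties).

    cases/mi = sum_p EF_p [g/mi] x 1e-6 [t/g] x damages[county, p] [cases/t].
    """
    efs = bundle.emission_factors[ef_label]
    if damages is None:
        damages = county_damages_per_ton(bundle, crfs)
    sub = _region_counties(bundle, region)
    d = damages[damages["county_id"].isin(sub["county_id"])].copy()
    ef = pd.Series(dict(efs.ef_g_per_mile), name="ef")
    d["cases_per_mile"] = d["cases_per_ton"] * d["pollutant"].map(ef).fillna(0.0) * 1e-6
    w = sub.set_index("county_id")["annual_vmt"]
    d["weight"] = d["county_id"].map(w / w.sum())
    out = (
        d.assign(cases_per_mile=d["cases_per_mile"] * d["weight"])
        .groupby(["outcome", "pollutant"], as_index=False)["cases_per_mile"].sum()
    )
    if toxicity_multiplier != 1.0:
        mask = out["pollutant"] == "PM25_primary"
        out.loc[mask, "cases_per_mile"] *= toxicity_multiplier
    return out


def electric_per_mile_cases(
    replaced_per_mile: pd.DataFrame,
    grid: GridImpactParams | None = None,
) -> pd.DataFrame:
    """Per-mile cases of the electric replacement, from grid damages.

    The asthma:mortality transfer ratio is taken from the diesel side of
    the same run, never hard-coded.
    """
    grid = grid or GridImpactParams()
    by_outcome = replaced_per_mile.groupby("outcome")["cases_per_mile"].sum()
    deaths = float(by_outcome.get("mortality", 0.0))
    asthma = float(by_outcome.get("asthma_onset", 0.0))
    ratio = asthma / deaths if deaths > 0 else 0.0
    res = electric_grid_impacts(grid, asthma_ratio=ratio)
    return pd.DataFrame(
        {
            "outcome": ["mortality", "asthma_onset"],
            "pollutant": ["grid", "grid"],
            "cases_per_mile": [res["deaths_per_mile"], res["asthma_per_mile"]],
        }
    )


# ---------------------------------------------------------------------------
# scenario evaluation
# ---------------------------------------------------------------------------

def _monetize_per_mile(cases: pd.DataFrame, vp: ValuationParams) -> dict[str, float]:
    counts = cases.groupby("outcome")["cases_per_mile"].sum().to_dict()
    m = monetize_impacts(counts, vp)
    return {"mortality": m["mortality"], "asthma_onset": m["asthma_onset"],
            "total": m["total"]}


def per_mile_benefit(
    scenario: ReplacementScenario,
    bundle: FixtureBundle,
    crfs: Sequence[ConcentrationResponse] | None = None,
    vp: ValuationParams | None = None,
    grid: GridImpactParams | None = None,
    damages: pd.DataFrame | None = None,
) -> BenefitResult:
    """Health benefit per mile: monetized replaced impacts minus replacement
    impacts, on the same receptor set."""
    vp = vp or ValuationParams()
    crfs = list(crfs) if crfs is not None else default_crfs()
    if damages is None:
        damages = county_damages_per_ton(bundle, crfs)

    replaced = per_mile_cases(
        bundle, scenario.replaced, scenario.region, crfs,
        scenario.toxicity_multiplier, damages,
    )
    if scenario.replacement == "electric" and scenario.replacement not in bundle.emission_factors:
        replacement = electric_per_mile_cases(replaced, grid)
    else:
        efs = bundle.emission_factors[scenario.replacement]
        if efs.is_zero and scenario.replacement == "electric":
            # electric set present in the bundle as an all-zero tailpipe set:
            # the tailpipe side is zero, grid impacts still apply
            replacement = electric_per_mile_cases(replaced, grid)
        else:
            replacement = per_mile_cases(
                bundle, scenario.replacement, scenario.region, crfs,
                scenario.toxicity_multiplier, damages,
            )

    m_replaced = _monetize_per_mile(replaced, vp)
    m_replacement = _monetize_per_mile(replacement, vp)
    dollars = {k: m_replaced[k] - m_replacement[k] for k in ("mortality", "asthma_onset", "total")}
    rep_counts = replaced.groupby("outcome")["cases_per_mile"].sum()
    new_counts = replacement.groupby("outcome")["cases_per_mile"].sum()
    cases = {
        o: float(rep_counts.get(o, 0.0) - new_counts.get(o, 0.0)) for o in OUTCOMES
    }
    return BenefitResult(
        scenario=scenario,
        per_mile_dollars=dollars,
        per_mile_cases=cases,
        replaced_cases_per_mile=replaced,
        replacement_cases_per_mile=replacement,
        replaced_dollars_per_mile=m_replaced["total"],
        replacement_dollars_per_mile=m_replacement["total"],
    )


def per_bus_benefit(
    result: BenefitResult,
    vp: ValuationParams | None = None,
    cp: ClimateParams | None = None,
    schedule: SccSchedule | None = None,
    convention: Convention = "mid-year",
) -> BenefitResult:
    """Extend a per-mile result to lifetime per-bus present values.

    Health: per-mile $ x lifetime miles x the uniform-driving discount
    multiplier.  Climate: present value of the CO2 flow difference (zero
    for diesel-to-diesel swaps, which leave fuel use unchanged here).
    """
    vp = vp or ValuationParams()
    cp = cp or ClimateParams()
    schedule = schedule or build_scc_schedule()
    sc = result.scenario
    mult = lifetime_discount_multiplier(sc.lifetime_years, vp.health_discount_rate, convention)
    result.per_bus_health = result.per_mile_dollars["total"] * sc.lifetime_miles * mult
    if sc.replacement == "electric":
        cp = cp.model_copy(
            update={"lifetime_miles": sc.lifetime_miles, "lifetime_years": sc.lifetime_years}
        )
        result.per_bus_climate = climate_benefit_per_bus(cp, schedule)
        result.ghg_tonnes = lifetime_ghg_reduction(cp)
    else:
        result.per_bus_climate = 0.0
        result.ghg_tonnes = 0.0
    result.net_benefit_dollars = net_benefit(result, sc.cost_differential)
    return result


def net_benefit(result: BenefitResult, cost_differential: float) -> float:
    """Health $ + climate $ - cost differential (per bus)."""
    health = result.per_bus_health or 0.0
    climate = result.per_bus_climate or 0.0
    return health + climate - cost_differential


# ---------------------------------------------------------------------------
# fleet and regional aggregation
# ---------------------------------------------------------------------------

def fleet_burden(
    bundle: FixtureBundle,
    ef_label: str,
    crfs: Sequence[ConcentrationResponse] | None = None,
    vmt_by_county: Mapping[int, float] | None = None,
    damages: pd.DataFrame | None = None,
) -> dict[str, float]:
    """Annual burden of a fleet: deaths/yr, asthma cases/yr, per-100M-mile
    rates.  VMT defaults to the bundle's county activity table."""
    crfs = list(crfs) if crfs is not None else default_crfs()
    if damages is None:
        damages = county_damages_per_ton(bundle, crfs)
    if vmt_by_county is None:
        vmt_by_county = bundle.counties.set_index("county_id")["annual_vmt"].to_dict()
    total_vmt = float(sum(vmt_by_county.values()))
    burden = {o: 0.0 for o in OUTCOMES}
    for county_id, vmt in vmt_by_county.items():
        if vmt < 0:
            raise ValueError("VMT must be non-negative")
        if vmt == 0:
            continue
        pm = per_mile_cases(bundle, ef_label, int(county_id), crfs, damages=damages)
        for o in OUTCOMES:
            burden[o] += vmt * float(
                pm.loc[pm["outcome"] == o, "cases_per_mile"].sum()
            )
    out = {
        "deaths_per_year": burden["mortality"],
        "asthma_per_year": burden["asthma_onset"],
        "total_vmt": total_vmt,
    }
    if total_vmt > 0:
        out["deaths_per_100M_miles"] = burden["mortality"] / (total_vmt / 1e8)
        out["asthma_per_100M_miles"] = burden["asthma_onset"] / (total_vmt / 1e8)
    return out


def aggregate_by_class(
    county_values: pd.DataFrame,
    counties: pd.DataFrame,
    value_col: str = "value",
    weight_col: str = "annual_vmt",
) -> pd.DataFrame:
    """VMT-weighted mean of a per-county quantity within each urbanization
    class, plus the class weight totals."""
    merged = county_values.merge(
        counties[["county_id", "urbanization_class", weight_col]],
        on="county_id", how="left",
    )
    if merged["urbanization_class"].isna().any():
        bad = merged.loc[merged["urbanization_class"].isna(), "county_id"].tolist()
        raise KeyError(f"counties without urbanization class: {bad}")
    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g[weight_col].to_numpy(float)
        v = g[value_col].to_numpy(float)
        return pd.Series(
            {"value": float(np.average(v, weights=w)) if w.sum() else float(v.mean()),
             "weight": float(w.sum()),
             "total": float(np.dot(v, w))}
        )
    return (
        merged.groupby("urbanization_class").apply(_agg, include_groups=False)
        .reset_index()
    )


def map_to_districts(
    county_values: pd.DataFrame,
    crosswalk: pd.DataFrame,
    value_col: str = "value",
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Map county-level values onto school districts with a weighted
    crosswalk (county_id, district_id, weight).

    Weights for each county must be non-negative and sum to 1 (within
    ``tol``), so district totals conserve county totals exactly.
    """
    if (crosswalk["weight"] < 0).any():
        raise ValueError("crosswalk weights must be non-negative")
    sums = crosswalk.groupby("county_id")["weight"].sum()
    bad = sums[(sums - 1.0).abs() > tol]
    if not bad.empty:
        raise ValueError(
            f"crosswalk weights for counties {bad.index.tolist()} do not sum to 1"
        )
    merged = crosswalk.merge(county_values, on="county_id", how="inner")
    merged["value"] = merged["weight"] * merged[value_col]
    return merged.groupby("district_id", as_index=False)["value"].sum()


def local_share(
    impacts: ImpactBreakdown,
    cells: pd.DataFrame,
    source_county: int,
    pollutant: str | None = None,
) -> float:
    """Fraction of an impact breakdown accruing to receptors in the source
    county."""
    d = impacts.cases
    if pollutant is not None:
        d = d[d["pollutant"] == pollutant]
    total = d["cases"].sum()
    if total == 0:
        return float("nan")
    county_of = cells.set_index("cell_id")["county_id"]
    inside = d.loc[d["receptor_id"].map(county_of) == source_county, "cases"].sum()
    return float(inside / total)
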