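"""Synthetic study domain: cells, counties, populations, rates, emission
factors and a pseudo source-receptor matrix.

The generator emulates the statistical structure the downstream analysis
assumes about the real inputs it stands in for: variable-resolution grid
cells that are smaller and denser in urban cores, counties as contiguous
groups of cells spanning a wide density range, an urban-rural gradient
expressed as six ordered urbanization classes, steeply declining diesel
emission factors by model year, Gaussian-kernel dispersion with a short
range for directly emitted PM2.5 and a long range for secondary species,
and age-structured baseline mortality and childhood-asthma rates.

Everything is a deterministic function of the spec (including its seed):
identical specs serialize to byte-identical fixture bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.spatial import distance_matrix

from .exposure import SourceReceptorMatrix
from .params import POLLUTANTS, SECONDARY_POLLUTANTS

# ---------------------------------------------------------------------------
# age structure and national baseline rates
# ---------------------------------------------------------------------------

CHILD_BINS: tuple[str, ...] = ("0-4", "5-11", "12-17")
ADULT_BINS: tuple[str, ...] = (
    "25-29", "30-34", "35-39", "40-44", "45-49", "50-54",
    "55-59", "60-64", "65-69", "70-74", "75-79", "80+",
)
AGE_BINS: tuple[str, ...] = CHILD_BINS + ("18-24",) + ADULT_BINS

#: share of total population in each age bin (approximate U.S. structure)
AGE_FRACTIONS: dict[str, float] = {
    "0-4": 0.059, "5-11": 0.086, "12-17": 0.076, "18-24": 0.092,
    "25-29": 0.071, "30-34": 0.068, "35-39": 0.066, "40-44": 0.061,
    "45-49": 0.062, "50-54": 0.063, "55-59": 0.067, "60-64": 0.061,
    "65-69": 0.051, "70-74": 0.039, "75-79": 0.026, "80+": 0.052,
}

#: all-cause mortality, deaths per person per year, by adult age bin
DEFAULT_MORTALITY: dict[str, float] = {
    "25-29": 0.0013, "30-34": 0.0016, "35-39": 0.0019, "40-44": 0.0023,
    "45-49": 0.0031, "50-54": 0.0047, "55-59": 0.0072, "60-64": 0.0100,
    "65-69": 0.0150, "70-74": 0.0220, "75-79": 0.0360, "80+": 0.0840,
}

#: childhood asthma onset, new cases per at-risk child per year
#: (averages 12.5 per 1,000 across the three child bins)
DEFAULT_ASTHMA_INCIDENCE: dict[str, float] = {"0-4": 0.019, "5-11": 0.0115, "12-17": 0.007}

#: fraction of children currently with asthma (removed from the at-risk pool)
DEFAULT_ASTHMA_PREVALENCE: dict[str, float] = {"0-4": 0.035, "5-11": 0.088, "12-17": 0.105}

#: six NCHS-style urbanization classes, ordered by decreasing density
URBANIZATION_CLASSES: tuple[str, ...] = (
    "large-central-metro", "large-fringe-metro", "medium-metro",
    "small-metro", "micropolitan", "noncore",
)


# ---------------------------------------------------------------------------
# domain spec
# ---------------------------------------------------------------------------

class SyntheticDomainSpec(BaseModel):
    """Parameters that fully determine a synthetic domain.

    ``density_mu``/``density_sigma`` are the log-normal parameters of the
    baseline population density field, in ln(persons/km2); urban hotspots
    multiply that field so that cities with orders-of-magnitude higher
    density than rural areas exist, as in the real county distribution.
    """

    model_config = {"frozen": True}

    n_cells: int = Field(400, ge=1)
    n_counties: int = Field(12, ge=1)
    seed: int = Field(0, ge=0)
    domain_km: float = Field(240.0, gt=0)
    density_mu: float = 3.0
    density_sigma: float = Field(1.1, gt=0)
    n_hotspots: int = Field(3, ge=0)
    hotspot_amplitude: float = Field(60.0, ge=0)
    hotspot_scale_km: float = Field(18.0, gt=0)
    miles_per_capita: float = Field(20.7, gt=0)  # annual school-bus VMT per resident
    decay_lengths_km: dict[str, float] = Field(
        default_factory=lambda: {
            "PM25_primary": 5.0, "NOx": 50.0, "SO2": 50.0, "NH3": 50.0, "VOC": 50.0,
        }
    )
    kernel_peak: dict[str, float] = Field(
        default_factory=lambda: {
            "PM25_primary": 5e-3, "NOx": 6e-5, "SO2": 4e-5, "NH3": 3e-5, "VOC": 2e-5,
        }
    )
    truncation: float = Field(1e-12, gt=0, lt=1)

    @model_validator(mode="after")
    def _check(self) -> "SyntheticDomainSpec":
        if self.n_counties > self.n_cells:
            raise ValueError("n_counties cannot exceed n_cells")
        for pol in POLLUTANTS:
            if self.decay_lengths_km.get(pol, 0) <= 0:
                raise ValueError(f"decay length for {pol} must be positive")
            if self.kernel_peak.get(pol, 0) <= 0:
                raise ValueError(f"kernel peak for {pol} must be positive")
        primary = self.decay_lengths_km["PM25_primary"]
        for pol in SECONDARY_POLLUTANTS:
            if not primary < self.decay_lengths_km[pol]:
                raise ValueError(
                    "primary PM2.5 decay length must be strictly smaller than "
                    f"the secondary-species length ({pol})"
                )
        return self


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def largest_remainder(values: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to ``total``.

    Each value gets its floor share; the remaining units go to the largest
    fractional remainders (ties broken by position, which keeps the result
    deterministic).
    """
    values = np.asarray(values, dtype=float)
    if np.any(values < 0):
        raise ValueError("values must be non-negative")
    if total < 0:
        raise ValueError("total must be non-negative")
    if values.sum() == 0:
        # no weights to apportion by: everything lands on the first slot
        out = np.zeros(values.size, dtype=np.int64)
        if total and values.size:
            out[0] = total
        return out
    scaled = values * (total / values.sum())
    floors = np.floor(scaled).astype(np.int64)
    short = total - int(floors.sum())
    if short > 0:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


# ---------------------------------------------------------------------------
# domain generation
# ---------------------------------------------------------------------------

def generate_domain(spec: SyntheticDomainSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cell and county tables for a synthetic domain.

    Returns
    -------
    cells
        One row per cell: cell_id, county_id, x_km, y_km, area_km2,
        density, population, urbanization_class, and one integer population
        column ``pop_<age bin>`` per age bin.
    counties
        One row per county: county_id, n_cells, population, area_km2,
        density, urbanization_class, annual_vmt.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_cells

    # jittered lattice of cell centroids over a square domain
    side = int(np.ceil(np.sqrt(n)))
    spacing = spec.domain_km / side
    gx, gy = np.meshgrid(np.arange(side), np.arange(side))
    xy = (np.column_stack([gx.ravel(), gy.ravel()])[:n] + 0.5) * spacing
    xy += rng.uniform(-0.25, 0.25, size=xy.shape) * spacing

    # log-normal density field amplified around urban hotspots
    density = np.exp(rng.normal(spec.density_mu, spec.density_sigma, size=n))
    hotspots = rng.uniform(0.15, 0.85, size=(spec.n_hotspots, 2)) * spec.domain_km
    for hx, hy in hotspots:
        d2 = (xy[:, 0] - hx) ** 2 + (xy[:, 1] - hy) ** 2
        density *= 1.0 + spec.hotspot_amplitude * np.exp(-d2 / (2 * spec.hotspot_scale_km**2))

    # variable resolution: denser areas get smaller cells, total area conserved
    raw_area = 1.0 / np.sqrt(density)
    area = raw_area * (spec.domain_km**2 / raw_area.sum())
    pop_real = density * area

    # counties: contiguous nearest-seed regions; seeds drawn density-weighted
    # so that at least some counties are compact urban cores
    seed_idx = rng.choice(n, size=spec.n_counties, replace=False, p=density / density.sum())
    county_of = np.argmin(distance_matrix(xy, xy[seed_idx]), axis=1)
    # guarantee each seed cell belongs to its own county (ties, jitter)
    county_of[seed_idx] = np.arange(spec.n_counties)

    # integer populations: county totals exact, then cell age splits exact
    population = np.zeros(n, dtype=np.int64)
    for c in range(spec.n_counties):
        mask = county_of == c
        target = int(round(pop_real[mask].sum()))
        population[mask] = largest_remainder(pop_real[mask], target)

    cells = pd.DataFrame(
        {
            "cell_id": np.arange(n, dtype=np.int64),
            "county_id": county_of.astype(np.int64),
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "area_km2": area,
            "density": population / area,
            "population": population,
        }
    )

    # per-cell urbanization class by population-density sextile
    ranks = cells["density"].rank(method="first", ascending=False).to_numpy()
    sextile = np.minimum(((ranks - 1) * 6 / n).astype(int), 5)
    cells["urbanization_class"] = [URBANIZATION_CLASSES[s] for s in sextile]

    fracs = np.array([AGE_FRACTIONS[b] for b in AGE_BINS])
    age_counts = np.vstack(
        [largest_remainder(fracs, int(p)) for p in population]
    )
    for j, b in enumerate(AGE_BINS):
        cells[f"pop_{b}"] = age_counts[:, j]

    counties = (
        cells.groupby("county_id")
        .agg(n_cells=("cell_id", "size"), population=("population", "sum"),
             area_km2=("area_km2", "sum"))
        .reset_index()
    )
    counties["density"] = counties["population"] / counties["area_km2"]
    cranks = counties["density"].rank(method="first", ascending=False).to_numpy()
    csex = np.minimum(((cranks - 1) * 6 / len(counties)).astype(int), 5)
    counties["urbanization_class"] = [URBANIZATION_CLASSES[s] for s in csex]
    # annual school-bus activity scales with population, with mild noise
    counties["annual_vmt"] = counties["population"] * spec.miles_per_capita * np.exp(
        rng.normal(0.0, 0.15, size=len(counties))
    )
    return cells, counties


def generate_srm(cells: pd.DataFrame, spec: SyntheticDomainSpec) -> SourceReceptorMatrix:
    """Gaussian-kernel pseudo source-receptor matrix.

    entry(s, r, p) = k_p * exp(-dist(s,r)^2 / (2 L_p^2)), stored sparsely
    after zeroing entries below ``truncation`` times the self-cell value.
    The self-cell entry is therefore the row maximum for every source, and
    the short primary-PM2.5 decay length concentrates its impacts near the
    source while secondary species spread over the whole domain.
    """
    if len(cells) == 0:
        raise ValueError("cell table is empty")
    from scipy import sparse as sp

    xy = cells[["x_km", "y_km"]].to_numpy(float)
    d2 = distance_matrix(xy, xy) ** 2
    mats = {}
    for pol in POLLUTANTS:
        k = spec.kernel_peak[pol]
        L = spec.decay_lengths_km[pol]
        dense = k * np.exp(-d2 / (2 * L**2))
        dense[dense < spec.truncation * k] = 0.0
        mats[pol] = sp.csr_matrix(dense)
    return SourceReceptorMatrix(matrices=mats, cell_ids=cells["cell_id"].to_numpy(np.int64))


# ---------------------------------------------------------------------------
# emission factors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EmissionFactorSet:
    """Tailpipe emission factors for one bus technology, g/mile.

    Values exclude tire and brake wear (similar between diesel and electric
    buses, hence irrelevant to replacement benefits); ``tire_brake_share``
    records the fraction that was removed, for provenance.
    """

    source_label: str
    ef_g_per_mile: Mapping[str, float]
    tire_brake_share: Mapping[str, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        for pol, v in self.ef_g_per_mile.items():
            if pol not in POLLUTANTS:
                raise ValueError(f"unknown pollutant {pol!r}")
            if v < 0:
                raise ValueError("emission factors must be non-negative")

    @property
    def is_zero(self) -> bool:
        return all(v == 0 for v in self.ef_g_per_mile.values())


#: anchor tailpipe emission factors, g/mile.  MY2005:MY2010 ratios are pinned
#: at 12x (primary PM2.5), 4x (NOx) and 5x (VOC); the 2017 fleet average sits
#: between the model-year anchors, and the electric set is all zero.
_EF_TABLE: dict[str, dict[str, float]] = {
    "MY2005": {"PM25_primary": 0.36, "NOx": 16.0, "SO2": 0.012, "NH3": 0.015, "VOC": 1.25},
    "MY2010": {"PM25_primary": 0.03, "NOx": 4.0, "SO2": 0.012, "NH3": 0.015, "VOC": 0.25},
    "MY2020": {"PM25_primary": 0.006, "NOx": 0.9, "SO2": 0.010, "NH3": 0.015, "VOC": 0.05},
    "fleet-average-2017": {
        "PM25_primary": 0.12, "NOx": 8.0, "SO2": 0.012, "NH3": 0.015, "VOC": 0.55,
    },
    "electric": {p: 0.0 for p in POLLUTANTS},
}

_ANCHOR_YEARS = {"MY2005": 2005, "MY2010": 2010, "MY2020": 2020}


def generate_emission_factors(
    model_years: Sequence[int] | None = None, seed: int = 0
) -> list[EmissionFactorSet]:
    """Emission-factor sets for the default fixture plus optional extra years.

    The default fixture (``model_years=None``) returns the five anchor sets
    exactly.  Extra model years between 1995 and 2030 are log-interpolated
    between the anchors with small seeded lognormal noise, emulating the
    steep decline of per-mile diesel emissions across model years.
    """
    sets = [
        EmissionFactorSet(source_label=label, ef_g_per_mile=dict(efs))
        for label, efs in _EF_TABLE.items()
    ]
    if model_years:
        rng = np.random.default_rng(seed)
        ay = sorted(_ANCHOR_YEARS.values())
        for year in model_years:
            if not 1995 <= year <= 2030:
                raise ValueError(f"model year {year} outside plausible range 1995-2030")
            label = f"MY{year}"
            if label in _EF_TABLE:
                continue
            efs = {}
            for pol in POLLUTANTS:
                logs = np.log([_EF_TABLE[f"MY{y}"][pol] for y in ay])
                val = np.exp(np.interp(year, ay, logs))
                efs[pol] = float(val * np.exp(rng.normal(0.0, 0.05)))
            sets.append(EmissionFactorSet(source_label=label, ef_g_per_mile=efs))
    return sets


def default_rates_table() -> pd.DataFrame:
    """National age-specific baseline rates as a long table."""
    rows = []
    for b in AGE_BINS:
        rows.append(
            {
                "age_bin": b,
                "mortality_rate": DEFAULT_MORTALITY.get(b, 0.0),
                "asthma_incidence": DEFAULT_ASTHMA_INCIDENCE.get(b, 0.0),
                "asthma_prevalence": DEFAULT_ASTHMA_PREVALENCE.get(b, 0.0),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fixture bundle I/O
# ---------------------------------------------------------------------------

@dataclass
class FixtureBundle:
    """Everything downstream stages need, as plain tables plus the SRM."""

    spec: SyntheticDomainSpec
    cells: pd.DataFrame
    counties: pd.DataFrame
    srm: SourceReceptorMatrix
    emission_factors: dict[str, EmissionFactorSet]
    rates: pd.DataFrame


def build_fixture(spec: SyntheticDomainSpec) -> FixtureBundle:
    """Generate a complete, self-consistent fixture bundle from a spec."""
    cells, counties = generate_domain(spec)
    srm = generate_srm(cells, spec)
    efs = {s.source_label: s for s in generate_emission_factors(seed=spec.seed)}
    return FixtureBundle(
        spec=spec, cells=cells, counties=counties, srm=srm,
        emission_factors=efs, rates=default_rates_table(),
    )


_FLOAT_FMT = "%.12g"


def write_fixture(bundle: FixtureBundle, path: str | Path) -> Path:
    """Serialize a bundle to delimited text + a JSON manifest.

    The layout is deliberately plain: TSV tables for cells, counties,
    emission factors and rates; the SRM in coordinate format
    (source_id, receptor_id, pollutant, value); and a manifest recording the
    generating spec so a bundle can be regenerated bit-identically.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    kw = dict(sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")
    bundle.cells.to_csv(path / "cells.tsv", **kw)
    bundle.counties.to_csv(path / "counties.tsv", **kw)
    bundle.rates.to_csv(path / "rates.tsv", **kw)
    bundle.srm.to_frame().to_csv(path / "srm.tsv", **kw)
    ef_rows = []
    for label in sorted(bundle.emission_factors):
        efs = bundle.emission_factors[label]
        for pol in POLLUTANTS:
            ef_rows.append(
                {"source_label": label, "pollutant": pol,
                 "ef_g_per_mile": efs.ef_g_per_mile.get(pol, 0.0)}
            )
    pd.DataFrame(ef_rows).to_csv(path / "emission_factors.tsv", **kw)
    manifest = {"format": "busbenefits-fixture-v1", "spec": bundle.spec.model_dump()}
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def read_fixture(path: str | Path) -> FixtureBundle:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    spec = SyntheticDomainSpec(**manifest["spec"])
    cells = pd.read_csv(path / "cells.tsv", sep="\t")
    counties = pd.read_csv(path / "counties.tsv", sep="\t")
    rates = pd.read_csv(path / "rates.tsv", sep="\t")
    srm = SourceReceptorMatrix.from_frame(
        pd.read_csv(path / "srm.tsv", sep="\t"), cells["cell_id"]
    )
    ef_df = pd.read_csv(path / "emission_factors.tsv", sep="\t")
    efs = {
        str(label): EmissionFactorSet(
            source_label=str(label),
            ef_g_per_mile=dict(zip(grp["pollutant"], grp["ef_g_per_mile"])),
        )
        for label, grp in ef_df.groupby("source_label")
    }
    return FixtureBundle(
        spec=spec, cells=cells, counties=counties, srm=srm,
        emission_factors=efs, rates=rates,
    )
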