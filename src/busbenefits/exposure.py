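"""Source-receptor dispersion stage.

A source-receptor matrix (SRM) is a precomputed linear map from a marginal
emission rate at a source cell to the marginal change in annual-average
ambient PM2.5 concentration at every receptor cell, one matrix per emitted
pollutant (directly emitted PM2.5 plus the precursor gases NOx, SO2, NH3 and
VOC that form PM2.5 in the atmosphere).

Unit contract used throughout the package:

    srm entry  : (ug/m3) of ambient PM2.5 per (metric ton/year) emitted
    emissions  : metric tons/year per (cell, pollutant)
    delta C    : ug/m3 per receptor cell, per pollutant channel

Missing sparse entries mean exactly zero contribution.  Secondary chemistry
is treated as linear, which real nitrate/ammonium formation is not; that
nonlinearity is explicitly out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import sparse

from .params import POLLUTANTS

SRM_UNITS = "(ug/m3)/(t/yr)"


@dataclass
class SourceReceptorMatrix:
    """Per-pollutant sparse matrices indexed [source, receptor].

    ``cell_ids`` maps matrix position -> cell identifier; all matrices share
    that index.
    """

    matrices: dict[str, sparse.csr_matrix]
    cell_ids: np.ndarray
    units: str = SRM_UNITS

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        n = self.cell_ids.size
        for pol, m in self.matrices.items():
            if pol not in POLLUTANTS:
                raise ValueError(f"unknown pollutant {pol!r}")
            if m.shape != (n, n):
                raise ValueError(f"matrix for {pol} has shape {m.shape}, expected {(n, n)}")
            if m.nnz and m.data.min() < 0:
                raise ValueError(f"negative source-receptor entries for {pol}")
        self._pos = {int(c): i for i, c in enumerate(self.cell_ids)}

    @property
    def pollutants(self) -> tuple[str, ...]:
        return tuple(self.matrices)

    @property
    def n_cells(self) -> int:
        return self.cell_ids.size

    def position(self, cell_id: int) -> int:
        try:
            return self._pos[int(cell_id)]
        except KeyError:
            raise KeyError(f"cell {cell_id} not in source-receptor matrix") from None

    def entry(self, source_id: int, receptor_id: int, pollutant: str) -> float:
        m = self.matrices[pollutant]
        return float(m[self.position(source_id), self.position(receptor_id)])

    def to_frame(self) -> pd.DataFrame:
        """Coordinate-format long table (source_id, receptor_id, pollutant, value)."""
        parts = []
        for pol in sorted(self.matrices):
            coo = self.matrices[pol].tocoo()
            parts.append(
                pd.DataFrame(
                    {
                        "source_id": self.cell_ids[coo.row],
                        "receptor_id": self.cell_ids[coo.col],
                        "pollutant": pol,
                        "value": coo.data,
                    }
                )
            )
        out = pd.concat(parts, ignore_index=True)
        return out.sort_values(["pollutant", "source_id", "receptor_id"], ignore_index=True)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, cell_ids: Iterable[int]) -> "SourceReceptorMatrix":
        cell_ids = np.asarray(list(cell_ids), dtype=np.int64)
        pos = {int(c): i for i, c in enumerate(cell_ids)}
        n = cell_ids.size
        mats = {}
        for pol, grp in frame.groupby("pollutant"):
            rows = grp["source_id"].map(pos).to_numpy()
            cols = grp["receptor_id"].map(pos).to_numpy()
            mats[str(pol)] = sparse.csr_matrix(
                (grp["value"].to_numpy(float), (rows, cols)), shape=(n, n)
            )
        return cls(matrices=mats, cell_ids=cell_ids)


@dataclass
class EmissionRateField:
    """Per-(cell, pollutant) emission rates in t/yr, aligned to an SRM index."""

    rates: dict[str, np.ndarray]
    cell_ids: np.ndarray
    units: str = "t/yr"

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        for pol, r in self.rates.items():
            r = np.asarray(r, dtype=float)
            if r.shape != self.cell_ids.shape:
                raise ValueError(f"rate vector for {pol} misaligned with cell index")
            if np.any(r < 0):
                raise ValueError(f"negative emission rates for {pol}")
            self.rates[pol] = r

    def __add__(self, other: "EmissionRateField") -> "EmissionRateField":
        if not np.array_equal(self.cell_ids, other.cell_ids):
            raise ValueError("emission fields defined on different cell indexes")
        pols = set(self.rates) | set(other.rates)
        z = np.zeros_like(self.cell_ids, dtype=float)
        return EmissionRateField(
            rates={p: self.rates.get(p, z) + other.rates.get(p, z) for p in pols},
            cell_ids=self.cell_ids,
        )

    def scaled(self, alpha: float) -> "EmissionRateField":
        if alpha < 0:
            raise ValueError("scale factor must be non-negative")
        return EmissionRateField(
            rates={p: alpha * r for p, r in self.rates.items()}, cell_ids=self.cell_ids
        )


@dataclass
class DeltaConcentration:
    """Marginal ambient PM2.5 change per receptor, kept per pollutant channel."""

    by_pollutant: dict[str, np.ndarray]
    cell_ids: np.ndarray

    def total(self) -> np.ndarray:
        return np.sum(list(self.by_pollutant.values()), axis=0)

    def to_frame(self) -> pd.DataFrame:
        parts = [
            pd.DataFrame({"receptor_id": self.cell_ids, "pollutant": p, "delta_c": v})
            for p, v in sorted(self.by_pollutant.items())
        ]
        return pd.concat(parts, ignore_index=True)


def allocate_county_emissions(
    county_emissions: Mapping[int, Mapping[str, float]] | pd.DataFrame,
    cells: pd.DataFrame,
    uniform_area_fallback: bool = False,
) -> EmissionRateField:
    """Spread county emission totals over the county's cells by population.

    The within-county spatial distribution of school-bus activity is assumed
    to follow that of population, so each cell receives

        E_cell = E_county * pop_cell / pop_county.

    Parameters
    ----------
    county_emissions
        Either ``{county_id: {pollutant: t/yr}}`` or a long DataFrame with
        columns (county_id, pollutant, tons_per_year).
    cells
        Cell table with columns cell_id, county_id, population.
    uniform_area_fallback
        If a referenced county has zero population, spread by cell area
        instead of raising.
    """
    if isinstance(county_emissions, pd.DataFrame):
        it: dict[int, dict[str, float]] = {}
        for row in county_emissions.itertuples(index=False):
            it.setdefault(int(row.county_id), {})[str(row.pollutant)] = float(row.tons_per_year)
        county_emissions = it

    cell_ids = cells["cell_id"].to_numpy(np.int64)
    rates: dict[str, np.ndarray] = {}
    for county_id, by_pol in county_emissions.items():
        mask = (cells["county_id"] == county_id).to_numpy()
        if not mask.any():
            raise KeyError(f"county {county_id} has no cells in the domain")
        pop = cells.loc[mask, "population"].to_numpy(float)
        if pop.sum() > 0:
            share = pop / pop.sum()
        elif uniform_area_fallback:
            area = cells.loc[mask, "area_km2"].to_numpy(float)
            share = area / area.sum()
        else:
            raise ValueError(
                f"county {county_id} has zero population; "
                "enable uniform_area_fallback to spread by area"
            )
        for pol, tons in by_pol.items():
            if tons < 0:
                raise ValueError("county emissions must be non-negative")
            vec = rates.setdefault(pol, np.zeros(cell_ids.size))
            vec[mask] += tons * share
    return EmissionRateField(rates=rates, cell_ids=cell_ids)


def apply_srm(field: EmissionRateField, srm: SourceReceptorMatrix) -> DeltaConcentration:
    """Propagate an emission field through the SRM: dC_r = sum_s,p srm[s,r,p] E[s,p]."""
    if not np.array_equal(field.cell_ids, srm.cell_ids):
        raise ValueError("emission field and SRM are on different cell indexes")
    if field.units != "t/yr" or srm.units != SRM_UNITS:
        raise ValueError(
            f"unit mismatch: field {field.units!r} vs srm {srm.units!r}"
        )
    missing = set(field.rates) - set(srm.matrices)
    if missing:
        raise KeyError(f"SRM lacks pollutants {sorted(missing)}")
    out = {
        pol: np.asarray(srm.matrices[pol].T @ field.rates[pol]).ravel()
        for pol in field.rates
    }
    return DeltaConcentration(by_pollutant=out, cell_ids=field.cell_ids)


def pseudo_intake_fraction(
    srm: SourceReceptorMatrix,
    cells: pd.DataFrame,
    source_cell: int,
    pollutant: str,
) -> float:
    """Population-weighted mean concentration change per unit emission (dC/dE).

    This is the 'pseudo intake fraction': the average exposure the whole
    population receives per t/yr emitted at ``source_cell``, in
    (ug/m3)/(t/yr).  It is the exposure kernel of the multiplicative damage
    decomposition slope x intake x emission-factor x baseline-rate x value.
    """
    pop = (
        cells.set_index("cell_id")["population"]
        .reindex(srm.cell_ids)
        .to_numpy(float)
    )
    total = pop.sum()
    if total <= 0:
        raise ValueError("domain population is zero")
    row = np.asarray(
        srm.matrices[pollutant][srm.position(source_cell)].todense()
    ).ravel()
    return float(np.dot(pop, row) / total)
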