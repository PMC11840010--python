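"""Scaling single-cell rates to the community.

The relative contribution of the active algal population to bulk uptake
of a substrate is

    contribution (%) = 100 * (rate_cell * N_cell) / rate_bulk

with rate_cell the mean per-cell assimilation rate (pmol or fmol
cell^-1 day^-1), N_cell the abundance of *active* cells (cells L^-1)
and rate_bulk the bulk assimilation rate (µmol L^-1 day^-1). Its
one-sigma uncertainty combines the relative SDs of the three factors in
quadrature (first-order, delta-method propagation for a
product/quotient of independent factors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceEstimate",
    "ContributionResult",
    "active_abundance",
    "contribution",
    "propagate_contribution_uncertainty",
    "poc_corrected_abundance",
    "contribution_table",
]

_UNIT_TO_UMOL = {"pmol": 1e-6, "fmol": 1e-9}


@dataclass(frozen=True)
class AbundanceEstimate:
    """Total algal abundance (cells ml^-1) and its active fraction."""

    total_cells_per_ml: float = 16.2e3
    sd_cells_per_ml: float = 1.2e3
    active_fraction: float = 0.90
    source: str = "counts"  # or "poc_corrected"

    def __post_init__(self) -> None:
        if self.total_cells_per_ml < 0 or self.sd_cells_per_ml < 0:
            raise ValueError("abundance and its SD must be >= 0")
        if not 0.0 <= self.active_fraction <= 1.0:
            raise ValueError("active_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class ContributionResult:
    """Algal share of a bulk uptake rate, in percent, with uncertainty."""

    percent: float
    sd_percent: float
    substrate: str
    timepoint: str
    abundance_source: str

    def __post_init__(self) -> None:
        if self.percent < 0 or self.sd_percent < 0:
            raise ValueError("percent and sd must be >= 0")


def active_abundance(est: AbundanceEstimate) -> tuple[float, float]:
    """Active cells per litre (mean, SD) from a per-ml count estimate.

    The fixed active fraction scales mean and SD identically; its own
    (binomial) uncertainty is not propagated because no SD is available
    for it.
    """
    factor = est.active_fraction * 1000.0  # ml -> L
    return est.total_cells_per_ml * factor, est.sd_cells_per_ml * factor


def contribution(cell_rate: float, active_cells_per_l: float,
                 bulk_rate: float, cell_rate_unit: str = "pmol") -> float:
    """Percent of the bulk uptake accounted for by the active algae.

    ``cell_rate`` is per cell per day in ``cell_rate_unit`` (pmol or
    fmol); ``bulk_rate`` is µmol L^-1 day^-1.
    """
    if bulk_rate <= 0:
        raise ValueError("bulk rate must be > 0")
    try:
        to_umol = _UNIT_TO_UMOL[cell_rate_unit]
    except KeyError:
        raise ValueError(f"unknown cell rate unit {cell_rate_unit!r}") from None
    return 100.0 * (cell_rate * to_umol * active_cells_per_l) / bulk_rate


def propagate_contribution_uncertainty(percent: float,
                                       *factors: tuple[float, float]) -> float:
    """One-sigma SD of a product/quotient estimate, in percent.

    Each factor is a ``(mean, sd)`` pair; relative SDs combine in
    quadrature and scale the point estimate:
    sd% = percent * sqrt(sum_i (sd_i / mean_i)^2).
    """
    rel_sq = 0.0
    for mean, sd in factors:
        if mean <= 0:
            raise ValueError("factor means must be > 0")
        if sd < 0:
            raise ValueError("factor SDs must be >= 0")
        rel_sq += (sd / mean) ** 2
    return float(percent) * float(np.sqrt(rel_sq))


def poc_corrected_abundance(abundance_t0: AbundanceEstimate,
                            poc_t0: float, poc_tx: float) -> AbundanceEstimate:
    """Abundance rescaled by the fractional POC change since T0.

    Accounts for heterogeneous biomass distribution between bottles:
    the T0 count is scaled by poc_Tx / poc_T0 (SD scaled identically).
    """
    if poc_t0 <= 0:
        raise ValueError("T0 POC must be > 0")
    if poc_tx < 0:
        raise ValueError("POC must be >= 0")
    ratio = poc_tx / poc_t0
    return AbundanceEstimate(
        total_cells_per_ml=abundance_t0.total_cells_per_ml * ratio,
        sd_cells_per_ml=abundance_t0.sd_cells_per_ml * ratio,
        active_fraction=abundance_t0.active_fraction,
        source="poc_corrected",
    )


# --------------------------------------------------------------------------
# table-level processing

#: bulk treatment whose rate is the denominator for each substrate
_SUBSTRATE_TREATMENT = {"DIC": "control", "NH4": "NH4", "NO3": "NO3"}
#: cell-rate column (and unit) that is the numerator for each substrate
_SUBSTRATE_CELL_QUANTITY = {"DIC": ("c_fix_pmol_d", "pmol"),
                            "NH4": ("n_assim_fmol_d", "fmol"),
                            "NO3": ("n_assim_fmol_d", "fmol")}


def contribution_table(cell_summary: pd.DataFrame, bulk_rates: pd.DataFrame,
                       abundance: AbundanceEstimate,
                       bulk: pd.DataFrame | None = None) -> pd.DataFrame:
    """Algal contribution per substrate x timepoint, with propagated SD.

    ``cell_summary`` is the active-population summary from
    :func:`cryosip.cells.population_summary`; ``bulk_rates`` the tidy
    frame from :func:`cryosip.bulk.bulk_rate_table`. When the raw
    ``bulk`` bottle table is given, a second set of rows uses the
    POC-change-corrected abundance.
    """
    rows = []
    variants: list[tuple[str, AbundanceEstimate | None]] = [("counts", abundance)]
    for substrate, treatment in _SUBSTRATE_TREATMENT.items():
        qty_col, unit = _SUBSTRATE_CELL_QUANTITY[substrate]
        for timepoint in ("T1", "T2"):
            cell_row = cell_summary[
                (cell_summary["treatment"] == treatment)
                & (cell_summary["timepoint"] == timepoint)
                & (cell_summary["quantity"] == qty_col)]
            bulk_row = bulk_rates[
                (bulk_rates["treatment"] == treatment)
                & (bulk_rates["timepoint"] == timepoint)
                & (bulk_rates["substrate"] == substrate)
                & (bulk_rates["kind"] == "assimilation")]
            if cell_row.empty or bulk_row.empty:
                continue
            cell_mean = float(cell_row["mean"].iloc[0])
            cell_sd = float(cell_row["sd"].iloc[0])
            bulk_mean = float(bulk_row["mean"].iloc[0])
            bulk_sd = float(bulk_row["sd"].iloc[0])
            if not np.isfinite(bulk_sd):
                bulk_sd = 0.0
            if not np.isfinite(cell_sd):
                cell_sd = 0.0

            for source, est in _abundance_variants(
                    abundance, bulk, treatment, timepoint):
                n_mean, n_sd = active_abundance(est)
                pct = contribution(cell_mean, n_mean, bulk_mean, unit)
                sd_pct = propagate_contribution_uncertainty(
                    pct, (cell_mean, cell_sd), (n_mean, n_sd),
                    (bulk_mean, bulk_sd))
                rows.append({
                    "substrate": substrate,
                    "timepoint": timepoint,
                    "abundance_source": source,
                    "percent": pct,
                    "sd_percent": sd_pct,
                })
    return pd.DataFrame.from_records(
        rows, columns=["substrate", "timepoint", "abundance_source",
                       "percent", "sd_percent"])


def _abundance_variants(abundance, bulk, treatment, timepoint):
    yield "counts", abundance
    if bulk is None:
        return
    t0 = bulk[bulk["timepoint"] == "T0"]["poc_umol_l"]
    tx = bulk[(bulk["timepoint"] == timepoint)
              & (bulk["treatment"] == treatment)]["poc_umol_l"]
    if t0.empty or tx.empty:
        return
    yield "poc_corrected", poc_corrected_abundance(
        abundance, float(t0.mean()), float(tx.mean()))
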