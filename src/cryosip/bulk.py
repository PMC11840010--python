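"""Bulk (filter-level) assimilation rates, growth rates and derived chemistry.

Rates follow the standard isotope mass-balance model for a tracer
incubation of length ``dt`` days:

* assimilation rate = (excess_POM / excess_pool) * POM / dt
  (µmol element L^-1 day^-1), and
* growth rate mu = log2[excess_pool / (excess_pool - excess_POM)] / dt
  (day^-1), assuming exponential growth, so that mu = 1/day means the
  biomass element pool doubles daily; doubling time = 1 / mu.

The same formulas apply to carbon (POC against the 13C-DIC pool) and
nitrogen (PON against the 15N-NH4+ or 15N-NO3- pool), and to single
cells (see :mod:`cryosip.cells`). Rates are net over the incubation; no
respiration correction is attempted.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .isotope import NaturalAbundance, pool_excess_timeavg

__all__ = [
    "Incubation",
    "RateResult",
    "bulk_assimilation_rate",
    "biomass_normalized_rate",
    "umol_to_mg",
    "growth_rate",
    "doubling_time",
    "poc_pon_ratio",
    "derived_organic_nutrients",
    "detection_limits",
    "bulk_rate_table",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Incubation:
    """Sampling schedule of a tracer incubation, in elapsed hours."""

    t1_hours: float = constants.T1_HOURS
    t2_hours: float = constants.T2_HOURS

    def __post_init__(self) -> None:
        if not 0.0 < self.t1_hours < self.t2_hours:
            raise ValueError("need 0 < t1 < t2")

    def dt_days(self, timepoint: str) -> float:
        """Elapsed time since tracer addition, in days."""
        hours = {"T1": self.t1_hours, "T2": self.t2_hours}
        try:
            return hours[timepoint] / constants.HOURS_PER_DAY
        except KeyError:
            raise ValueError(f"unknown timepoint {timepoint!r}") from None


@dataclass(frozen=True)
class RateResult:
    """A rate estimate with its uncertainty and provenance."""

    kind: str  # {"assimilation", "growth", "doubling"}
    substrate: str  # {"DIC", "NH4", "NO3"}
    value: float
    units: str
    sd: float | None = None
    n: int | None = None
    basis: str = "bulk"  # {"bulk", "cell"}

    def __post_init__(self) -> None:
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be >= 0")


def bulk_assimilation_rate(excess_pom, excess_pool, pom_conc, dt):
    """Bulk assimilation rate in µmol element L^-1 day^-1.

    ``excess_pom`` / ``excess_pool`` are atom% excess of the particulate
    matter and of the dissolved source pool; ``pom_conc`` is µmol L^-1;
    ``dt`` is the incubation length in days.
    """
    excess_pool = np.asarray(excess_pool, dtype=float)
    if np.any(excess_pool <= 0):
        raise ValueError(
            "source pool atom% excess must be > 0 (tracer accounting broken)")
    if np.any(np.asarray(dt, dtype=float) <= 0):
        raise ValueError("dt must be > 0 days")
    if np.any(np.asarray(pom_conc, dtype=float) < 0):
        raise ValueError("POM concentration must be >= 0")
    out = (np.asarray(excess_pom, dtype=float) / excess_pool) \
        * np.asarray(pom_conc, dtype=float) / np.asarray(dt, dtype=float)
    return out if np.ndim(out) else float(out)


def umol_to_mg(umol_per_l, element: str):
    """Convert µmol element L^-1 to mg element L^-1 via the atomic mass."""
    return np.asarray(umol_per_l, dtype=float) \
        * constants.ATOMIC_MASS[element] / 1000.0


def biomass_normalized_rate(rate, pom_mass_mg):
    """Biomass-specific rate: µmol element per mg POM-element per day."""
    pom_mass_mg = np.asarray(pom_mass_mg, dtype=float)
    if np.any(pom_mass_mg <= 0):
        raise ValueError("POM mass must be > 0")
    out = np.asarray(rate, dtype=float) / pom_mass_mg
    return out if np.ndim(out) else float(out)


def growth_rate(excess_pool, excess_biomass, dt):
    """Isotope-based specific growth rate (day^-1).

    mu = log2[E_pool / (E_pool - E_biomass)] / dt. Biomass cannot be more
    labelled than its source pool; that situation raises.
    """
    e_pool = np.asarray(excess_pool, dtype=float)
    e_bio = np.asarray(excess_biomass, dtype=float)
    dt = np.asarray(dt, dtype=float)
    if np.any(e_pool <= 0):
        raise ValueError("source pool atom% excess must be > 0")
    if np.any(dt <= 0):
        raise ValueError("dt must be > 0 days")
    if np.any(e_bio >= e_pool):
        raise ValueError("biomass more labelled than its source pool")
    if np.any(e_bio < 0):
        raise ValueError("biomass atom% excess must be >= 0")
    out = np.log2(e_pool / (e_pool - e_bio)) / dt
    return out if np.ndim(out) else float(out)


def doubling_time(growth):
    """Population doubling time in days: 1 / growth rate.

    Non-positive growth has no doubling time; NaN is returned with a
    warning rather than raising, so summary tables keep their shape.
    """
    g = np.asarray(growth, dtype=float)
    bad = g <= 0
    if np.any(bad):
        warnings.warn("doubling time undefined for non-positive growth; "
                      "returning NaN", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(bad, np.nan, 1.0 / np.where(bad, np.nan, g))
    return out if out.ndim else float(out)


def poc_pon_ratio(poc, pon):
    """Molar POC:PON ratio of the particulate matter."""
    pon = np.asarray(pon, dtype=float)
    if np.any(pon <= 0):
        raise ValueError("PON must be > 0")
    out = np.asarray(poc, dtype=float) / pon
    return out if np.ndim(out) else float(out)


def derived_organic_nutrients(tdn, din_components, tdp=None, po4=None):
    """Dissolved organic N and P by difference.

    DON = TDN - DIN where DIN sums the inorganic N species present
    (NO3-, NH4+, NO2-); DOP = TDP - PO4(3-). Negative differences are
    below-detection artefacts: preserved, but flagged with a warning.
    Returns ``(don, dop)``; ``dop`` is None when TDP/PO4 are not given.
    """
    components = [c for c in din_components if c is not None]
    if any(np.asarray(v, dtype=float) < 0
           for v in [tdn, *components] if v is not None):
        raise ValueError("concentrations must be >= 0")
    din = float(np.sum([float(c) for c in components])) if components else 0.0
    don = float(tdn) - din
    dop = None
    if tdp is not None and po4 is not None:
        if float(tdp) < 0 or float(po4) < 0:
            raise ValueError("concentrations must be >= 0")
        dop = float(tdp) - float(po4)
    negatives = [v for v in (don, dop) if v is not None and v < 0]
    if negatives:
        warnings.warn("negative organic nutrient concentration "
                      "(below-detection artefact)", stacklevel=2)
    return don, dop


def detection_limits(sd_low_standard: float) -> tuple[float, float]:
    """(LOD, LOQ) = (3, 10) x the SD of the lowest calibration standard."""
    sd = float(sd_low_standard)
    if sd < 0:
        raise ValueError("sd must be >= 0")
    return 3.0 * sd, 10.0 * sd


# --------------------------------------------------------------------------
# table-level processing

_SUBSTRATE_ELEMENT = {"DIC": "C", "NH4": "N", "NO3": "N"}


def _pool_excess(pools: pd.DataFrame, treatment: str, substrate: str,
                 timepoint: str) -> float | None:
    """Pool excess for rate math: T1 uses the T1 value; T2 uses the
    T1/T2 time average when both are present."""
    rows = pools[(pools["treatment"] == treatment)
                 & (pools["substrate"] == substrate)]
    if rows.empty:
        return None
    by_tp = {r["timepoint"]: r["atom_percent"] - r["natural_atom_percent"]
             for _, r in rows.iterrows()}
    if timepoint == "T1":
        return by_tp.get("T1", next(iter(by_tp.values())))
    if "T1" in by_tp and "T2" in by_tp:
        return pool_excess_timeavg(by_tp["T1"], by_tp["T2"])
    return by_tp.get(timepoint, next(iter(by_tp.values())))


def bulk_rate_table(
    bulk: pd.DataFrame,
    pools: pd.DataFrame,
    incubation: Incubation | None = None,
) -> pd.DataFrame:
    """Per-treatment bulk rates from a bottle table and a pool table.

    ``bulk`` columns: treatment, timepoint, replicate, poc_umol_l,
    pon_umol_l, ap13c_poc, ap15n_pon. Rows at timepoint T0 define the
    natural-abundance baseline of the particulate matter. ``pools``
    columns: treatment, substrate, timepoint, concentration_um,
    atom_percent, natural_atom_percent.

    Returns a tidy frame with one row per treatment x timepoint x
    substrate x quantity, aggregated as mean +- SD over replicate
    bottles. Bottles with missing atom% are dropped with a logged
    reason; bottles whose POM excess is negative (noise on unlabelled
    material) get NaN growth with a logged reason.
    """
    incubation = incubation or Incubation()
    t0 = bulk[bulk["timepoint"] == "T0"]
    if t0.empty:
        raise ValueError("bulk table has no T0 baseline rows")
    base_c = float(t0["ap13c_poc"].mean())
    base_n = float(t0["ap15n_pon"].mean())

    records: list[dict] = []
    labelled = bulk[bulk["timepoint"].isin(["T1", "T2"])]
    for (treatment, timepoint), grp in labelled.groupby(
            ["treatment", "timepoint"], sort=True):
        dt = incubation.dt_days(timepoint)
        for substrate in ("DIC", "NH4", "NO3"):
            e_pool = _pool_excess(pools, treatment, substrate, timepoint)
            if e_pool is None or e_pool <= 0:
                continue
            ap_col = "ap13c_poc" if substrate == "DIC" else "ap15n_pon"
            pom_col = "poc_umol_l" if substrate == "DIC" else "pon_umol_l"
            base = base_c if substrate == "DIC" else base_n
            element = _SUBSTRATE_ELEMENT[substrate]

            assim, specific, mus = [], [], []
            for _, row in grp.iterrows():
                if pd.isna(row[ap_col]) or pd.isna(row[pom_col]):
                    log.warning("dropping bottle %s/%s/%s: missing %s",
                                treatment, timepoint, row["replicate"], ap_col)
                    continue
                e_pom = row[ap_col] - base
                pom = row[pom_col]
                assim.append(bulk_assimilation_rate(e_pom, e_pool, pom, dt))
                specific.append(
                    biomass_normalized_rate(assim[-1], umol_to_mg(pom, element)))
                if 0.0 <= e_pom < e_pool:
                    mus.append(growth_rate(e_pool, e_pom, dt))
                else:
                    log.warning("bottle %s/%s/%s: POM excess %.4g outside "
                                "[0, pool excess); growth set to NaN",
                                treatment, timepoint, row["replicate"], e_pom)
                    mus.append(np.nan)

            if not assim:
                continue
            mus_arr = np.asarray(mus, dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                doubling = doubling_time(mus_arr)
            quantities = [
                ("assimilation", f"umol {element} L-1 day-1",
                 np.asarray(assim, dtype=float)),
                ("assimilation_specific",
                 f"umol {element} mg-1 {element}_POM day-1",
                 np.asarray(specific, dtype=float)),
                ("growth", "day-1", mus_arr),
                ("doubling", "days", np.asarray(doubling, dtype=float)),
            ]
            for kind, units, vals in quantities:
                ok = vals[np.isfinite(vals)]
                records.append({
                    "treatment": treatment,
                    "timepoint": timepoint,
                    "substrate": substrate,
                    "kind": kind,
                    "units": units,
                    "mean": float(np.mean(ok)) if ok.size else np.nan,
                    "sd": float(np.std(ok, ddof=1)) if ok.size > 1 else np.nan,
                    "n": int(ok.size),
                })
    return pd.DataFrame.from_records(records)
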