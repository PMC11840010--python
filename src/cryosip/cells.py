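"""Single-cell pipeline: ion-image ROI quantification, cell geometry and
elemental quotas, per-cell fixation and growth rates, and SEM-EDS
stoichiometry.

A HR-SIMS measurement yields per-pixel ion counts of the isotopologues
12C14N-, 13C14N- and 12C15N-. For each region of interest (ROI, the
pixel set of one cell) the isotope fractions

    frac13C = 13C14N / (13C14N + 12C14N)
    frac15N = 12C15N / (12C15N + 12C14N)

are computed per pixel and averaged over the ROI (the default), or from
summed counts (the lower-variance alternative). Cell carbon content
follows the chain biovolume (cylinder) -> dry weight (buoyant density x
dry fraction) -> element content (median dry-mass fractions / atomic
mass), and per-cell rates use the same isotope mass-balance model as
the bulk module with the cell's element quota in place of the POM
concentration.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import constants
from .bulk import Incubation, doubling_time, growth_rate
from .isotope import NaturalAbundance, classify_active

__all__ = [
    "CellComposition",
    "roi_quantify",
    "biovolume_cylinder",
    "cell_dry_weight",
    "cell_elemental_content",
    "cell_fixation_rate",
    "cell_growth_rate",
    "assimilation_cn_ratio",
    "stoichiometry_from_eds",
    "cell_rate_table",
    "population_summary",
]

log = logging.getLogger(__name__)

ISOTOPOLOGUES = ("12C14N", "13C14N", "12C15N")


@dataclass(frozen=True)
class CellComposition:
    """Biovolume, dry weight and C/N/P quotas of a cell (pmol cell^-1)."""

    biovolume_um3: float
    dry_weight_pg: float
    content_c_pmol: float
    content_n_pmol: float
    content_p_pmol: float
    source: str = "per_cell"  # or "population_mean"

    def __post_init__(self) -> None:
        for name in ("biovolume_um3", "dry_weight_pg", "content_c_pmol",
                     "content_n_pmol", "content_p_pmol"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def roi_quantify(images: dict, labels: np.ndarray,
                 estimator: str = "pixel_mean") -> pd.DataFrame:
    """Per-ROI isotope fractions from isotopologue count images.

    ``images`` maps the isotopologue names ``"12C14N"``, ``"13C14N"``,
    ``"12C15N"`` to 2-D non-negative count rasters; ``labels`` is an
    integer mask of the same shape (0 = background, each positive label
    one cell). Pixels whose denominator is zero are excluded; an ROI
    with no usable pixel for either ratio is skipped with a warning.

    ``estimator="pixel_mean"`` averages per-pixel ratios over the ROI
    (the default); ``"count_sum"`` forms the ratio of summed counts,
    which has lower variance at low per-pixel counts.

    Returns a frame with cell_id, frac13c, frac15n, roi_pixels.
    """
    if estimator not in ("pixel_mean", "count_sum"):
        raise ValueError(f"unknown estimator {estimator!r}")
    missing = [k for k in ISOTOPOLOGUES if k not in images]
    if missing:
        raise ValueError(f"missing isotopologue images: {missing}")
    labels = np.asarray(labels)
    arrays = {k: np.asarray(images[k], dtype=float) for k in ISOTOPOLOGUES}
    for k, arr in arrays.items():
        if arr.shape != labels.shape:
            raise ValueError(
                f"shape mismatch: {k} {arr.shape} vs labels {labels.shape}")
        if np.any(arr < 0):
            raise ValueError(f"negative counts in {k}")

    c12, c13, c15 = (arrays[k] for k in ISOTOPOLOGUES)
    records = []
    for cell_id in np.unique(labels[labels > 0]):
        roi = labels == cell_id
        n_px = int(roi.sum())
        fracs = {}
        for name, heavy in (("frac13c", c13), ("frac15n", c15)):
            h, l = heavy[roi], c12[roi]
            total = h + l
            use = total > 0
            if not use.any():
                fracs[name] = None
                continue
            if estimator == "pixel_mean":
                fracs[name] = float(np.mean(h[use] / total[use]))
            else:
                fracs[name] = float(h[use].sum() / total[use].sum())
        if fracs["frac13c"] is None and fracs["frac15n"] is None:
            warnings.warn(f"ROI {cell_id}: all denominators zero; skipped",
                          stacklevel=2)
            continue
        records.append({"cell_id": int(cell_id),
                        "frac13c": fracs["frac13c"],
                        "frac15n": fracs["frac15n"],
                        "roi_pixels": n_px})
    return pd.DataFrame.from_records(
        records, columns=["cell_id", "frac13c", "frac15n", "roi_pixels"])


def biovolume_cylinder(length_um, width_um):
    """Cell biovolume (µm^3) assuming a cylinder: V = pi/4 * w^2 * l."""
    length_um = np.asarray(length_um, dtype=float)
    width_um = np.asarray(width_um, dtype=float)
    if np.any(length_um <= 0) or np.any(width_um <= 0):
        raise ValueError("cell dimensions must be > 0")
    out = np.pi / 4.0 * width_um ** 2 * length_um
    return out if np.ndim(out) else float(out)


def cell_dry_weight(biovolume_um3,
                    density_kg_m3: float = constants.CELL_DENSITY_KG_M3,
                    dry_fraction: float = constants.DRY_FRACTION):
    """Cell dry weight in pg: biovolume x buoyant density x dry fraction.

    1 µm^3 of material at 1000 kg m^-3 weighs exactly 1 pg, so the
    conversion reduces to density/1000.
    """
    if density_kg_m3 <= 0 or dry_fraction <= 0:
        raise ValueError("density and dry fraction must be > 0")
    bv = np.asarray(biovolume_um3, dtype=float)
    if np.any(bv < 0):
        raise ValueError("biovolume must be >= 0")
    out = bv * (density_kg_m3 / 1000.0) * dry_fraction
    return out if np.ndim(out) else float(out)


def cell_elemental_content(dry_weight_pg, mass_fractions: dict | None = None,
                           biovolume_um3: float = np.nan,
                           source: str = "per_cell") -> CellComposition:
    """C/N/P quotas (pmol cell^-1) from dry weight and mass fractions.

    content_X = dry_weight * w_X / atomic_mass_X; mass fractions default
    to the median glacier ice algal values (C 0.72, N 0.04, P 0.04).
    """
    mf = dict(constants.MASS_FRACTIONS if mass_fractions is None
              else mass_fractions)
    for el, w in mf.items():
        if not 0.0 <= w <= 1.0:
            raise ValueError(f"mass fraction of {el} must lie in [0, 1]")
    dw = float(dry_weight_pg)
    if dw < 0:
        raise ValueError("dry weight must be >= 0")
    content = {el: dw * mf.get(el, 0.0) / constants.ATOMIC_MASS[el]
               for el in ("C", "N", "P")}
    return CellComposition(
        biovolume_um3=float(biovolume_um3),
        dry_weight_pg=dw,
        content_c_pmol=content["C"],
        content_n_pmol=content["N"],
        content_p_pmol=content["P"],
        source=source,
    )


def cell_fixation_rate(excess_cell, excess_pool, content_pmol, dt):
    """Single-cell fixation/assimilation rate, pmol element cell^-1 day^-1.

    (excess_cell / excess_pool) * content / dt — the cell analogue of
    the bulk assimilation equation, with the cell's element quota in
    place of the POM concentration.
    """
    excess_pool = np.asarray(excess_pool, dtype=float)
    if np.any(excess_pool <= 0):
        raise ValueError("source pool atom% excess must be > 0")
    if np.any(np.asarray(dt, dtype=float) <= 0):
        raise ValueError("dt must be > 0 days")
    out = (np.asarray(excess_cell, dtype=float) / excess_pool) \
        * np.asarray(content_pmol, dtype=float) / np.asarray(dt, dtype=float)
    return out if np.ndim(out) else float(out)


def cell_growth_rate(excess_pool, excess_cell, dt):
    """Per-cell isotope growth rate (day^-1); same model as the bulk."""
    return growth_rate(excess_pool, excess_cell, dt)


def assimilation_cn_ratio(c_rates, n_rates):
    """Per-cell C:N assimilation ratios and their mean-of-ratios summary.

    Cells with non-positive N rates are excluded with a warning (the
    ratio is undefined there). Returns ``(ratios, summary)`` where
    ``ratios`` is an array aligned to the kept cells and ``summary`` a
    dict with mean, sd and n. The population summary is the mean of
    per-cell ratios, not the ratio of mean rates.
    """
    c = np.atleast_1d(np.asarray(c_rates, dtype=float))
    n = np.atleast_1d(np.asarray(n_rates, dtype=float))
    if c.shape != n.shape:
        raise ValueError("c_rates and n_rates must align")
    keep = n > 0
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} cell(s) with non-positive "
                      "N rate excluded from C:N ratios", stacklevel=2)
    ratios = c[keep] / n[keep]
    summary = {
        "mean": float(np.mean(ratios)) if ratios.size else np.nan,
        "sd": float(np.std(ratios, ddof=1)) if ratios.size > 1 else np.nan,
        "n": int(ratios.size),
    }
    return ratios, summary


def stoichiometry_from_eds(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cell and summary C:N, C:P, N:P atomic ratios from EDS atom%.

    ``records`` needs columns cell_id, atom_percent_c, atom_percent_n,
    atom_percent_p (already-quantified spectra; instrument conversion is
    upstream of this package). Cells with a zero denominator are
    excluded with a warning. The summary attaches the Redfield
    reference value of each ratio for comparison.
    """
    required = ["cell_id", "atom_percent_c", "atom_percent_n", "atom_percent_p"]
    missing = [c for c in required if c not in records.columns]
    if missing:
        raise ValueError(f"EDS table missing columns: {missing}")
    c = records["atom_percent_c"].to_numpy(dtype=float)
    n = records["atom_percent_n"].to_numpy(dtype=float)
    p = records["atom_percent_p"].to_numpy(dtype=float)
    if np.any(c < 0) or np.any(n < 0) or np.any(p < 0):
        raise ValueError("atom% values must be >= 0")
    keep = (n > 0) & (p > 0)
    if not keep.all():
        warnings.warn(f"{int((~keep).sum())} cell(s) with zero N or P "
                      "excluded from stoichiometry", stacklevel=2)
    per_cell = pd.DataFrame({
        "cell_id": records.loc[keep, "cell_id"].to_numpy(),
        "cn": c[keep] / n[keep],
        "cp": c[keep] / p[keep],
        "np": n[keep] / p[keep],
    })
    rows = []
    for col, name, redfield in (("cn", "C:N", constants.REDFIELD["C:N"]),
                                ("cp", "C:P", constants.REDFIELD["C:P"]),
                                ("np", "N:P", constants.REDFIELD["N:P"])):
        vals = per_cell[col].to_numpy()
        rows.append({
            "ratio": name,
            "mean": float(np.mean(vals)) if vals.size else np.nan,
            "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
            "n": int(vals.size),
            "redfield": redfield,
        })
    return per_cell, pd.DataFrame(rows)


# --------------------------------------------------------------------------
# table-level processing

_N_SUBSTRATE_OF_TREATMENT = {"NH4": "NH4", "NH4_PO4": "NH4", "NO3": "NO3"}


def _pool_excess_for(pools: pd.DataFrame, treatment: str, substrate: str,
                     timepoint: str) -> float | None:
    from .bulk import _pool_excess
    return _pool_excess(pools, treatment, substrate, timepoint)


def cell_rate_table(
    cells: pd.DataFrame,
    pools: pd.DataFrame,
    incubation: Incubation | None = None,
    na_c: NaturalAbundance | None = None,
    na_n: NaturalAbundance | None = None,
    mean_content: CellComposition | None = None,
    k: float = constants.ACTIVITY_K,
    content_basis: str = "population_mean",
) -> pd.DataFrame:
    """Per-cell rates from a cell ROI table and a pool table.

    ``cells`` columns: cell_id, treatment, timepoint, frac13c, frac15n,
    length_um, width_um (dimensions may be missing for some cells).

    The element quota entering the fixation-rate equation defaults to
    the population mean over all cells with usable geometry
    (``content_basis="population_mean"``); ``"per_cell"`` uses each
    cell's own quota instead. Cells without usable geometry fall back to
    the population mean and are flagged in ``content_source``.

    Adds: ap13c / ap15n (atom%), excess columns, the activity flag and
    its threshold, C and N quotas, fixation/assimilation rates
    (pmol cell^-1 day^-1; N also as fmol), growth rates and doubling
    times. Growth is only defined for excess in [0, pool excess);
    out-of-range cells get NaN.
    """
    if content_basis not in ("population_mean", "per_cell"):
        raise ValueError(f"unknown content_basis {content_basis!r}")
    incubation = incubation or Incubation()
    na_c = na_c or NaturalAbundance.carbon()
    na_n = na_n or NaturalAbundance.nitrogen()

    out = cells.copy().reset_index(drop=True)
    for col in ("frac15n", "length_um", "width_um"):
        if col not in out.columns:
            out[col] = np.nan
    out["ap13c"] = out["frac13c"].astype(float) * 100.0
    out["ap15n"] = out["frac15n"].astype(float) * 100.0
    out["excess13c"] = out["ap13c"] - na_c.mean_atom_percent
    out["excess15n"] = out["ap15n"] - na_n.mean_atom_percent

    active, thr = classify_active(out["ap13c"].to_numpy(), na_c, k)
    out["active"] = active
    out["activity_threshold_ap"] = thr

    # geometry -> per-cell composition; population mean as fallback
    geom_ok = (out["length_um"].notna() & out["width_um"].notna()
               & (out["length_um"] > 0) & (out["width_um"] > 0))
    bv = np.full(len(out), np.nan)
    bv[geom_ok.to_numpy()] = biovolume_cylinder(
        out.loc[geom_ok, "length_um"].to_numpy(),
        out.loc[geom_ok, "width_um"].to_numpy())
    dw = np.where(np.isfinite(bv), cell_dry_weight(np.nan_to_num(bv)), np.nan)
    content_c = dw * constants.MASS_FRACTIONS["C"] / constants.ATOMIC_MASS["C"]
    content_n = dw * constants.MASS_FRACTIONS["N"] / constants.ATOMIC_MASS["N"]
    if mean_content is None:
        if not np.isfinite(content_c).any():
            raise ValueError("no cell with usable geometry and no "
                             "mean_content supplied")
        mean_c = float(np.nanmean(content_c))
        mean_n = float(np.nanmean(content_n))
    else:
        mean_c = mean_content.content_c_pmol
        mean_n = mean_content.content_n_pmol

    if content_basis == "population_mean":
        use_c = np.full(len(out), mean_c)
        use_n = np.full(len(out), mean_n)
        out["content_source"] = "population_mean"
    else:
        use_c = np.where(np.isfinite(content_c), content_c, mean_c)
        use_n = np.where(np.isfinite(content_n), content_n, mean_n)
        out["content_source"] = np.where(np.isfinite(content_c),
                                         "per_cell", "population_mean")
        n_fallback = int((~np.isfinite(content_c)).sum())
        if n_fallback:
            log.warning("%d cell(s) without usable geometry use the "
                        "population-mean quota", n_fallback)
    out["biovolume_um3"] = bv
    out["content_c_pmol"] = use_c
    out["content_n_pmol"] = use_n

    # rates, per treatment x timepoint (pool excess differs between them)
    out["c_fix_pmol_d"] = np.nan
    out["c_growth_d"] = np.nan
    out["n_substrate"] = [
        _N_SUBSTRATE_OF_TREATMENT.get(t) for t in out["treatment"]]
    out["n_assim_pmol_d"] = np.nan
    out["n_growth_d"] = np.nan
    for (treatment, timepoint), idx in out.groupby(
            ["treatment", "timepoint"], sort=False).groups.items():
        if timepoint not in ("T1", "T2"):
            continue
        idx = np.asarray(idx)
        dt = incubation.dt_days(timepoint)
        e_dic = _pool_excess_for(pools, treatment, "DIC", timepoint)
        if e_dic is not None and e_dic > 0:
            exc = out.loc[idx, "excess13c"].to_numpy()
            out.loc[idx, "c_fix_pmol_d"] = cell_fixation_rate(
                exc, e_dic, use_c[idx], dt)
            okg = (exc >= 0) & (exc < e_dic)
            mu = np.full(exc.shape, np.nan)
            if okg.any():
                mu[okg] = cell_growth_rate(e_dic, exc[okg], dt)
            out.loc[idx, "c_growth_d"] = mu
        substrate = _N_SUBSTRATE_OF_TREATMENT.get(treatment)
        if substrate is None:
            continue
        e_n = _pool_excess_for(pools, treatment, substrate, timepoint)
        if e_n is None or e_n <= 0:
            continue
        exc = out.loc[idx, "excess15n"].to_numpy()
        out.loc[idx, "n_assim_pmol_d"] = cell_fixation_rate(
            exc, e_n, use_n[idx], dt)
        okg = (exc >= 0) & (exc < e_n)
        mu = np.full(exc.shape, np.nan)
        if okg.any():
            mu[okg] = cell_growth_rate(e_n, exc[okg], dt)
        out.loc[idx, "n_growth_d"] = mu

    out["n_assim_fmol_d"] = out["n_assim_pmol_d"] * 1000.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["c_doubling_d"] = doubling_time(out["c_growth_d"].to_numpy())
        out["n_doubling_d"] = doubling_time(out["n_growth_d"].to_numpy())
    return out


_SUMMARY_COLUMNS = ("c_fix_pmol_d", "n_assim_fmol_d", "c_growth_d",
                    "n_growth_d", "c_doubling_d", "n_doubling_d")


def population_summary(cell_rates: pd.DataFrame,
                       active_only: bool = True) -> pd.DataFrame:
    """Mean, SD and n per treatment x timepoint for each rate column.

    With ``active_only`` the summary covers the active fraction of the
    population (cells above the labelling threshold), mirroring how
    headline rates are reported; the all-cells variant retains inactive
    cells. An empty active set yields an empty summary with a warning.
    """
    if cell_rates.empty:
        raise ValueError("need at least one cell")
    df = cell_rates[cell_rates["active"]] if active_only else cell_rates
    if df.empty:
        warnings.warn("no active cells; summary is empty", stacklevel=2)
        return pd.DataFrame(
            columns=["treatment", "timepoint", "quantity", "mean", "sd", "n"])
    rows = []
    for (treatment, timepoint), grp in df.groupby(
            ["treatment", "timepoint"], sort=True):
        for col in _SUMMARY_COLUMNS:
            if col not in grp.columns:
                continue
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            rows.append({
                "treatment": treatment,
                "timepoint": timepoint,
                "quantity": col,
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan,
                "n": int(vals.size),
            })
    return pd.DataFrame.from_records(
        rows, columns=["treatment", "timepoint", "quantity", "mean", "sd", "n"])
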