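"""Synthetic stable-isotope-probing experiments with known ground truth.

The generator emulates a nutrient-amendment tracer incubation on melted
surface ice: five treatments (control, NH4, NO3, PO4, NH4+PO4) all
receive a 13C-DIC spike, the N treatments additionally a 15N tracer.
Cells carry lognormally distributed growth rates with an inactive
subpopulation; their labelling follows the inverse of the isotope
growth model, excess_cell(t) = E_pool(t) * (1 - 2^(-mu*t)), where
E_pool(t) is the flux-averaged pool excess over the incubation so far.
Pool label and concentration decline exponentially with configured
half-lives (the observed behaviour: the DIC excess eases from ~4.4 to
~3.6 atom% while most of the NH4+ and much of the NO3- tracer is
consumed within hours); an alternative ``depletion_mode="uptake"``
derives the pool trajectory from community uptake instead and conserves
tracer atoms exactly, which is what mass-balance checks use.

Bulk POM is the content-weighted mixture of the algal population and a
non-algal background with its own growth rate, so bulk tables, cell
tables, pool tables and EDS tables are mutually consistent and every
analysis stage can be validated against the recorded ground truth.
Biomass concentrations are held constant over the 30-h incubation
(labelling, not biomass accrual, carries the signal); bottle-to-bottle
biomass variability is lognormal noise.

Ion-count images are rendered as per-pixel Poisson draws of the three
isotopologues, with cells placed as axis-aligned rectangles (cylinder
projections) in 256 x 256 rasters and an integer label mask as ground
truth segmentation.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedExperiment",
    "simulate_experiment",
    "render_sims_images",
    "write_experiment",
]

TREATMENTS = ("control", "NH4", "NO3", "PO4", "NH4_PO4")
N_SUBSTRATE = {"NH4": "NH4", "NH4_PO4": "NH4", "NO3": "NO3"}

DEFAULT_CELL_GROUPS = (
    ("control", "T1"), ("NH4", "T1"),
    ("control", "T2"), ("NH4", "T2"), ("NO3", "T2"),
    ("PO4", "T2"), ("NH4_PO4", "T2"),
)


def _default_multipliers() -> dict:
    # nutrient loading suppresses growth in the P-amended treatments
    return {"control": 1.0, "NH4": 1.0, "NO3": 1.0,
            "PO4": 0.43, "NH4_PO4": 0.49}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of a synthetic incubation experiment."""

    seed: int = 0
    n_cells: int = 244
    inactive_fraction: float = 0.10
    #: lognormal growth heterogeneity of active cells (day^-1);
    #: median 0.42 / GSD 1.62 give mean ~0.47, SD ~0.24 day^-1
    growth_median: float = 0.42
    growth_gsd: float = 1.62
    #: growth rate of the non-algal bulk background (day^-1)
    background_growth: float = 0.65
    treatment_growth_multiplier: dict = field(
        default_factory=_default_multipliers)
    t1_hours: float = constants.T1_HOURS
    t2_hours: float = constants.T2_HOURS
    cell_groups: tuple = DEFAULT_CELL_GROUPS

    # dissolved pools and tracer additions
    ambient_dic_um: float = 630.0
    dic_tracer_um: float = 30.0
    ambient_nh4_um: float = 0.078
    ambient_no3_um: float = 0.05
    n_tracer_um: float = 10.0
    tracer_purity_ap: float = 98.0
    nat_pool_13c_ap: float = 100.0 * constants.NAT_13C_FRACTION
    nat_pool_15n_ap: float = constants.NAT_15N_POOL_ATOM_PERCENT
    #: excess half-life of the DIC pool label (hours); None = constant
    dic_excess_half_life_h: float | None = 104.0
    #: concentration half-lives of the N tracers (hours)
    nh4_conc_half_life_h: float = 1.1
    no3_conc_half_life_h: float = 4.0
    depletion_mode: str = "half_life"  # or "uptake"

    # community and bulk POM
    abundance_per_ml: float = 16.2e3
    abundance_sd_per_ml: float = 1.2e3
    poc_t0_umol_l: float = 2849.0
    poc_t0_sd: float = 1015.0
    poc_pon: float = 20.06
    #: non-algal share of bulk POC; None derives it from abundance x
    #: mean cell C quota so the community is internally consistent
    non_algal_bulk_fraction: float | None = None
    n_bottles_t0: int = 3
    n_bottles_t1: int = 1
    n_bottles_t2: int = 3

    # cell geometry (cylinders), medians and geometric SDs
    length_median_um: float = 15.0
    length_gsd: float = 1.35
    width_median_um: float = 10.3
    width_gsd: float = 1.25

    # SEM-EDS table
    n_eds_cells: int = 48
    eds_cn_mean: float = 19.0
    eds_cn_sd: float = 2.9
    eds_np_mean: float = 26.0
    eds_np_sd: float = 5.0
    eds_p_atom_percent: float = 0.12
    eds_mass_fraction_cv: float = 0.10

    # ion-count imaging
    raster_size: int = 256
    pixel_size_um: float = 70.0 / 256.0
    counts_per_cell: float = 1.0e6
    background_lambda: float = 0.0

    # noise switches
    noise_free: bool = False
    measurement_sd_frac13: float = 2e-4
    measurement_sd_frac15: float = 8e-5
    bulk_ap_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if not 0.0 <= self.inactive_fraction <= 1.0:
            raise ValueError("inactive_fraction must lie in [0, 1]")
        for name in ("n_cells", "growth_median", "growth_gsd",
                     "counts_per_cell", "raster_size", "pixel_size_um",
                     "poc_t0_umol_l", "abundance_per_ml", "poc_pon",
                     "length_median_um", "width_median_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.t1_hours < self.t2_hours:
            raise ValueError("need 0 < t1 < t2")
        if self.depletion_mode not in ("half_life", "uptake"):
            raise ValueError(f"unknown depletion_mode {self.depletion_mode!r}")
        if self.non_algal_bulk_fraction is not None and not (
                0.0 <= self.non_algal_bulk_fraction < 1.0):
            raise ValueError("non_algal_bulk_fraction must lie in [0, 1)")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    cells: pd.DataFrame       # per-cell true mu, fractions, composition
    pools: pd.DataFrame       # per treatment/substrate excess trajectories
    contribution: pd.DataFrame  # true algal share of bulk uptake
    mass_balance: pd.DataFrame  # tracer-atom ledger (uptake mode: exact)
    summary: dict             # scalar truths (mean mu, fractions, ...)


@dataclass
class SimulatedExperiment:
    config: SimulationConfig
    truth: GroundTruth
    cells: pd.DataFrame   # what the ROI table would contain
    bulk: pd.DataFrame    # EA-IRMS bottle table
    pools: pd.DataFrame   # measured pool table
    eds: pd.DataFrame     # SEM-EDS per-cell table


# --------------------------------------------------------------------------
# pool label kinetics

def _excess_at(e0: float, half_life_h: float | None, t_h: float) -> float:
    if half_life_h is None or not math.isfinite(half_life_h):
        return e0
    return e0 * 2.0 ** (-t_h / half_life_h)


def _excess_flux_avg(e0: float, half_life_h: float | None, t_h: float) -> float:
    """Time-averaged pool excess over [0, t] for an exponential decline."""
    if half_life_h is None or not math.isfinite(half_life_h):
        return e0
    lam = math.log(2.0) / half_life_h
    return e0 * (1.0 - math.exp(-lam * t_h)) / (lam * t_h)


def _mixed_excess(ambient_um, ambient_ap, added_um, purity_ap):
    total = ambient_um + added_um
    mixed = (added_um * purity_ap + ambient_um * ambient_ap) / total
    return mixed - ambient_ap, total


def _pool_params(cfg: SimulationConfig) -> dict:
    """Per-substrate initial excess, concentration and half-lives."""
    e_dic, c_dic = _mixed_excess(cfg.ambient_dic_um, cfg.nat_pool_13c_ap,
                                 cfg.dic_tracer_um, cfg.tracer_purity_ap)
    e_nh4, c_nh4 = _mixed_excess(cfg.ambient_nh4_um, cfg.nat_pool_15n_ap,
                                 cfg.n_tracer_um, cfg.tracer_purity_ap)
    e_no3, c_no3 = _mixed_excess(cfg.ambient_no3_um, cfg.nat_pool_15n_ap,
                                 cfg.n_tracer_um, cfg.tracer_purity_ap)
    return {
        "DIC": {"e0": e_dic, "conc0": c_dic, "natural": cfg.nat_pool_13c_ap,
                "excess_hl": cfg.dic_excess_half_life_h, "conc_hl": None},
        "NH4": {"e0": e_nh4, "conc0": c_nh4, "natural": cfg.nat_pool_15n_ap,
                "excess_hl": None, "conc_hl": cfg.nh4_conc_half_life_h},
        "NO3": {"e0": e_no3, "conc0": c_no3, "natural": cfg.nat_pool_15n_ap,
                "excess_hl": None, "conc_hl": cfg.no3_conc_half_life_h},
    }


def _treatment_substrates(treatment: str) -> list[str]:
    subs = ["DIC"]
    if treatment in N_SUBSTRATE:
        subs.append(N_SUBSTRATE[treatment])
    return subs


# --------------------------------------------------------------------------
# the experiment

def _labelled_fraction(mu, t_days):
    return 1.0 - 2.0 ** (-np.asarray(mu, dtype=float) * t_days)


def simulate_experiment(config: SimulationConfig | None = None) -> SimulatedExperiment:
    """Generate a full synthetic experiment, deterministic per seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    pool_par = _pool_params(cfg)
    timepoint_hours = {"T1": cfg.t1_hours, "T2": cfg.t2_hours}

    # ---- cells: allocation, growth, geometry, composition -------------
    groups = list(cfg.cell_groups)
    n_per = [cfg.n_cells // len(groups)] * len(groups)
    for i in range(cfg.n_cells - sum(n_per)):
        n_per[i] += 1
    treatment_col, timepoint_col = [], []
    for (treatment, timepoint), n in zip(groups, n_per):
        treatment_col += [treatment] * n
        timepoint_col += [timepoint] * n

    n = cfg.n_cells
    active = rng.random(n) >= cfg.inactive_fraction
    sigma = math.log(cfg.growth_gsd)
    mult = np.array([cfg.treatment_growth_multiplier.get(t, 1.0)
                     for t in treatment_col])
    mu = np.where(
        active,
        rng.lognormal(math.log(cfg.growth_median), sigma, size=n) * mult,
        0.0)

    length = rng.lognormal(math.log(cfg.length_median_um),
                           math.log(cfg.length_gsd), size=n)
    width = rng.lognormal(math.log(cfg.width_median_um),
                          math.log(cfg.width_gsd), size=n)
    swap = length < width
    length[swap], width[swap] = width[swap].copy(), length[swap].copy()
    biovolume = np.pi / 4.0 * width ** 2 * length
    dry_weight = biovolume * (constants.CELL_DENSITY_KG_M3 / 1000.0) \
        * constants.DRY_FRACTION
    content_c = dry_weight * constants.MASS_FRACTIONS["C"] / constants.ATOMIC_MASS["C"]
    content_n = dry_weight * constants.MASS_FRACTIONS["N"] / constants.ATOMIC_MASS["N"]

    # ---- community bookkeeping ----------------------------------------
    abundance_l = cfg.abundance_per_ml * 1000.0
    mean_content_c = float(np.mean(content_c))
    mean_content_n = float(np.mean(content_n))
    algal_poc = abundance_l * mean_content_c * 1e-6  # µmol C L^-1
    algal_pon = abundance_l * mean_content_n * 1e-6
    if cfg.non_algal_bulk_fraction is None:
        alg_frac_c = algal_poc / cfg.poc_t0_umol_l
        alg_frac_n = algal_pon / (cfg.poc_t0_umol_l / cfg.poc_pon)
    else:
        alg_frac_c = alg_frac_n = 1.0 - cfg.non_algal_bulk_fraction
    if not (0.0 < alg_frac_c < 1.0 and 0.0 < alg_frac_n < 1.0):
        raise ValueError(
            "infeasible config: algal biomass exceeds the bulk POM "
            f"(algal C fraction {alg_frac_c:.3g}, N fraction {alg_frac_n:.3g})")

    mu_by_treatment = {
        t: mu[np.asarray(treatment_col) == t] for t in TREATMENTS
        if (np.asarray(treatment_col) == t).any()}

    # population-mean labelled fraction of the algae in one treatment
    def alg_labelled(treatment: str, t_days: float) -> float:
        mus = mu_by_treatment.get(treatment)
        if mus is None or mus.size == 0:  # treatment without imaged cells
            mus = mu
        return float(np.mean(_labelled_fraction(mus, t_days)))

    # community uptake of one element pool over [0, t], µmol L^-1
    def community_uptake(treatment: str, element: str, t_days: float) -> float:
        if element == "C":
            alg_pool, alg_share = cfg.poc_t0_umol_l * alg_frac_c, alg_frac_c
            total = cfg.poc_t0_umol_l
        else:
            total = cfg.poc_t0_umol_l / cfg.poc_pon
            alg_pool, alg_share = total * alg_frac_n, alg_frac_n
        f_alg = alg_labelled(treatment, t_days)
        f_bg = float(_labelled_fraction(cfg.background_growth, t_days))
        return alg_pool * f_alg + (total - alg_pool) * f_bg

    # ---- pool trajectories (per treatment x substrate) -----------------
    pool_truth_rows, pool_rows, balance_rows = [], [], []
    flux_avg: dict[tuple[str, str, str], float] = {}
    for treatment in TREATMENTS:
        for substrate in _treatment_substrates(treatment):
            par = pool_par[substrate]
            element = "C" if substrate == "DIC" else "N"
            for timepoint, t_h in timepoint_hours.items():
                t_d = t_h / constants.HOURS_PER_DAY
                if cfg.depletion_mode == "half_life":
                    exc = _excess_at(par["e0"], par["excess_hl"], t_h)
                    eavg = _excess_flux_avg(par["e0"], par["excess_hl"], t_h)
                    conc = (par["conc0"] if par["conc_hl"] is None
                            else par["conc0"] * 2.0 ** (-t_h / par["conc_hl"]))
                else:  # uptake: label constant, concentration conserved
                    exc = eavg = par["e0"]
                    conc = par["conc0"] - community_uptake(
                        treatment, element, t_d)
                    if conc < 0:
                        raise ValueError(
                            "infeasible config: community uptake exhausts "
                            f"the {substrate} pool in treatment {treatment}")
                flux_avg[(treatment, substrate, timepoint)] = eavg
                pool_truth_rows.append({
                    "treatment": treatment, "substrate": substrate,
                    "timepoint": timepoint, "excess0": par["e0"],
                    "excess": exc, "excess_flux_avg": eavg,
                    "concentration_um": conc,
                })
                ap_noise = (0.0 if cfg.noise_free
                            else rng.normal(0.0, cfg.bulk_ap_noise_sd * 0.1))
                pool_rows.append({
                    "treatment": treatment, "substrate": substrate,
                    "timepoint": timepoint,
                    "concentration_um": conc,
                    "atom_percent": par["natural"] + exc + ap_noise,
                    "natural_atom_percent": par["natural"],
                })
                if cfg.depletion_mode == "uptake":
                    uptake = par["conc0"] - conc
                    balance_rows.append({
                        "treatment": treatment, "substrate": substrate,
                        "timepoint": timepoint,
                        "initial_tracer_umol_l": par["conc0"] * par["e0"] / 100.0,
                        "pool_tracer_umol_l": conc * par["e0"] / 100.0,
                        "biomass_tracer_umol_l": uptake * par["e0"] / 100.0,
                    })

    # ---- per-cell true and observed isotope fractions ------------------
    nat13, sd13 = constants.NAT_13C_FRACTION, constants.NAT_13C_SD
    nat15, sd15 = constants.NAT_15N_FRACTION, constants.NAT_15N_SD
    frac13_true = np.empty(n)
    frac15_true = np.empty(n)
    for i in range(n):
        treatment, timepoint = treatment_col[i], timepoint_col[i]
        t_d = timepoint_hours[timepoint] / constants.HOURS_PER_DAY
        base13 = nat13 if cfg.noise_free else rng.normal(nat13, sd13)
        base15 = nat15 if cfg.noise_free else rng.normal(nat15, sd15)
        e_dic = flux_avg[(treatment, "DIC", timepoint)]
        frac13_true[i] = base13 + (
            e_dic * _labelled_fraction(mu[i], t_d) / 100.0)
        substrate = N_SUBSTRATE.get(treatment)
        if substrate is None:
            frac15_true[i] = base15
        else:
            e_n = flux_avg[(treatment, substrate, timepoint)]
            frac15_true[i] = base15 + (
                e_n * _labelled_fraction(mu[i], t_d) / 100.0)
    frac13_true = np.clip(frac13_true, 0.0, 1.0)
    frac15_true = np.clip(frac15_true, 0.0, 1.0)

    frac13_obs = frac13_true if cfg.noise_free else np.clip(
        frac13_true + rng.normal(0.0, cfg.measurement_sd_frac13, n), 0.0, 1.0)
    frac15_obs = frac15_true if cfg.noise_free else np.clip(
        frac15_true + rng.normal(0.0, cfg.measurement_sd_frac15, n), 0.0, 1.0)

    cell_ids = np.arange(1, n + 1)
    truth_cells = pd.DataFrame({
        "cell_id": cell_ids, "treatment": treatment_col,
        "timepoint": timepoint_col, "active_true": active,
        "mu_true_per_day": mu,
        "frac13c_true": frac13_true, "frac15n_true": frac15_true,
        "length_um": length, "width_um": width,
        "biovolume_um3": biovolume, "dry_weight_pg": dry_weight,
        "content_c_pmol": content_c, "content_n_pmol": content_n,
    })
    cells = pd.DataFrame({
        "cell_id": cell_ids, "treatment": treatment_col,
        "timepoint": timepoint_col,
        "frac13c": frac13_obs, "frac15n": frac15_obs,
        "length_um": length, "width_um": width,
        "taxon": "glacier_ice_algae",
    })

    # ---- bulk bottle table ---------------------------------------------
    bulk_rows = []
    poc_cv = cfg.poc_t0_sd / cfg.poc_t0_umol_l
    sigma_poc = math.sqrt(math.log(1.0 + poc_cv ** 2))

    def draw_poc() -> float:
        if cfg.noise_free:
            return cfg.poc_t0_umol_l
        return rng.lognormal(
            math.log(cfg.poc_t0_umol_l) - sigma_poc ** 2 / 2.0, sigma_poc)

    for rep in range(cfg.n_bottles_t0):
        poc = draw_poc()
        ap13 = 100.0 * nat13 + (0.0 if cfg.noise_free
                                else rng.normal(0.0, cfg.bulk_ap_noise_sd))
        ap15 = 100.0 * nat15 + (0.0 if cfg.noise_free
                                else rng.normal(0.0, cfg.bulk_ap_noise_sd * 0.3))
        bulk_rows.append({
            "treatment": "none", "timepoint": "T0", "replicate": rep + 1,
            "poc_umol_l": poc, "pon_umol_l": poc / cfg.poc_pon,
            "ap13c_poc": max(ap13, 0.0), "ap15n_pon": max(ap15, 0.0)})

    f_bg = {tp: float(_labelled_fraction(
        cfg.background_growth, t_h / constants.HOURS_PER_DAY))
        for tp, t_h in timepoint_hours.items()}
    contribution_rows = []
    for treatment in TREATMENTS:
        for timepoint, n_rep in (("T1", cfg.n_bottles_t1),
                                 ("T2", cfg.n_bottles_t2)):
            t_d = timepoint_hours[timepoint] / constants.HOURS_PER_DAY
            f_alg_c = alg_labelled(treatment, t_d)
            exc13 = flux_avg[(treatment, "DIC", timepoint)] * (
                alg_frac_c * f_alg_c + (1.0 - alg_frac_c) * f_bg[timepoint])
            substrate = N_SUBSTRATE.get(treatment)
            if substrate is None:
                exc15 = 0.0
            else:
                exc15 = flux_avg[(treatment, substrate, timepoint)] * (
                    alg_frac_n * f_alg_c + (1.0 - alg_frac_n) * f_bg[timepoint])
            for rep in range(n_rep):
                poc = draw_poc()
                noise13 = (0.0 if cfg.noise_free
                           else rng.normal(0.0, cfg.bulk_ap_noise_sd))
                noise15 = (0.0 if cfg.noise_free
                           else rng.normal(0.0, cfg.bulk_ap_noise_sd * 0.3))
                bulk_rows.append({
                    "treatment": treatment, "timepoint": timepoint,
                    "replicate": rep + 1,
                    "poc_umol_l": poc, "pon_umol_l": poc / cfg.poc_pon,
                    "ap13c_poc": 100.0 * nat13 + exc13 + noise13,
                    "ap15n_pon": 100.0 * nat15 + exc15 + noise15})

            # true algal share of the bulk uptake (Eq. 4 numerator/denominator)
            denom_c = alg_frac_c * f_alg_c + (1.0 - alg_frac_c) * f_bg[timepoint]
            contribution_rows.append({
                "treatment": treatment, "substrate": "DIC",
                "timepoint": timepoint,
                "true_percent": 100.0 * alg_frac_c * f_alg_c / denom_c})
            if substrate is not None:
                denom_n = alg_frac_n * f_alg_c + (1.0 - alg_frac_n) * f_bg[timepoint]
                contribution_rows.append({
                    "treatment": treatment, "substrate": substrate,
                    "timepoint": timepoint,
                    "true_percent": 100.0 * alg_frac_n * f_alg_c / denom_n})

    bulk = pd.DataFrame(bulk_rows)
    pools = pd.DataFrame(pool_rows)

    # ---- SEM-EDS table --------------------------------------------------
    m = cfg.n_eds_cells
    s_cn = math.sqrt(math.log(1.0 + (cfg.eds_cn_sd / cfg.eds_cn_mean) ** 2))
    s_np = math.sqrt(math.log(1.0 + (cfg.eds_np_sd / cfg.eds_np_mean) ** 2))
    if cfg.noise_free:
        r_cn = np.full(m, cfg.eds_cn_mean)
        r_np = np.full(m, cfg.eds_np_mean)
        mf_noise = np.ones((m, 3))
    else:
        r_cn = rng.lognormal(math.log(cfg.eds_cn_mean) - s_cn ** 2 / 2, s_cn, m)
        r_np = rng.lognormal(math.log(cfg.eds_np_mean) - s_np ** 2 / 2, s_np, m)
        s_mf = math.sqrt(math.log(1.0 + cfg.eds_mass_fraction_cv ** 2))
        mf_noise = rng.lognormal(-s_mf ** 2 / 2, s_mf, (m, 3))
    p_ap = np.full(m, cfg.eds_p_atom_percent)
    n_ap = p_ap * r_np
    c_ap = n_ap * r_cn
    o_ap = np.clip(100.0 - c_ap - n_ap - p_ap, 0.0, None)
    eds = pd.DataFrame({
        "cell_id": np.arange(1, m + 1),
        "atom_percent_c": c_ap, "atom_percent_n": n_ap,
        "atom_percent_o": o_ap, "atom_percent_p": p_ap,
        "mass_percent_c": 100 * constants.MASS_FRACTIONS["C"] * mf_noise[:, 0],
        "mass_percent_n": 100 * constants.MASS_FRACTIONS["N"] * mf_noise[:, 1],
        "mass_percent_p": 100 * constants.MASS_FRACTIONS["P"] * mf_noise[:, 2],
    })

    truth = GroundTruth(
        cells=truth_cells,
        pools=pd.DataFrame(pool_truth_rows),
        contribution=pd.DataFrame(contribution_rows),
        mass_balance=pd.DataFrame(balance_rows),
        summary={
            "seed": cfg.seed,
            "n_cells": n,
            "inactive_fraction_true": float(np.mean(~active)),
            "mean_mu_active": float(np.mean(mu[active])) if active.any() else 0.0,
            "sd_mu_active": float(np.std(mu[active], ddof=1))
            if active.sum() > 1 else 0.0,
            "algal_fraction_poc": alg_frac_c,
            "algal_fraction_pon": alg_frac_n,
            "abundance_per_l": abundance_l,
            "mean_content_c_pmol": mean_content_c,
            "mean_content_n_pmol": mean_content_n,
        },
    )
    return SimulatedExperiment(config=cfg, truth=truth, cells=cells,
                               bulk=bulk, pools=pools, eds=eds)


# --------------------------------------------------------------------------
# ion-image rendering

def render_sims_images(truth_cells: pd.DataFrame, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> list[dict]:
    """Render Poisson ion-count rasters and label masks for the cells.

    Cells are drawn as axis-aligned rectangles (projected cylinders) and
    shelf-packed into as many ``raster_size`` x ``raster_size`` fields
    as needed, with a 2-pixel gap. Each pixel of a cell draws Poisson
    counts in the three isotopologue channels, with expectations set by
    the cell's true isotope fractions and a per-cell total 12C14N
    expectation of ``counts_per_cell``; in noise-free mode the expected
    counts themselves are returned. A cell that cannot fit in an empty
    raster raises.

    Returns a list of fields, each ``{"images": {name: array},
    "labels": int32 array}`` with globally unique labels equal to
    ``cell_id``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    size, gap = config.raster_size, 2
    fields: list[dict] = []

    def new_field() -> dict:
        images = {k: np.zeros((size, size)) for k in
                  ("12C14N", "13C14N", "12C15N")}
        if config.background_lambda > 0:
            for k in images:
                images[k] = (np.full((size, size), config.background_lambda)
                             if config.noise_free else
                             rng.poisson(config.background_lambda,
                                         (size, size)).astype(float))
        return {"images": images,
                "labels": np.zeros((size, size), dtype=np.int32),
                "_cursor": [gap, gap, 0]}  # row, col, shelf height

    current = new_field()
    fields.append(current)
    for row in truth_cells.itertuples(index=False):
        h = max(1, int(round(row.length_um / config.pixel_size_um)))
        w = max(1, int(round(row.width_um / config.pixel_size_um)))
        if h + 2 * gap > size or w + 2 * gap > size:
            raise ValueError(
                f"cell {row.cell_id} ({row.length_um:.1f} x "
                f"{row.width_um:.1f} µm) does not fit the raster")
        r, c, shelf = current["_cursor"]
        if c + w + gap > size:  # next shelf
            r, c, shelf = r + shelf + gap, gap, 0
        if r + h + gap > size:  # next field
            current = new_field()
            fields.append(current)
            r, c, shelf = gap, gap, 0
        n_px = h * w
        lam12 = config.counts_per_cell / n_px
        f13 = min(row.frac13c_true, 1.0 - 1e-12)
        f15 = min(row.frac15n_true, 1.0 - 1e-12)
        lam13 = lam12 * f13 / (1.0 - f13)
        lam15 = lam12 * f15 / (1.0 - f15)
        sl = (slice(r, r + h), slice(c, c + w))
        for name, lam in (("12C14N", lam12), ("13C14N", lam13),
                          ("12C15N", lam15)):
            block = (np.full((h, w), lam) if config.noise_free
                     else rng.poisson(lam, (h, w)).astype(float))
            current["images"][name][sl] += block
        current["labels"][sl] = int(row.cell_id)
        current["_cursor"] = [r, c + w + gap, max(shelf, h)]

    for fld in fields:
        fld.pop("_cursor")
    return fields


# --------------------------------------------------------------------------
# persistence

def write_experiment(sim: SimulatedExperiment, outdir: str | Path,
                     images: bool = False) -> dict[str, Path]:
    """Write the experiment tables (and optionally TIFF images) to disk.

    Output is byte-identical for identical seeds and configs. Ground
    truth goes to its own CSVs plus a JSON scalar summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tables = {
        "cells": sim.cells, "bulk": sim.bulk, "pools": sim.pools,
        "eds": sim.eds, "ground_truth_cells": sim.truth.cells,
        "ground_truth_pools": sim.truth.pools,
        "ground_truth_contribution": sim.truth.contribution,
    }
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        paths[name] = path
    summary_path = outdir / "ground_truth_summary.json"
    summary_path.write_text(
        json.dumps(sim.truth.summary, indent=2, sort_keys=True) + "\n")
    paths["ground_truth_summary"] = summary_path
    if images:
        import tifffile
        img_dir = outdir / "images"
        img_dir.mkdir(exist_ok=True)
        fields = render_sims_images(sim.truth.cells, sim.config)
        for i, fld in enumerate(fields):
            for name, arr in fld["images"].items():
                p = img_dir / f"field{i:02d}_{name}.tif"
                tifffile.imwrite(p, np.round(arr).astype(np.uint32))
                paths[f"field{i:02d}_{name}"] = p
            p = img_dir / f"field{i:02d}_labels.tif"
            tifffile.imwrite(p, fld["labels"])
            paths[f"field{i:02d}_labels"] = p
    return paths
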