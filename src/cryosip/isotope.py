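"""Isotope bookkeeping for stable-isotope-probing experiments.

The tracer signal of every measurement in this package is an *atom%
excess*: the heavy-isotope atom percentage of a sample minus the
natural-abundance baseline. This module holds the baseline constants,
the tracer-pool mixing arithmetic (dilution of a >=98 atom% spike by the
ambient unlabelled pool), the two-timepoint pool averaging used when the
pool label declines during the incubation, and the activity threshold
that separates labelled (active) from unlabelled (inactive) cells.

Atom% values are on the 0-100 scale everywhere in the package; isotope
fractions (0-1) appear only at SIMS I/O boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import constants

__all__ = [
    "NaturalAbundance",
    "TracerAddition",
    "IsotopePool",
    "atom_percent_from_counts",
    "atom_percent_excess",
    "tracer_pool_mixing",
    "pool_excess_timeavg",
    "activity_threshold",
    "classify_active",
]


@dataclass(frozen=True)
class NaturalAbundance:
    """Natural heavy-isotope abundance of unlabelled biomass.

    ``mean_fraction`` and ``sd_fraction`` are dimensionless isotope
    fractions (heavy / (heavy + light)) measured on unlabelled control
    cells; ``n_cells`` is the number of cells behind the estimate.
    """

    element: str
    mean_fraction: float
    sd_fraction: float
    n_cells: int | None = None

    def __post_init__(self) -> None:
        if self.element not in ("C", "N"):
            raise ValueError(f"unsupported element {self.element!r}")
        if not 0.0 < self.mean_fraction < 0.5:
            raise ValueError("mean_fraction must lie in (0, 0.5)")
        if self.sd_fraction < 0.0:
            raise ValueError("sd_fraction must be >= 0")

    @property
    def mean_atom_percent(self) -> float:
        return 100.0 * self.mean_fraction

    @property
    def sd_atom_percent(self) -> float:
        return 100.0 * self.sd_fraction

    @classmethod
    def carbon(cls) -> "NaturalAbundance":
        """Measured 13C baseline of unlabelled glacier ice algae."""
        return cls("C", constants.NAT_13C_FRACTION, constants.NAT_13C_SD,
                   constants.NAT_N_CELLS)

    @classmethod
    def nitrogen(cls) -> "NaturalAbundance":
        """Measured 15N baseline of unlabelled glacier ice algae."""
        return cls("N", constants.NAT_15N_FRACTION, constants.NAT_15N_SD,
                   constants.NAT_N_CELLS)


@dataclass(frozen=True)
class TracerAddition:
    """A heavy-isotope spike added to an incubation bottle."""

    element: str
    added_concentration: float  # µM
    label_atom_percent: float  # purity of the label, atom%

    def __post_init__(self) -> None:
        if self.added_concentration <= 0.0:
            raise ValueError("added_concentration must be > 0")
        if not 0.0 < self.label_atom_percent <= 100.0:
            raise ValueError("label_atom_percent must lie in (0, 100]")


@dataclass(frozen=True)
class IsotopePool:
    """An element's dissolved pool (DIC, NH4+ or NO3-) at one timepoint.

    The pool's atom% excess is the denominator of every assimilation and
    growth rate equation in the package.
    """

    element: str
    concentration: float  # µM
    atom_percent: float
    natural_atom_percent: float
    timepoint_label: str = ""

    def __post_init__(self) -> None:
        if self.concentration < 0.0:
            raise ValueError("concentration must be >= 0")
        if not 0.0 <= self.atom_percent <= 100.0:
            raise ValueError("atom_percent must lie in [0, 100]")
        if self.atom_percent < self.natural_atom_percent - 1e-9:
            raise ValueError(
                "pool atom% below its natural abundance baseline")

    @property
    def atom_percent_excess(self) -> float:
        return self.atom_percent - self.natural_atom_percent


def atom_percent_from_counts(heavy, light):
    """Atom% from heavy/light ion counts: 100 * heavy / (heavy + light).

    Accepts scalars or arrays. Raises if any heavy+light total is zero
    (the isotope ratio is undefined without counts).
    """
    heavy = np.asarray(heavy, dtype=float)
    light = np.asarray(light, dtype=float)
    if np.any(heavy < 0) or np.any(light < 0):
        raise ValueError("counts must be non-negative")
    total = heavy + light
    if np.any(total <= 0):
        raise ValueError("undefined isotope ratio: heavy + light counts are zero")
    out = 100.0 * heavy / total
    return out if out.ndim else float(out)


def atom_percent_excess(measured, natural):
    """Measured atom% minus the natural-abundance atom%.

    Negative results (measurement noise on unlabelled material) are
    returned unclipped but flagged with a warning, so that population
    means are not biased while QC can still see them.
    """
    measured = np.asarray(measured, dtype=float)
    if np.any(measured < 0):
        raise ValueError("measured atom% must be >= 0")
    out = measured - np.asarray(natural, dtype=float)
    if np.any(out < 0):
        warnings.warn(
            "negative atom% excess encountered (below natural abundance); "
            "values preserved unclipped",
            stacklevel=2,
        )
    return out if out.ndim else float(out)


def tracer_pool_mixing(
    ambient_conc: float,
    ambient_ap: float,
    tracer: TracerAddition,
    timepoint_label: str = "T0",
) -> IsotopePool:
    """Mix a tracer spike into the ambient pool (concentration-weighted).

    The mixed atom% is the concentration-weighted mean of the label and
    the ambient pool; its excess is quoted against the *ambient* natural
    abundance.
    """
    if ambient_conc < 0:
        raise ValueError("ambient concentration must be >= 0")
    total = ambient_conc + tracer.added_concentration
    if total <= 0:
        raise ValueError("cannot mix an empty pool")
    mixed_ap = (
        tracer.added_concentration * tracer.label_atom_percent
        + ambient_conc * ambient_ap
    ) / total
    return IsotopePool(
        element=tracer.element,
        concentration=total,
        atom_percent=mixed_ap,
        natural_atom_percent=ambient_ap,
        timepoint_label=timepoint_label,
    )


def pool_excess_timeavg(excess_t1: float, excess_t2: float) -> float:
    """Arithmetic mean of the pool excess at two sampling timepoints.

    Used for end-of-incubation rate calculations when the pool label
    declined between the first and second sampling.
    """
    e1 = float(excess_t1)
    e2 = float(excess_t2)
    if not (np.isfinite(e1) and np.isfinite(e2)):
        raise ValueError("pool excess values must be finite")
    return 0.5 * (e1 + e2)


def activity_threshold(na: NaturalAbundance | None = None,
                       k: float = constants.ACTIVITY_K) -> float:
    """Atom% above which a cell counts as labelled: 100*(mean + k*sd)."""
    if na is None:
        na = NaturalAbundance.carbon()
    if k <= 0:
        raise ValueError("k must be > 0")
    return 100.0 * (na.mean_fraction + k * na.sd_fraction)


def classify_active(cell_ap, na: NaturalAbundance | None = None,
                    k: float = constants.ACTIVITY_K):
    """Classify cells as active (labelled) or inactive.

    A cell is active when its atom% strictly exceeds the natural mean
    plus ``k`` natural standard deviations. Returns ``(active,
    threshold_atom_percent)`` where ``active`` is a bool (or bool array)
    so the threshold in use is always reported alongside the labels.
    """
    thr = activity_threshold(na, k)
    cell_ap = np.asarray(cell_ap, dtype=float)
    if np.any(cell_ap < 0):
        raise ValueError("cell atom% must be >= 0")
    active = cell_ap > thr
    return (active if active.ndim else bool(active)), thr
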