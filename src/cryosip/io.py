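"""Table readers/writers, run configuration and validation.

CSV/TSV schemas are documented per table. Unit conventions are
normalized on read: SIMS isotope ratios enter as fractions (0-1) and
stay fractions in the cell table (conversion to atom% happens in the
rate pipeline); abundances are cells ml^-1. Unparseable rows are
skipped with a logged reason (collected in ``df.attrs["skipped_rows"]``
with line numbers); parseable but out-of-range values raise
:class:`ValidationError`.
"""

from __future__ import annotations

import logging
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants

__all__ = ["ValidationError", "RunConfig", "read_cell_table",
           "read_bulk_table", "read_pool_table", "read_eds_table",
           "write_table"]

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """An input table violates its documented schema."""


@dataclass
class RunConfig:
    """Constants and paths for one analysis run."""

    seed: int = 0
    t1_hours: float = constants.T1_HOURS
    t2_hours: float = constants.T2_HOURS
    nat_13c_fraction: float = constants.NAT_13C_FRACTION
    nat_13c_sd: float = constants.NAT_13C_SD
    nat_15n_fraction: float = constants.NAT_15N_FRACTION
    nat_15n_sd: float = constants.NAT_15N_SD
    cell_density_kg_m3: float = constants.CELL_DENSITY_KG_M3
    dry_fraction: float = constants.DRY_FRACTION
    mass_fractions: dict = field(
        default_factory=lambda: dict(constants.MASS_FRACTIONS))
    activity_k: float = constants.ACTIVITY_K
    roi_estimator: str = "pixel_mean"
    content_basis: str = "population_mean"
    abundance_per_ml: float = 16.2e3
    abundance_sd_per_ml: float = 1.2e3
    active_fraction: float = 0.90
    output_dir: str = "cryosip_out"

    def __post_init__(self) -> None:
        for name in ("t1_hours", "t2_hours", "nat_13c_fraction",
                     "nat_15n_fraction", "cell_density_kg_m3",
                     "dry_fraction", "activity_k"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a plain-text key = value (TOML) configuration file.

        Keyword overrides (e.g. from CLI options) win over file values.
        """
        data = tomllib.loads(Path(path).read_text())
        known = {f.name for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
        unknown = set(data) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


# --------------------------------------------------------------------------
# schemas: column -> (required, validator or None)

def _fraction(v): return 0.0 <= v <= 1.0
def _nonneg(v): return v >= 0.0
def _atom_percent(v): return 0.0 <= v <= 100.0
def _positive(v): return v > 0.0


_CELL_SCHEMA = {
    "cell_id": (True, None),
    "treatment": (True, None),
    "timepoint": (True, None),
    "frac13c": (True, _fraction),
    "frac15n": (False, _fraction),
    "length_um": (False, _positive),
    "width_um": (False, _positive),
    "taxon": (False, None),
}
_BULK_SCHEMA = {
    "treatment": (True, None),
    "timepoint": (True, None),
    "replicate": (True, None),
    "poc_umol_l": (True, _nonneg),
    "pon_umol_l": (True, _nonneg),
    "ap13c_poc": (True, _atom_percent),
    "ap15n_pon": (True, _atom_percent),
}
_POOL_SCHEMA = {
    "treatment": (True, None),
    "substrate": (True, None),
    "timepoint": (True, None),
    "concentration_um": (True, _nonneg),
    "atom_percent": (True, _atom_percent),
    "natural_atom_percent": (True, _atom_percent),
}
_EDS_SCHEMA = {
    "cell_id": (True, None),
    "atom_percent_c": (True, _nonneg),
    "atom_percent_n": (True, _nonneg),
    "atom_percent_p": (True, _nonneg),
}

_STRING_COLUMNS = {"treatment", "timepoint", "substrate", "taxon",
                   "cell_id", "replicate"}


def _read_table(path: str | Path, schema: dict, name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=True,
                     skip_blank_lines=True)
    missing = [c for c, (req, _) in schema.items()
               if req and c not in df.columns]
    if missing:
        raise ValidationError(
            f"{name} table {path} is missing required column(s): {missing}")

    numeric_cols = [c for c in schema if c in df.columns
                    and c not in _STRING_COLUMNS]
    skipped: list[tuple[int, str]] = []
    keep = np.ones(len(df), dtype=bool)
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        for idx in df.index[bad]:
            # +2: header line and 1-based numbering
            skipped.append((int(idx) + 2, f"unparseable {col}={df.at[idx, col]!r}"))
        keep &= ~bad.to_numpy()
        df[col] = parsed
    for line, reason in skipped:
        log.warning("%s table %s line %d skipped: %s", name, path, line, reason)
    df = df[keep].reset_index(drop=True)

    for col, (required, check) in schema.items():
        if col not in df.columns or check is None:
            continue
        vals = df[col]
        present = vals.notna()
        if required and not present.all():
            raise ValidationError(
                f"{name} table {path}: required column {col!r} has "
                "missing values")
        bad = present & ~vals[present].map(check).reindex(vals.index,
                                                          fill_value=True)
        if bad.any():
            first = df.index[bad][0]
            raise ValidationError(
                f"{name} table {path} line {int(first) + 2}: "
                f"{col}={vals[first]!r} is out of range")
    df.attrs["skipped_rows"] = skipped
    return df


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Per-cell ROI table: cell_id, treatment, timepoint, frac13c
    (fraction, 0-1), frac15n, length_um, width_um[, taxon]."""
    return _read_table(path, _CELL_SCHEMA, "cell")


def read_bulk_table(path: str | Path) -> pd.DataFrame:
    """EA-IRMS bottle table: treatment, timepoint, replicate,
    poc_umol_l, pon_umol_l, ap13c_poc, ap15n_pon (atom%)."""
    return _read_table(path, _BULK_SCHEMA, "bulk")


def read_pool_table(path: str | Path) -> pd.DataFrame:
    """Dissolved pool table: treatment, substrate (DIC/NH4/NO3),
    timepoint, concentration_um, atom_percent, natural_atom_percent."""
    return _read_table(path, _POOL_SCHEMA, "pool")


def read_eds_table(path: str | Path) -> pd.DataFrame:
    """SEM-EDS table: cell_id plus atom_percent_c/n/p (and optionally
    further elements and mass_percent columns)."""
    return _read_table(path, _EDS_SCHEMA, "eds")


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    """Write a tidy CSV (UTF-8, '.' decimal); returns the path."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path
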