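"""Physical and biological constants used throughout the package.

All atom% quantities are on the 0-100 scale; isotope *fractions* (0-1)
appear only at SIMS I/O boundaries and are converted on read.
"""

#: Standard atomic masses (g mol^-1) for the elements tracked per cell.
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}

#: Natural heavy-isotope fractions of unlabelled glacier ice algal cells,
#: measured on non-incubated control cells (n = 29).
NAT_13C_FRACTION = 0.0111
NAT_13C_SD = 0.00016
NAT_15N_FRACTION = 0.0037
NAT_15N_SD = 0.00006
NAT_N_CELLS = 29

#: Natural abundance of the dissolved N pools (atom% 15N) used for tracer
#: dilution corrections.
NAT_15N_POOL_ATOM_PERCENT = 0.36

#: Canonical marine plankton (Redfield) reference stoichiometry.
REDFIELD = {"C:N": 6.6, "C:P": 116.0, "N:P": 16.0}

#: Buoyant density of glacier ice algal cells (kg m^-3).
CELL_DENSITY_KG_M3 = 1160.0
#: Dry mass fraction of wet cell mass.
DRY_FRACTION = 0.28
#: Median dry-mass fractions of C, N and P in glacier ice algal cells.
MASS_FRACTIONS = {"C": 0.72, "N": 0.04, "P": 0.04}

#: Default activity-threshold multiplier: a cell is active when its 13C
#: atom% exceeds the natural mean by more than this many natural SDs.
ACTIVITY_K = 3.0

#: Default incubation sampling times (hours after tracer addition).
T1_HOURS = 6.0
T2_HOURS = 30.0

HOURS_PER_DAY = 24.0
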