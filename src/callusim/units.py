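"""Central unit ledger.

Internal conventions used throughout the package:

* lengths          mm   (cell-site spacing is also exposed in µm)
* forces           N    -> stresses / moduli in MPa (N/mm^2)
* concentrations   ng/cm^3
* masses of BMP-2  µg for carrier bookkeeping, ng inside the field
* time             days for biological rates, hours for the iteration step,
                   minutes for the sponge retention schedule, seconds for
                   load ramps
* permeability     table units of 1e-14 m^4/(N s), converted to mm^4/(N s)
"""

from __future__ import annotations

# --- time ---
HOURS_PER_DAY = 24.0
MINUTES_PER_DAY = 1440.0
SECONDS_PER_DAY = 86400.0


def hours_to_days(h: float) -> float:
    return h / HOURS_PER_DAY


def days_to_minutes(d: float) -> float:
    return d * MINUTES_PER_DAY


# --- length / volume ---
MM_PER_CM = 10.0
UM_PER_MM = 1000.0
MM3_PER_CM3 = 1000.0
UM3_PER_MM3 = 1e9


def mm_to_um(x: float) -> float:
    return x * UM_PER_MM


def um_to_mm(x: float) -> float:
    return x / UM_PER_MM


def mm3_to_cm3(v: float) -> float:
    return v / MM3_PER_CM3


# --- mass ---
NG_PER_UG = 1000.0


def ug_to_ng(m: float) -> float:
    return m * NG_PER_UG


# --- permeability ---
# Table values are given in units of 1e-14 m^4/(N s).
# 1 m^4 = 1e12 mm^4, hence 1e-14 m^4/(N s) = 1e-2 mm^4/(N s).
PERM_TABLE_TO_MM4 = 1e-2
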