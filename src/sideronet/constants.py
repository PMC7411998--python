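"""Pinned physical constants used throughout the package.

The monoisotopic masses below are the single source of truth for every
calculated mass in this package; tests reference this table rather than
re-declaring values.  Masses are IUPAC/CODATA monoisotopic atomic masses
(most abundant isotope) in Da.
"""

from __future__ import annotations

#: Version tag for the constants table.  Bump when a mass is changed so that
#: downstream results can be traced to the table that produced them.
CONSTANTS_VERSION = "2024.1"

#: Monoisotopic mass (Da) of the most abundant isotope of each supported
#: element.  C is exactly 12 by definition.  Fe is included only so that
#: ferrioxamine (iron-bound) reference-library entries can be mass-checked;
#: formula *enumeration* is restricted to CHNO.
MONOISOTOPIC_MASS: dict[str, float] = {
    "C": 12.0,
    "H": 1.0078250319,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "Na": 22.98976928,
    "Fe": 55.9349375,
}

#: Electron rest mass in Da.  Charged-species m/z values are computed
#: *without* subtracting the electron mass by default ("proton added as a
#: neutral H atom"), which is the convention used for printed calculated
#: [M+H]+ values in the dereplication literature this package targets.
#: Pass ``electron_correction=True`` where supported to get the physically
#: exact m/z.
ELECTRON_MASS = 0.00054857990907

#: Convenience derived masses (Da).
MASS_H = MONOISOTOPIC_MASS["H"]
MASS_H2O = 2 * MASS_H + MONOISOTOPIC_MASS["O"]
MASS_O = MONOISOTOPIC_MASS["O"]
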