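"""Shared physical constants: isotope masses and natural abundances.

Every mass computed anywhere in the package traces back to this single
table, so that synthetic spectra, formula enumeration and isotope-pattern
verification are mutually consistent by construction.

Masses are monoisotopic atomic masses in Da (AME2020 / IUPAC); abundances
are IUPAC representative natural abundances.
"""

from __future__ import annotations

# electron rest mass, Da
ELECTRON_MASS = 0.000548579909

# Per element: list of (isotope mass, natural abundance), most abundant first.
# The first entry is the isotope used for monoisotopic masses.
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "H": [(1.00782503207, 0.999885), (2.01410177785, 0.000115)],
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [
        (15.99491461957, 0.99757),
        (17.99915961286, 0.00205),
        (16.99913175650, 0.00038),
    ],
    "P": [(30.97376199842, 1.0)],
    "S": [
        (31.9720711744, 0.9499),
        (33.967867004, 0.0425),
        (32.9714589098, 0.0075),
        (35.96708071, 0.0001),
    ],
    # Li: 7Li dominates; the 6Li isotopologue of Li+ adducts sits
    # 1.00088 Da below the parent at ~8.2% of its intensity.
    "Li": [(7.0160034366, 0.9241), (6.0151228874, 0.0759)],
    "Na": [(22.9897692820, 1.0)],
    "K": [(38.9637064864, 0.932581), (40.9618252579, 0.067302),
          (39.963998166, 0.000117)],
}

#: monoisotopic mass of each element (leading isotope), Da
MONO_MASS: dict[str, float] = {el: iso[0][0] for el, iso in ISOTOPES.items()}

#: mass gap between the two lithium isotopes (7Li − 6Li), Da
LI7_LI6_DELTA = ISOTOPES["Li"][0][0] - ISOTOPES["Li"][1][0]
#: expected intensity ratio of a 6Li isotopologue relative to the 7Li peak
LI6_LI7_RATIO = ISOTOPES["Li"][1][1] / ISOTOPES["Li"][0][1]

#: mass gap 13C − 12C, Da
C13_C12_DELTA = ISOTOPES["C"][1][0] - ISOTOPES["C"][0][0]
#: per-carbon intensity ratio of the M+1 (13C) isotopologue
C13_C12_RATIO = ISOTOPES["C"][1][1] / ISOTOPES["C"][0][1]

#: mass of a proton (1H minus one electron), Da
PROTON_MASS = MONO_MASS["H"] - ELECTRON_MASS


def check_abundances() -> None:
    """Raise if any element's abundances do not sum to 1 within 1e-4."""
    for el, iso in ISOTOPES.items():
        total = sum(a for _, a in iso)
        if abs(total - 1.0) > 1e-4:
            raise ValueError(f"abundances for {el} sum to {total}")
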