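"""Putative metabolite annotation for positive-mode direct-infusion spectra.

Covers exact-mass arithmetic on elemental compositions, bounded enumeration
of candidate molecular formulae within a ppm tolerance, matching against a
small packaged compound table, verification of isotopologue partners
(13C M+1, and the 6Li partner of Li+ adducts at −1.0009 Da / ~8% relative
intensity), and mass-consistency annotation of the taurine-lipid
neutral-loss series: losses of fatty acyl units from a fixed backbone of
taurine condensed with a C20H34O2 (306 Da) unit.

A formula is a plain ``dict[str, int]`` of element counts; parsing from
Hill-style strings ("C6H14N4O2") is provided. All masses derive from the
isotope table in :mod:`difms.constants`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import (C13_C12_DELTA, C13_C12_RATIO, ELECTRON_MASS,
                        ISOTOPES, LI6_LI7_RATIO, LI7_LI6_DELTA, MONO_MASS)
from .spectra_io import PeakList

Formula = dict[str, int]

_FORMULA_RE = re.compile(r"([A-Z][a-z]?)(\d*)")

# default element bounds for formula enumeration (positive-mode small
# molecules and lipids); configurable per call
DEFAULT_BOUNDS: dict[str, int] = {"C": 60, "H": 120, "N": 15, "O": 30, "P": 6, "S": 4}

WATER: Formula = {"H": 2, "O": 1}
TAURINE: Formula = {"C": 2, "H": 7, "N": 1, "O": 3, "S": 1}
#: the invariant 306 Da unit of the taurine lipids
C20_UNIT: Formula = {"C": 20, "H": 34, "O": 2}


def parse_formula(text: str) -> Formula:
    """Parse ``"C6H14N4O2"`` into element counts. Unknown elements raise."""
    counts: Formula = {}
    pos = 0
    for m in _FORMULA_RE.finditer(text):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
        if not m.group(0):
            break
        el, n = m.group(1), int(m.group(2) or 1)
        if el not in ISOTOPES:
            raise ValueError(f"unknown element {el!r} in {text!r}")
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    if pos != len(text):
        raise ValueError(f"cannot parse formula {text!r} at {text[pos:]!r}")
    return counts


def format_formula(formula: Formula) -> str:
    """Hill order: C, H, then other elements alphabetically."""
    parts = []
    for el in ["C", "H"] + sorted(set(formula) - {"C", "H"}):
        n = formula.get(el, 0)
        if n:
            parts.append(el + (str(n) if n > 1 else ""))
    return "".join(parts)


def formula_add(a: Formula, b: Formula, sign: int = 1) -> Formula:
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
        if out[el] < 0:
            raise ValueError(f"negative count for {el} in formula arithmetic")
        if out[el] == 0:
            del out[el]
    return out


def monoisotopic_mass(formula: Formula) -> float:
    """Sum of leading-isotope masses; empty formula has mass 0."""
    mass = 0.0
    for el, n in formula.items():
        if el not in MONO_MASS:
            raise ValueError(f"unknown element {el!r}")
        if n < 0:
            raise ValueError(f"negative count for {el}")
        mass += n * MONO_MASS[el]
    return mass


@dataclass(frozen=True)
class AdductSpec:
    """Positive-mode adduct: atoms added to the neutral molecule and charge."""

    name: str
    added: Formula
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ValueError("positive-mode adducts require charge >= 1")

    @property
    def delta_mass(self) -> float:
        return monoisotopic_mass(self.added)


M_PLUS_H = AdductSpec("M+H", {"H": 1})
M_PLUS_NA = AdductSpec("M+Na", {"Na": 1})
M_PLUS_K = AdductSpec("M+K", {"K": 1})
M_PLUS_LI = AdductSpec("M+Li", {"Li": 1})
M_PLUS_NH4 = AdductSpec("M+NH4", {"N": 1, "H": 4})
M_PLUS_2H = AdductSpec("M+2H", {"H": 2}, charge=2)

DEFAULT_ADDUCTS = [M_PLUS_H, M_PLUS_NA, M_PLUS_K, M_PLUS_LI]
ADDUCTS_BY_NAME = {a.name: a for a in
                   [M_PLUS_H, M_PLUS_NA, M_PLUS_K, M_PLUS_LI, M_PLUS_NH4, M_PLUS_2H]}


def adduct_mz(formula: Formula, adduct: AdductSpec) -> float:
    """m/z of the adduct ion: (M + added atoms − z·m_e) / z."""
    mz = (monoisotopic_mass(formula) + adduct.delta_mass
          - adduct.charge * ELECTRON_MASS) / adduct.charge
    if mz <= 0:
        raise ValueError("adduct m/z must be positive")
    return mz


def rdbe(formula: Formula) -> float:
    """Rings-plus-double-bonds equivalent of a neutral formula.

    Monovalent metals (Li, Na, K) count like hydrogen.
    """
    c = formula.get("C", 0)
    h = (formula.get("H", 0) + formula.get("Li", 0) + formula.get("Na", 0)
         + formula.get("K", 0))
    n = formula.get("N", 0) + formula.get("P", 0)
    return c - h / 2.0 + n / 2.0 + 1.0


def ppm_error(observed_mz: float, theoretical_mz: float) -> float:
    """Signed error in ppm, referenced to the theoretical mass."""
    return 1e6 * (observed_mz - theoretical_mz) / theoretical_mz


@dataclass
class FormulaCandidate:
    formula: Formula
    adduct: AdductSpec
    theoretical_mz: float
    ppm_error: float
    rdbe: float
    db_hits: list[str] = field(default_factory=list)

    def __repr__(self):
        hits = f" {self.db_hits}" if self.db_hits else ""
        return (f"<{format_formula(self.formula)} [{self.adduct.name}]+ "
                f"{self.theoretical_mz:.5f} Th {self.ppm_error:+.3f} ppm"
                f" rdbe={self.rdbe:g}{hits}>")


# element iteration order for the nested search: heavy/rare first, H solved
# last from the mass residual
_ENUM_ORDER = ["S", "P", "N", "O", "C"]


def enumerate_formulas(observed_mz: float,
                       adducts: list[AdductSpec] | None = None,
                       tol_ppm: float = 1.0,
                       element_bounds: dict[str, int] | None = None,
                       require_integer_rdbe: bool = True) -> list[FormulaCandidate]:
    """All CHNOPS compositions whose adduct ion matches ``observed_mz``.

    Nested search over S, P, N, O, C with partial-mass pruning; the hydrogen
    count is solved from the mass residual, which makes the search exhaustive
    over the bounds without iterating H. Candidates with negative RDBE are
    discarded; non-integer RDBE (radical ions, not expected for even-electron
    electrospray adducts) is filtered when ``require_integer_rdbe``.
    Results are sorted by \\|ppm error| (ties: formula string).
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be > 0")
    if adducts is None:
        adducts = DEFAULT_ADDUCTS
    bounds = dict(DEFAULT_BOUNDS)
    if element_bounds:
        bounds.update(element_bounds)
    h_mass = MONO_MASS["H"]
    out: list[FormulaCandidate] = []
    for adduct in adducts:
        # neutral monoisotopic target mass and absolute window
        target = (observed_mz * adduct.charge + adduct.charge * ELECTRON_MASS
                  - adduct.delta_mass)
        tol_da = tol_ppm * 1e-6 * observed_mz * adduct.charge
        if target <= 0:
            continue
        lo, hi = target - tol_da, target + tol_da

        def recurse(idx: int, mass: float, counts: Formula):
            if mass > hi:
                return
            if idx == len(_ENUM_ORDER):
                residual = target - mass
                if residual < -tol_da:
                    return
                h_guess = int(round(residual / h_mass))
                for h in {max(h_guess - 1, 0), h_guess, h_guess + 1}:
                    if h < 0 or h > bounds.get("H", 0):
                        continue
                    total = mass + h * h_mass
                    if lo <= total <= hi:
                        f = {el: n for el, n in counts.items() if n}
                        if h:
                            f["H"] = h
                        r = rdbe(f)
                        if r < 0:
                            continue
                        if require_integer_rdbe and abs(r - round(r)) > 1e-9:
                            continue
                        theo = adduct_mz(f, adduct)
                        out.append(FormulaCandidate(
                            f, adduct, theo, ppm_error(observed_mz, theo), r))
                return
            el = _ENUM_ORDER[idx]
            el_mass = MONO_MASS[el]
            n_max = min(bounds.get(el, 0), int((hi - mass) / el_mass))
            for n in range(n_max + 1):
                counts[el] = n
                recurse(idx + 1, mass + n * el_mass, counts)
            counts[el] = 0

        recurse(0, 0.0, {})
    # deduplicate identical (formula, adduct) pairs, then sort
    seen = set()
    unique = []
    for c in out:
        key = (format_formula(c.formula), c.adduct.name)
        if key not in seen:
            seen.add(key)
            unique.append(c)
    unique.sort(key=lambda c: (abs(c.ppm_error), format_formula(c.formula)))
    return unique


def load_compound_table(path: str | Path | None = None) -> dict[str, list[str]]:
    """Load the packaged (or user) compound table as formula → names.

    The packaged table is a small curated fixture (name, formula TSV) of
    ~100 marine-invertebrate metabolites and lipids; it is not a live
    database mirror.
    """
    if path is None:
        src = resources.files("difms").joinpath("data/compounds.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    table: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if lineno == 1 and line.lower().startswith("name\t"):
            continue
        name, formula_text = line.split("\t")
        key = format_formula(parse_formula(formula_text))
        names = table.setdefault(key, [])
        if name not in names:
            names.append(name)
    return table


def match_database(candidates: list[FormulaCandidate],
                   compound_table: dict[str, list[str]] | None = None
                   ) -> list[FormulaCandidate]:
    """Attach compound names whose formula equals the candidate's neutral one."""
    if compound_table is None:
        compound_table = load_compound_table()
    for c in candidates:
        c.db_hits = list(compound_table.get(format_formula(c.formula), []))
    return candidates


@dataclass
class IsotopeCheck:
    kind: str                    # "6Li" or "13C"
    passed: bool
    reason: str
    partner_mz: float | None = None
    observed_ratio: float | None = None
    expected_ratio: float | None = None


def _find_peak(pl: PeakList, mz: float, tol_ppm: float) -> int | None:
    if len(pl) == 0:
        return None
    idx = int(np.argmin(np.abs(pl.mz - mz)))
    if abs(ppm_error(pl.mz[idx], mz)) <= tol_ppm:
        return idx
    return None


def verify_isotope_pattern(pl: PeakList, observed_mz: float,
                           candidate: FormulaCandidate,
                           tol_ppm: float = 1.5,
                           ratio_tolerance: float = 2.0) -> list[IsotopeCheck]:
    """Check isotopologue partners of an annotated peak.

    For Li adducts, the 6Li partner is sought at m/z − 1.00088 with expected
    relative intensity 0.0759/0.9241 ≈ 0.082 — the familiar "~8% at
    −1.0009 Da" signature of lithium adducts. For carbon-containing candidates, the 13C M+1
    partner is sought at +1.00336·(1/z) with expected ratio
    nC · (0.0107/0.9893). A check passes when the partner exists at the
    expected spacing within ``tol_ppm`` and its intensity ratio is within a
    factor of ``ratio_tolerance`` of the prediction.
    """
    checks: list[IsotopeCheck] = []
    base_idx = _find_peak(pl, observed_mz, tol_ppm)
    if base_idx is None:
        return [IsotopeCheck("base", False, "annotated peak absent from peak list")]
    base_int = pl.intensity[base_idx]
    z = candidate.adduct.charge

    def check_partner(kind: str, partner_mz: float, expected: float):
        idx = _find_peak(pl, partner_mz, tol_ppm)
        if idx is None:
            checks.append(IsotopeCheck(kind, False, "partner absent",
                                       partner_mz, None, expected))
            return
        observed = pl.intensity[idx] / base_int if base_int > 0 else np.inf
        ok = expected / ratio_tolerance <= observed <= expected * ratio_tolerance
        reason = "ok" if ok else "intensity ratio outside tolerance"
        checks.append(IsotopeCheck(kind, ok, reason, partner_mz, observed, expected))

    if candidate.adduct.added.get("Li", 0):
        check_partner("6Li", observed_mz - LI7_LI6_DELTA / z, LI6_LI7_RATIO)
    n_c = candidate.formula.get("C", 0)
    if n_c:
        check_partner("13C", observed_mz + C13_C12_DELTA / z, n_c * C13_C12_RATIO)
    return checks


# --- taurine-lipid neutral-loss series ------------------------------------

def fatty_acyl_formula(carbons: int, double_bonds: int) -> Formula:
    """Free fatty acid CnH(2n−2d)O2 for acyl shorthand ``n:d``."""
    h = 2 * carbons - 2 * double_bonds
    if carbons < 2 or h < 2:
        raise ValueError(f"impossible fatty acyl {carbons}:{double_bonds}")
    return {"C": carbons, "H": h, "O": 2}


def default_fatty_acyl_catalog() -> dict[str, Formula]:
    """Acyl label → free-fatty-acid formula for 14:0 … 22:6."""
    catalog: dict[str, Formula] = {}
    for n in range(14, 23):
        for d in range(0, 7):
            catalog[f"{n}:{d}"] = fatty_acyl_formula(n, d)
    return catalog


def taurolipid_backbone(condensed: bool = True) -> Formula:
    """Fixed backbone: taurine + C20H34O2, minus water when ``condensed``.

    The linkage chemistry is unresolved; the default assumes one
    amide/ester condensation (−H2O), with the plain sum available.
    """
    backbone = formula_add(TAURINE, C20_UNIT)
    if condensed:
        backbone = formula_add(backbone, WATER, sign=-1)
    return backbone


@dataclass
class TaurolipidAnnotation:
    precursor_mz: float
    fragment_mz: float
    matched_fatty_acyl: str
    backbone_residual_mz: float
    backbone_ppm_error: float
    loss_ppm_error: float


def annotate_taurolipid_series(precursor_mz: float,
                               fragment_mzs: list[float] | np.ndarray,
                               fatty_acyl_catalog: dict[str, Formula] | None = None,
                               tol_ppm: float = 1.5,
                               adduct: AdductSpec = M_PLUS_H,
                               condensed_backbone: bool = True,
                               loss: str = "free_acid") -> list[TaurolipidAnnotation]:
    """Annotate fragments consistent with fatty-acid losses off the backbone.

    A (precursor, fragment) pair is annotated when the fragment matches the
    backbone adduct m/z within ``tol_ppm`` AND the precursor−fragment
    difference matches a catalogued fatty-acyl loss within ``tol_ppm``
    (referenced to the theoretical loss mass). ``loss`` selects the neutral
    lost: the free fatty acid (default) or the condensed acyl unit
    (fatty acid − H2O).
    """
    if fatty_acyl_catalog is None:
        fatty_acyl_catalog = default_fatty_acyl_catalog()
    backbone_mz = adduct_mz(taurolipid_backbone(condensed_backbone), adduct)
    annotations: list[TaurolipidAnnotation] = []
    for frag in np.atleast_1d(np.asarray(fragment_mzs, dtype=float)):
        backbone_err = ppm_error(frag, backbone_mz)
        if abs(backbone_err) > tol_ppm:
            continue
        delta = precursor_mz - frag
        for label, fa in sorted(fatty_acyl_catalog.items()):
            loss_formula = fa if loss == "free_acid" else formula_add(fa, WATER, -1)
            loss_mass = monoisotopic_mass(loss_formula) / adduct.charge
            err = 1e6 * (delta - loss_mass) / loss_mass
            if abs(err) <= tol_ppm:
                annotations.append(TaurolipidAnnotation(
                    precursor_mz, float(frag), label, backbone_mz,
                    backbone_err, err))
    return annotations
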