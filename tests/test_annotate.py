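import itertools

import numpy as np
import pytest

from difms import annotate as ann
from difms import constants as const

# Independent mass oracle: atomic masses re-typed from the NIST/CODATA
# tables, used only to cross-check the package's element table.
ORACLE_MASS = {
    "H": 1.00782503224,
    "C": 12.0,
    "N": 14.0030740052,
    "O": 15.9949146221,
    "P": 30.97376151,
    "S": 31.97207069,
    "Li": 7.01600343,
    "Na": 22.98976928,
    "K": 38.96370649,
}
ORACLE_ELECTRON = 0.00054857990946


def oracle_mass(text: str) -> float:
    return sum(n * ORACLE_MASS[el] for el, n in ann.parse_formula(text).items())


REFERENCE_FORMULAS = [
    "C2H5NO2", "C6H14N4O2", "C6H9N3O2", "C5H10N2O3", "C4H7NO4", "C5H11NO2S",
    "C11H12N2O2", "C2H7NO3S", "C9H20N2O2", "C7H15NO3", "C4H4O5", "C20H30O2",
    "C22H32O2", "C20H38O2", "C22H42O2", "C20H34O2", "C42H67NO5S",
    "C44H69NO5S", "C10H16N5O13P3", "C23H49N2O5P",
]


class TestMasses:
    @pytest.mark.parametrize("formula", REFERENCE_FORMULAS)
    def test_monoisotopic_mass_matches_independent_oracle(self, formula):
        got = ann.monoisotopic_mass(ann.parse_formula(formula))
        assert got == pytest.approx(oracle_mass(formula), abs=1e-5)

    def test_c20_unit_is_nominal_306(self):
        mass = ann.monoisotopic_mass(ann.C20_UNIT)
        assert round(mass) == 306
        assert round(mass, 4) == 306.2559

    def test_taurine_mass(self):
        assert ann.monoisotopic_mass(ann.TAURINE) == pytest.approx(125.0147,
                                                                   abs=1e-4)

    def test_empty_formula_is_zero(self):
        assert ann.monoisotopic_mass({}) == 0.0

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="unknown element"):
            ann.monoisotopic_mass({"Xx": 1})
        with pytest.raises(ValueError):
            ann.parse_formula("C2Xx3")

    def test_abundances_sum_to_one(self):
        const.check_abundances()


class TestAdducts:
    def test_protonated_water(self):
        assert ann.adduct_mz(ann.parse_formula("H2O"), ann.M_PLUS_H) == \
            pytest.approx(19.01784, abs=1e-5)

    def test_lithium_vs_proton_offset(self):
        f = ann.parse_formula("C3H6O3")
        diff = ann.adduct_mz(f, ann.M_PLUS_LI) - ann.adduct_mz(f, ann.M_PLUS_H)
        assert diff == pytest.approx(7.01546 - 1.00728, abs=2e-5)

    def test_doubly_charged_halves_isotope_spacing(self):
        f = ann.parse_formula("C10H16N5O13P3")
        single = ann.adduct_mz(f, ann.M_PLUS_H)
        double = ann.adduct_mz(f, ann.M_PLUS_2H)
        # m/z of 13C isotopologue shifts by delta/charge
        assert (single + const.C13_C12_DELTA) - single == \
            pytest.approx(2 * ((double + const.C13_C12_DELTA / 2) - double))

    def test_charge_must_be_positive(self):
        with pytest.raises(ValueError):
            ann.AdductSpec("bad", {"H": 1}, charge=0)


def brute_force_enumeration(observed_mz, adduct, tol_ppm, bounds):
    """Exhaustive nested-loop oracle over every element count combination."""
    target = observed_mz * adduct.charge + adduct.charge * const.ELECTRON_MASS \
        - adduct.delta_mass
    tol_da = tol_ppm * 1e-6 * observed_mz * adduct.charge
    hits = set()
    ranges = [range(bounds.get(el, 0) + 1) for el in ["C", "H", "N", "O", "P", "S"]]
    for c, h, n, o, p, s in itertools.product(*ranges):
        f = {k: v for k, v in
             zip(["C", "H", "N", "O", "P", "S"], [c, h, n, o, p, s]) if v}
        if not f:
            continue
        if abs(ann.monoisotopic_mass(f) - target) <= tol_da:
            r = ann.rdbe(f)
            if r >= 0 and abs(r - round(r)) < 1e-9:
                hits.add(ann.format_formula(f))
    return hits


SMALL_BOUNDS = {"C": 8, "H": 20, "N": 5, "O": 6, "P": 1, "S": 1}


class TestEnumerateFormulas:
    def test_arginine_recovered_and_matches_exhaustive_oracle(self):
        mz = ann.adduct_mz(ann.parse_formula("C6H14N4O2"), ann.M_PLUS_H)
        got = ann.enumerate_formulas(mz, [ann.M_PLUS_H], tol_ppm=1.0,
                                     element_bounds=SMALL_BOUNDS)
        names = {ann.format_formula(c.formula) for c in got}
        assert "C6H14N4O2" in names
        assert names == brute_force_enumeration(mz, ann.M_PLUS_H, 1.0,
                                                SMALL_BOUNDS)

    @pytest.mark.parametrize("mz", [151.0407, 203.0526, 260.1899])
    def test_matches_exhaustive_oracle_on_arbitrary_masses(self, mz):
        got = ann.enumerate_formulas(mz, [ann.M_PLUS_H], tol_ppm=5.0,
                                     element_bounds=SMALL_BOUNDS)
        names = {ann.format_formula(c.formula) for c in got}
        assert names == brute_force_enumeration(mz, ann.M_PLUS_H, 5.0,
                                                SMALL_BOUNDS)

    def test_tiny_tolerance_yields_empty_list(self):
        assert ann.enumerate_formulas(137.84219137, [ann.M_PLUS_H],
                                      tol_ppm=1e-4,
                                      element_bounds=SMALL_BOUNDS) == []

    def test_widening_tolerance_is_monotone(self):
        mz = 181.0719
        narrow = {ann.format_formula(c.formula) for c in
                  ann.enumerate_formulas(mz, [ann.M_PLUS_H], 1.0, SMALL_BOUNDS)}
        wide = {ann.format_formula(c.formula) for c in
                ann.enumerate_formulas(mz, [ann.M_PLUS_H], 5.0, SMALL_BOUNDS)}
        assert narrow <= wide

    def test_sorted_by_absolute_ppm_error(self):
        got = ann.enumerate_formulas(181.0719, [ann.M_PLUS_H], tol_ppm=10.0,
                                     element_bounds=SMALL_BOUNDS)
        errors = [abs(c.ppm_error) for c in got]
        assert errors == sorted(errors)


class TestDatabaseMatch:
    def test_taurine_hit(self):
        mz = ann.adduct_mz(ann.TAURINE, ann.M_PLUS_H)
        cands = ann.match_database(ann.enumerate_formulas(mz, [ann.M_PLUS_H]))
        hits = {h for c in cands for h in c.db_hits}
        assert "taurine" in hits

    def test_absent_formula_retained_with_empty_hits(self):
        c = ann.FormulaCandidate({"C": 30, "H": 62}, ann.M_PLUS_H, 423.0, 0.0, 0.0)
        ann.match_database([c])
        assert c.db_hits == []

    def test_duplicate_names_deduplicated(self, tmp_path):
        table_path = tmp_path / "c.tsv"
        table_path.write_text("name\tformula\nfoo\tC2H7NO3S\nfoo\tC2H7NO3S\n")
        table = ann.load_compound_table(table_path)
        assert table["C2H7NO3S"] == ["foo"]


def make_li_pair_peaklist(parent_mz, parent_int, ratio=None, spacing=None):
    from difms.spectra_io import PeakList
    ratio = const.LI6_LI7_RATIO if ratio is None else ratio
    spacing = const.LI7_LI6_DELTA if spacing is None else spacing
    return PeakList("s", "r", "w",
                    [parent_mz - spacing, parent_mz],
                    [parent_int * ratio, parent_int])


class TestIsotopeVerification:
    def setup_method(self):
        self.formula = ann.parse_formula("C3H6O3")  # lactate
        self.mz = ann.adduct_mz(self.formula, ann.M_PLUS_LI)
        self.cand = ann.FormulaCandidate(self.formula, ann.M_PLUS_LI,
                                         self.mz, 0.0, 1.0)

    def test_exact_pair_passes_with_published_signature(self):
        pl = make_li_pair_peaklist(self.mz, 1e6)
        checks = ann.verify_isotope_pattern(pl, self.mz, self.cand)
        li = [c for c in checks if c.kind == "6Li"][0]
        assert li.passed
        assert li.observed_ratio == pytest.approx(0.0821, abs=1e-4)
        # the printed signature: −1.0009 Da and ~8% relative intensity
        assert round(const.LI7_LI6_DELTA, 4) == 1.0009
        assert round(100 * const.LI6_LI7_RATIO) == 8

    def test_missing_partner_reports_absent(self):
        from difms.spectra_io import PeakList
        pl = PeakList("s", "r", "w", [self.mz], [1e6])
        li = [c for c in ann.verify_isotope_pattern(pl, self.mz, self.cand)
              if c.kind == "6Li"][0]
        assert not li.passed and "absent" in li.reason

    def test_wrong_spacing_fails(self):
        pl = make_li_pair_peaklist(self.mz, 1e6, spacing=0.9)
        li = [c for c in ann.verify_isotope_pattern(pl, self.mz, self.cand)
              if c.kind == "6Li"][0]
        assert not li.passed

    def test_wrong_ratio_fails(self):
        pl = make_li_pair_peaklist(self.mz, 1e6, ratio=0.5)
        li = [c for c in ann.verify_isotope_pattern(pl, self.mz, self.cand)
              if c.kind == "6Li"][0]
        assert not li.passed and "ratio" in li.reason

    def test_carbon13_partner_verified(self):
        from difms.spectra_io import PeakList
        n_c = self.formula["C"]
        pl = PeakList("s", "r", "w",
                      [self.mz, self.mz + const.C13_C12_DELTA],
                      [1e6, 1e6 * n_c * const.C13_C12_RATIO])
        c13 = [c for c in ann.verify_isotope_pattern(pl, self.mz, self.cand)
               if c.kind == "13C"][0]
        assert c13.passed
        assert c13.expected_ratio == pytest.approx(n_c * 0.0107, rel=0.02)


class TestTaurolipids:
    def test_constructed_epa_loss_is_annotated(self):
        backbone_mz = ann.adduct_mz(ann.taurolipid_backbone(), ann.M_PLUS_H)
        loss = ann.monoisotopic_mass(ann.fatty_acyl_formula(20, 5))
        precursor = backbone_mz + loss
        out = ann.annotate_taurolipid_series(precursor, [backbone_mz])
        assert [a.matched_fatty_acyl for a in out] == ["20:5"]
        assert out[0].backbone_ppm_error == pytest.approx(0.0, abs=1e-9)

    def test_non_condensed_backbone_mode(self):
        backbone_mz = ann.adduct_mz(ann.taurolipid_backbone(condensed=False),
                                    ann.M_PLUS_H)
        loss = ann.monoisotopic_mass(ann.fatty_acyl_formula(22, 6))
        out = ann.annotate_taurolipid_series(backbone_mz + loss, [backbone_mz],
                                             condensed_backbone=False)
        assert [a.matched_fatty_acyl for a in out] == ["22:6"]

    def test_empty_fragthan_list_gives_no_annotations(self):
        assert ann.annotate_taurolipid_series(700.0, []) == []

    def test_ten_ppm_perturbation_rejected_at_1p5_ppm(self):
        backbone_mz = ann.adduct_mz(ann.taurolipid_backbone(), ann.M_PLUS_H)
        loss = ann.monoisotopic_mass(ann.fatty_acyl_formula(20, 5))
        shifted = backbone_mz * (1 + 10e-6)
        assert ann.annotate_taurolipid_series(backbone_mz + loss, [shifted],
                                              tol_ppm=1.5) == []

    def test_catalog_covers_named_acyls(self):
        catalog = ann.default_fatty_acyl_catalog()
        for label in ["14:0", "20:1", "22:1", "20:5", "22:6"]:
            assert label in catalog
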