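import numpy as np
import pytest

from difms import annotate as ann
from difms import constants as const
from difms import synthetic_data as syn


class TestDesign:
    def test_full_factorial_layout(self):
        d = syn.build_design(10, n_qc=2)
        bio = d[~d["qc"]]
        assert len(bio) == 60
        assert bio["group"].value_counts().eq(10).all()
        assert set(bio["group"]) == set(syn.GROUPS)
        # t0 samples carry no CO2 treatment beyond ambient
        assert (bio.loc[bio["timepoint"] == "t0", "pco2"] == 380).all()
        assert d["qc"].sum() == 2

    def test_minimal_design(self):
        assert len(syn.build_design(1, ["a"], n_qc=0)) == 1

    def test_product_count(self):
        d = syn.build_design(3, ["a", "b"], n_qc=0)
        assert len(d) == 6
        assert d["group"].value_counts().eq(3).all()

    def test_empty_groups_rejected(self):
        with pytest.raises(ValueError):
            syn.build_design(3, [], n_qc=0)

    def test_deterministic_ordering(self):
        a = syn.build_design(4)
        b = syn.build_design(4)
        assert a.equals(b)


class TestWindows:
    def test_polar_windows_cover_70_590_in_seven(self):
        wins = syn.polar_windows()
        assert len(wins) == 7
        assert wins[0][0] == 70.0 and wins[-1][1] == pytest.approx(590.0)
        for (_, a_hi), (b_lo, _) in zip(wins, wins[1:]):
            assert a_hi - b_lo == pytest.approx(10.0)

    def test_nonpolar_windows_cover_120_1200_with_ramped_widths(self):
        wins = syn.nonpolar_windows()
        assert wins[0][0] == 120.0 and wins[-1][1] == pytest.approx(1200.0)
        widths = [hi - lo for lo, hi in wins]
        assert widths[0] == pytest.approx(100.0)
        assert max(widths) <= 200.0
        assert all(b >= a for a, b in zip(widths, widths[1:]))


def noise_free(library, seed=0, extract="polar", n_reps=2, windows=None):
    effects = syn.default_effect_model(library, seed=seed, intensity_cv=0.0,
                                       dilution_sd=0.0, dropout_threshold=0.0)
    acq = syn.AcquisitionConfig(
        windows=windows or (syn.polar_windows() if extract == "polar"
                            else syn.nonpolar_windows()),
        ppm_error_sd=0.0, n_tech_reps=2, seed=seed)
    design = syn.build_design(n_reps, n_qc=1)
    return syn.simulate_peaklists(library, effects, acq, design, extract)


class TestSimulatePeaklists:
    def test_noise_free_mzs_exactly_theoretical(self):
        lib = syn.default_library()
        exp = noise_free(lib)
        glycine_mz = ann.adduct_mz(ann.parse_formula("C2H5NO2"), ann.M_PLUS_H)
        found = False
        pl = exp.peaklists[("t0-8C-r01", "tr1", "w00")]
        for mz in pl.mz:
            if mz == glycine_mz:
                found = True
        assert found

    def test_noise_free_intensities_equal_group_means(self):
        lib = syn.default_library()
        exp = noise_free(lib)
        truth = exp.truth.set_index("metabolite")
        taurine_mz = ann.adduct_mz(ann.TAURINE, ann.M_PLUS_H)
        for grp in ["t0-8C", "t5-10C-1000"]:
            pl_key = (f"{grp}-r01", "tr1", "w00")
            pl = exp.peaklists[pl_key]
            idx = np.argmin(np.abs(pl.mz - taurine_mz))
            expected = truth.loc["taurine", f"mean_{grp}"] * 0.8  # M+H yield
            assert pl.intensity[idx] == pytest.approx(expected, rel=1e-12)

    def test_li_adduct_emits_6li_partner_with_natural_ratio(self):
        lib = [syn.MetaboliteSpec("x", ann.parse_formula("C3H6O3"), 1e6,
                                  "polar", [("M+Li", 1.0)])]
        exp = noise_free(lib, n_reps=1)
        mz_li = ann.adduct_mz(ann.parse_formula("C3H6O3"), ann.M_PLUS_LI)
        pl = None
        for (sid, rid, wid), cand in exp.peaklists.items():
            if len(cand) and np.any(np.isclose(cand.mz, mz_li)):
                pl = cand
                break
        assert pl is not None
        partner = mz_li - const.LI7_LI6_DELTA
        j = np.argmin(np.abs(pl.mz - partner))
        assert pl.mz[j] == pytest.approx(partner, abs=1e-9)
        base = pl.intensity[np.argmin(np.abs(pl.mz - mz_li))]
        ratio = pl.intensity[j] / base
        # 0.0759 / 0.9241, exact before noise
        assert ratio == pytest.approx(0.0759 / 0.9241, rel=1e-6)
        assert partner - mz_li == pytest.approx(-1.00088, abs=5e-6)

    def test_13c_partner_has_natural_abundance_ratio(self):
        lib = [syn.MetaboliteSpec("x", ann.parse_formula("C6H12O6"), 1e6,
                                  "polar", [("M+H", 1.0)])]
        exp = noise_free(lib, n_reps=1)
        mz = ann.adduct_mz(ann.parse_formula("C6H12O6"), ann.M_PLUS_H)
        pl = next(p for p in exp.peaklists.values()
                  if len(p) and np.any(np.isclose(p.mz, mz)))
        j13 = np.argmin(np.abs(pl.mz - (mz + const.C13_C12_DELTA)))
        ratio = pl.intensity[j13] / pl.intensity[np.argmin(np.abs(pl.mz - mz))]
        assert ratio == pytest.approx(6 * 0.0107 / 0.9893, rel=1e-6)

    def test_seeded_output_is_identical(self):
        lib = syn.default_library()
        effects = syn.default_effect_model(lib, seed=9)
        design = syn.build_design(2, n_qc=1)
        acq = syn.AcquisitionConfig(windows=syn.polar_windows(), seed=9)
        a = syn.simulate_peaklists(lib, effects, acq, design, "polar")
        b = syn.simulate_peaklists(lib, effects, acq, design, "polar")
        assert set(a.peaklists) == set(b.peaklists)
        for key in a.peaklists:
            np.testing.assert_array_equal(a.peaklists[key].mz,
                                          b.peaklists[key].mz)
            np.testing.assert_array_equal(a.peaklists[key].intensity,
                                          b.peaklists[key].intensity)

    def test_out_of_window_metabolite_warns_and_is_flagged(self):
        lib = [syn.MetaboliteSpec("tiny", ann.parse_formula("CH4"), 1e6,
                                  "polar", [("M+H", 1.0)])]
        with pytest.warns(UserWarning, match="tiny"):
            exp = noise_free(lib, n_reps=1)
        assert exp.truth.loc[exp.truth["metabolite"] == "tiny",
                             "excluded"].item()

    def test_truth_covers_every_library_metabolite(self):
        lib = syn.default_library()
        exp = noise_free(lib)
        polar_names = {m.name for m in lib if m.extract == "polar"}
        assert set(exp.truth["metabolite"]) == polar_names

    def test_named_metabolites_have_pinned_directions(self):
        effects = syn.default_effect_model(seed=1)
        assert effects.timepoint_log2fc["taurine"] < 0
        assert effects.timepoint_log2fc["trimethyllysine"] > 0
        assert effects.timepoint_log2fc["FA 20:5 (EPA)"] < 0
        assert effects.timepoint_log2fc["taurolipid TL(20:1)"] > 0
        assert not effects.temperature_log2fc and not effects.co2_log2fc

    def test_default_library_contains_required_species(self):
        names = {m.name for m in syn.default_library()}
        for required in ["glycine", "arginine", "histidine", "glutamine",
                         "aspartate", "methionine", "tryptophan", "taurine",
                         "trimethyllysine", "carnitine", "oxaloacetate"]:
            assert required in names
        assert sum(1 for n in names if n.startswith("taurolipid")) >= 3
        for fa in ["FA 20:1", "FA 22:1", "FA 20:5", "FA 22:6"]:
            assert any(n.startswith(fa) for n in names)


class TestWriteExperiment:
    def test_files_written_and_readable(self, tmp_path):
        lib = syn.default_library()[:3]
        exp = noise_free(lib, n_reps=1)
        syn.write_experiment(exp, tmp_path)
        assert (tmp_path / "design.csv").exists()
        assert (tmp_path / "truth.csv").exists()
        from difms.spectra_io import read_peaklist
        some = next(iter(exp.peaklists))
        from difms.spectra_io import peaklist_filename
        back = read_peaklist(tmp_path / peaklist_filename(*some))
        np.testing.assert_array_equal(back.mz, exp.peaklists[some].mz)


class TestIntensityMatrixShortcut:
    def test_shapes_and_truth(self):
        fm, labels, truth = syn.simulate_intensity_matrix(
            n_per_class=5, n_features=100, seed=1)
        assert fm.values.shape == (10, 100)
        assert (labels == "t5").sum() == 5
        assert truth["affected"].sum() == 20

    def test_affected_features_shift_by_log2fc(self):
        fm, labels, truth = syn.simulate_intensity_matrix(
            n_per_class=4, n_features=50, intensity_cv=0.0, seed=2)
        j = int(truth.index[truth["affected"]][0])
        lfc = truth.loc[j, "log2fc"]
        t0 = fm.values[labels == "t0", j].mean()
        t5 = fm.values[labels == "t5", j].mean()
        assert np.log2(t5 / t0) == pytest.approx(lfc, rel=1e-9)
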