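"""Synthetic-data generators: determinism, template fidelity, end-to-end recovery."""

import numpy as np
import pytest

from acylquin.bioassay import four_pl
from acylquin.isomer_key import classify
from acylquin.oxidation import detect_series, dominant_state
from acylquin.simulate import (
    ELUENT_PRESETS,
    MDICQA_TEMPLATES,
    NoiseModel,
    gen_dose_response,
    gen_ms1_oxidation,
    gen_msms,
    gen_tissue_table,
    reference_mdicqa,
)
from acylquin.formula import mz_ion
from acylquin.structures import neutral_formula

ISOMERS = ("cpd4", "cpd5", "cpd6", "cpd7")


def spectra_for(label, noise25=None, noise45=None):
    s25 = gen_msms(MDICQA_TEMPLATES[(label, 25)], noise25)
    s45 = (
        gen_msms(MDICQA_TEMPLATES[(label, 45)], noise45)
        if (label, 45) in MDICQA_TEMPLATES
        else None
    )
    return s25, s45


class TestMsmsGenerator:
    def test_zero_noise_reproduces_template_fractions_exactly(self):
        spec = gen_msms(MDICQA_TEMPLATES[("cpd7", 45)])
        assert spec.tic_fraction(173) == pytest.approx(0.40, abs=1e-12)
        assert spec.tic_fraction(233) == pytest.approx(0.30, abs=1e-12)

    def test_same_seed_same_spectrum(self):
        noise = NoiseModel(mz_jitter_ppm=3, intensity_cv=0.05, n_decoy_peaks=5, seed=42)
        a = gen_msms(MDICQA_TEMPLATES[("cpd4", 25)], noise)
        b = gen_msms(MDICQA_TEMPLATES[("cpd4", 25)], noise)
        assert a.peaks == b.peaks

    def test_different_seeds_differ(self):
        n1 = NoiseModel(intensity_cv=0.05, seed=1)
        n2 = NoiseModel(intensity_cv=0.05, seed=2)
        assert gen_msms(MDICQA_TEMPLATES[("cpd4", 25)], n1).peaks != \
            gen_msms(MDICQA_TEMPLATES[("cpd4", 25)], n2).peaks

    def test_decoys_keep_clear_of_key_ions(self):
        noise = NoiseModel(n_decoy_peaks=50, seed=3)
        spec = gen_msms(MDICQA_TEMPLATES[("cpd6", 25)], noise)
        template_mzs = {
            mz for mz, _ in gen_msms(MDICQA_TEMPLATES[("cpd6", 25)]).peaks
        }
        decoys = [mz for mz, _ in spec.peaks if mz not in template_mzs]
        assert len(decoys) == 50
        for mz in decoys:
            for key in (173, 233, 395):
                assert abs(mz - key) >= 0.5

    def test_end_to_end_zero_noise_all_four_isomers_called(self):
        for label in ISOMERS:
            call = classify(*spectra_for(label))
            assert call.label == label, f"{label} misclassified as {call.label}"


class TestMs1Generator:
    def test_water_preset_doubly_oxidized_dominates(self, mdicqa):
        peaks = gen_ms1_oxidation(mdicqa, "water")
        base = mz_ion(neutral_formula(mdicqa), "negative")
        assert dominant_state(detect_series(peaks, base, 2)) == "-4H"

    def test_formic_acid_preset_keeps_intact_ion_dominant(self, mdicqa):
        base = mz_ion(neutral_formula(mdicqa), "negative")
        for preset in ("formic_0.1", "formic_0.3"):
            peaks = gen_ms1_oxidation(mdicqa, preset)
            assert dominant_state(detect_series(peaks, base, 2)) == "0"

    def test_formic_03_suppresses_satellites_below_formic_01(self, mdicqa):
        base = mz_ion(neutral_formula(mdicqa), "negative")
        s01 = detect_series(gen_ms1_oxidation(mdicqa, "formic_0.1"), base, 2)
        s03 = detect_series(gen_ms1_oxidation(mdicqa, "formic_0.3"), base, 2)
        for k in (1, 2):
            assert s03.members[k][1] < s01.members[k][1]

    def test_catechol_free_structure_yields_no_satellites(
        self, kaempferol_malonyl_glucoside
    ):
        for preset in ELUENT_PRESETS:
            peaks = gen_ms1_oxidation(kaempferol_malonyl_glucoside, preset)
            assert len(peaks) == 1

    def test_single_catechol_structure_stops_at_minus_2h(self):
        peaks = gen_ms1_oxidation("LUT-7-Glc[2'':mal,6'':mal]", "formic_0.1")
        assert len(peaks) == 2

    def test_unknown_preset_rejected(self, mdicqa):
        with pytest.raises(ValueError, match="preset"):
            gen_ms1_oxidation(mdicqa, "acetonitrile")


class TestDoseResponseGenerator:
    def test_zero_sigma_equals_closed_form(self):
        dr = gen_dose_response(ic50=10.0, hill=1.3, bottom=2.0, top=95.0,
                               sigma=0.0, n_parallel=1)
        expected = four_pl(dr.doses, 2.0, 95.0, np.log(10.0), 1.3)
        assert np.allclose(dr.responses, expected)

    def test_seed_reproducible(self):
        a = gen_dose_response(ic50=10.0, sigma=3.0, seed=9)
        b = gen_dose_response(ic50=10.0, sigma=3.0, seed=9)
        assert a.responses == b.responses

    def test_doses_far_below_ic50_generate_censorable_curve(self):
        from acylquin.bioassay import fit_ic50

        dr = gen_dose_response(ic50=1000.0, doses=(0.1, 0.3, 1.0, 3.0, 10.0),
                               sigma=0.0, n_parallel=1)
        assert max(dr.responses) < 50.0
        assert fit_ic50(dr).status == "censored_above_max"

    def test_invalid_ic50_rejected(self):
        with pytest.raises(ValueError):
            gen_dose_response(ic50=-1.0)


class TestTissueGenerator:
    def test_zero_cv_records_equal_cell_means(self):
        table = gen_tissue_table(
            {("inflorescence", "flowering"): 11.5, ("leaf", "BVC"): 1.2},
            compound="cpd1", n_per_cell=3, cv=0.0,
        )
        assert len(table) == 6
        by_cell = table.groupby(["organ", "phase"])["mg_per_g"].unique()
        assert list(by_cell[("inflorescence", "flowering")]) == [11.5]
        assert list(by_cell[("leaf", "BVC")]) == [1.2]

    def test_generating_contrast_recovered(self):
        from acylquin.bioassay import summarize_tissues

        table = gen_tissue_table(
            {("inflorescence", "flowering"): 10.0, ("leaf", "flowering"): 1.0},
            compound="cpd1", n_per_cell=25, cv=0.2, seed=11,
        )
        summary = summarize_tissues(table, "cpd1")
        assert summary.fold_difference == pytest.approx(10.0, rel=0.25)

    def test_empty_profile_gives_empty_table_and_summary_error(self):
        from acylquin.bioassay import summarize_tissues

        table = gen_tissue_table({("leaf", "BVC"): 1.0}, compound="cpd1",
                                 n_per_cell=0)
        assert table.empty
        with pytest.raises(ValueError):
            summarize_tissues(table, "cpd1")

    def test_seed_reproducible(self):
        kwargs = dict(profile={("leaf", "BVC"): 2.0}, compound="c", cv=0.5, seed=3)
        assert gen_tissue_table(**kwargs).equals(gen_tissue_table(**kwargs))


def test_reference_structure_is_an_mdicqa():
    s = reference_mdicqa()
    assert s.n_caffeoyl == 2 and s.n_malonyl == 1
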