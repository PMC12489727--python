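"""Neutral-loss grammar, fragment trees and peak annotation."""

import itertools

import pytest

from acylquin.formula import monoisotopic_mass, mz_ion
from acylquin.fragments import (
    NEUTRAL_LOSSES,
    annotate_peaks,
    explain_loss,
    generate_fragments,
)
from acylquin.spectra import Spectrum
from acylquin.structures import enumerate_regioisomers, neutral_formula, parse_descriptor


class TestFragmentTrees:
    def test_mdicqa_series_covers_all_printed_ions(self, mdicqa):
        nominals = {n.nominal for n in generate_fragments(mdicqa, max_depth=3)}
        assert {515, 439, 353, 557, 395, 377, 233, 191, 179, 173} <= nominals

    def test_dimdicqa_demalonylation_and_decaffeoylation(self, dimdicqa):
        nominals = {n.nominal for n in generate_fragments(dimdicqa, max_depth=1)}
        assert {601, 525} <= nominals

    def test_flavonoid_demalonylation_then_aglycone(self, quercetin_malonyl_glucoside):
        nominals = {
            n.nominal for n in generate_fragments(quercetin_malonyl_glucoside, 3)
        }
        assert {463, 301} <= nominals  # demalonylated ion, quercetin aglycone

    def test_dimalonyl_glucoside_demalonylation_series(
        self, luteolin_dimalonyl_glucoside
    ):
        nominals = {
            n.nominal for n in generate_fragments(luteolin_dimalonyl_glucoside, 3)
        }
        assert {619, 533, 447, 285} <= nominals  # 619 -> 533 -> 447 -> luteolin

    def test_depth_zero_is_precursor_only(self, mdicqa):
        nodes = generate_fragments(mdicqa, max_depth=0)
        assert len(nodes) == 1
        (node,) = nodes
        assert node.path == ()
        assert node.nominal == 601

    def test_negative_depth_rejected(self, mdicqa):
        with pytest.raises(ValueError):
            generate_fragments(mdicqa, max_depth=-1)

    def test_deeper_trees_contain_shallower(self, mdicqa):
        for depth in range(4):
            shallow = {n.remaining for n in generate_fragments(mdicqa, depth)}
            deep = {n.remaining for n in generate_fragments(mdicqa, depth + 1)}
            assert shallow <= deep

    def test_nominal_set_identical_across_all_twelve_regioisomers(self):
        reference = None
        for isomer in enumerate_regioisomers(2, 1):
            nominals = frozenset(n.nominal for n in generate_fragments(isomer, 4))
            reference = reference or nominals
            assert nominals == reference

    def test_mass_conservation_along_paths(self, mdicqa):
        """Grammar-node m/z = precursor m/z minus the summed loss masses."""
        precursor = mz_ion(neutral_formula(mdicqa), "negative")
        for node in generate_fragments(mdicqa, max_depth=4):
            if node.is_terminal_marker:
                continue
            lost = sum(monoisotopic_mass(NEUTRAL_LOSSES[lab]) for lab in node.path)
            assert node.mz == pytest.approx(precursor - lost, abs=1e-6)

    def test_glucosyl_loss_requires_prior_demalonylation(
        self, luteolin_dimalonyl_glucoside
    ):
        for node in generate_fragments(luteolin_dimalonyl_glucoside, 4):
            if "glucosyl_residue" in node.path:
                i = node.path.index("glucosyl_residue")
                assert node.path[:i].count("malonyl_residue") == 2

    def test_grammar_matches_brute_force_loss_multiset_enumeration(self, mdicqa):
        """Oracle: exhaustively enumerate admissible loss multisets and compare."""
        precursor = neutral_formula(mdicqa)
        budget = {"malonyl_residue": 1, "caffeoyl_residue": 2, "CO2": 1, "H2O": 1}
        expected = set()
        pool = [lab for lab, n in budget.items() for _ in range(n)]
        for size in range(len(pool) + 1):
            for combo in itertools.combinations(pool, size):
                remaining = precursor
                try:
                    for lab in combo:
                        remaining = remaining - NEUTRAL_LOSSES[lab]
                except ValueError:
                    continue
                if remaining["H"] >= 1:
                    expected.add(remaining)
        got = {
            n.remaining
            for n in generate_fragments(mdicqa, max_depth=5)
            if not n.is_terminal_marker
        }
        assert got == expected


class TestAnnotation:
    def test_peak_matched_within_tolerance(self, mdicqa):
        nodes = generate_fragments(mdicqa, 3)
        node515 = next(n for n in nodes if n.nominal == 515)
        spec = Spectrum(peaks=[(node515.mz * (1 + 0.2e-6), 100.0)])
        (ann,) = annotate_peaks(spec, nodes, tol_ppm=5)
        assert ann.matched
        assert ann.matched_node.nominal == 515
        assert ann.ppm == pytest.approx(0.2, abs=0.05)

    def test_empty_spectrum_empty_report(self, mdicqa):
        assert annotate_peaks(Spectrum(peaks=[]), generate_fragments(mdicqa, 3)) == []

    def test_far_peak_unmatched(self, mdicqa):
        spec = Spectrum(peaks=[(500.0, 10.0)])
        (ann,) = annotate_peaks(spec, generate_fragments(mdicqa, 3), tol_ppm=5)
        assert not ann.matched
        assert ann.ppm is None

    def test_empty_node_set_leaves_all_unannotated(self):
        spec = Spectrum(peaks=[(233.0661, 70.0)])
        (ann,) = annotate_peaks(spec, set(), tol_ppm=5)
        assert not ann.matched


class TestExplainLoss:
    def test_malonyl_residue_loss(self):
        assert explain_loss(601.12, 515.12)[0] == ("malonyl_residue",)

    def test_co2_loss(self):
        assert explain_loss(601.12, 557.13)[0] == ("CO2",)

    def test_identity_explained_by_empty_combination(self):
        assert explain_loss(601.12, 601.12) == [()]

    def test_caffeoyl_vs_glucosyl_disambiguated_by_error_order(self):
        # both residues weigh ~162; caffeoyl (162.0317) is nearer this delta
        combos = explain_loss(601.1199, 439.0882, tol_mDa=25)
        assert combos[0] == ("caffeoyl_residue",)
        assert ("glucosyl_residue",) in combos

    def test_parent_below_fragment_rejected(self):
        with pytest.raises(ValueError):
            explain_loss(439.0, 601.0)

    def test_no_match_outside_tolerance(self):
        assert explain_loss(601.12, 590.0, tol_mDa=5) == []
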