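"""Utilization spectra, minimal carbon combinations, supplement essentiality."""

import numpy as np
import pytest

from hydroscreen.gem import build_draft_model
from hydroscreen.fba import apply_medium, check_growth, solve_fba
from hydroscreen.spectrum import (
    NoGrowthError,
    characterize_model,
    detect_essential_supplements,
    find_minimal_carbon_combination,
    single_carbon_spectrum,
)
from hydroscreen.synthetic import (
    GroundTruthEntry,
    SyntheticConfig,
    generate_cohort,
    instantiate_model,
)

from oracles import exhaustive_min_combo


def _medium(base, carbons=(), supplements=(), rate=10.0):
    extra = {f"{c}_e": rate for c in carbons}
    extra.update({f"{s}_e": rate for s in supplements})
    return base.plus("probe", extra)


@pytest.fixture(scope="module")
def supps(small_template):
    return small_template.supplement_panel.ids


class TestSingleCarbonSpectrum:
    def test_planted_single_grower_true_only_at_its_carbons(self, small_template, base):
        usable = frozenset({"c03_galactose", "c05_xylose"})
        entry = GroundTruthEntry(True, usable, frozenset({"c03_galactose"}), frozenset())
        m = instantiate_model(entry, small_template)
        calls = single_carbon_spectrum(m, small_template.carbon_panel, base)
        by_carbon = dict(zip(small_template.carbon_panel.ids, calls))
        assert {c for c, g in by_carbon.items() if g} == set(usable)

    def test_ec_empty_draft_all_false(self, small_template, base):
        m = build_draft_model(set(), small_template)
        assert not any(single_carbon_spectrum(m, small_template.carbon_panel, base))

    def test_base_containing_a_panel_carbon_rejected(self, small_template, base):
        poisoned = base.plus("bad", {"c01_glucose_e": 5.0})
        m = build_draft_model(set(), small_template)
        with pytest.raises(ValueError, match="c01_glucose"):
            single_carbon_spectrum(m, small_template.carbon_panel, poisoned)

    def test_spectra_recover_planted_usable_carbons(self, small_cohort,
                                                    small_template, base, supps):
        """Planted-vs-recovered agreement across a whole cohort."""
        _, records, truth = small_cohort
        base_s = _medium(base, supplements=supps)
        for r in records[:25]:
            entry = truth.entries[r.mag_id]
            m = instantiate_model(entry, small_template, r.mag_id)
            calls = single_carbon_spectrum(m, small_template.carbon_panel, base_s)
            found = {c for c, g in zip(small_template.carbon_panel.ids, calls) if g}
            assert found == set(entry.singly_usable_carbons)


class TestMinimalCombination:
    def test_planted_pair_recovered(self, small_template, base):
        combo = frozenset({"c02_fructose", "c04_mannose"})
        entry = GroundTruthEntry(True, combo, combo, frozenset())
        m = instantiate_model(entry, small_template)
        assert find_minimal_carbon_combination(
            m, small_template.carbon_panel, base) == combo

    def test_single_grower_short_circuits_to_size_one(self, small_template, base):
        entry = GroundTruthEntry(True, frozenset({"c05_xylose"}),
                                 frozenset({"c05_xylose"}), frozenset())
        m = instantiate_model(entry, small_template)
        assert find_minimal_carbon_combination(
            m, small_template.carbon_panel, base) == frozenset({"c05_xylose"})

    def test_nothing_grows_returns_none(self, small_template, base):
        m = build_draft_model(set(), small_template)
        assert find_minimal_carbon_combination(
            m, small_template.carbon_panel, base) is None

    def test_max_k_validation(self, small_template, base, chain_model):
        with pytest.raises(ValueError, match="max_k"):
            find_minimal_carbon_combination(
                chain_model, small_template.carbon_panel, base, max_k=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_agreement_with_exhaustive_subset_search(self, seed, small_template, base):
        """Random planted instances: the search result equals brute-force
        enumeration of all subsets up to max_k."""
        rng = np.random.default_rng(seed)
        panel = small_template.carbon_panel
        if rng.random() < 0.5:
            pair = rng.choice(5, size=2, replace=False)
            usable = frozenset(panel.ids[i] for i in pair)
            entry = GroundTruthEntry(True, usable, usable, frozenset())
        else:
            k = int(rng.integers(1, 4))
            usable = frozenset(panel.ids[i]
                               for i in rng.choice(5, size=k, replace=False))
            first = min(usable, key=panel.ids.index)
            entry = GroundTruthEntry(True, usable, frozenset({first}), frozenset())
        m = instantiate_model(entry, small_template)

        def grows(subset) -> bool:
            sol = solve_fba(apply_medium(m, _medium(base, carbons=subset)))
            return check_growth(sol)

        expected = exhaustive_min_combo(grows, panel.ids, max_k=3)
        assert find_minimal_carbon_combination(m, panel, base) == expected


class TestEssentialSupplements:
    def test_planted_auxotrophy_found(self, small_template, base, supps):
        entry = GroundTruthEntry(True, frozenset({"c01_glucose"}),
                                 frozenset({"c01_glucose"}),
                                 frozenset({"s2_thiamine"}))
        m = instantiate_model(entry, small_template)
        gm = _medium(base, carbons=["c01_glucose"], supplements=supps)
        assert detect_essential_supplements(m, gm, supps) == frozenset({"s2_thiamine"})

    def test_prototroph_has_no_essential_supplements(self, small_template, base, supps):
        entry = GroundTruthEntry(True, frozenset({"c01_glucose"}),
                                 frozenset({"c01_glucose"}), frozenset())
        m = instantiate_model(entry, small_template)
        gm = _medium(base, carbons=["c01_glucose"], supplements=supps)
        assert detect_essential_supplements(m, gm, supps) == frozenset()

    def test_double_auxotroph_leave_one_out_finds_both(self, small_template, base, supps):
        entry = GroundTruthEntry(True, frozenset({"c01_glucose"}),
                                 frozenset({"c01_glucose"}),
                                 frozenset({"s1_biotin", "s2_thiamine"}))
        m = instantiate_model(entry, small_template)
        gm = _medium(base, carbons=["c01_glucose"], supplements=supps)
        assert detect_essential_supplements(m, gm, supps) == entry.required_supplements

    def test_no_growth_is_an_explicit_report_not_empty_set(self, small_template,
                                                           base, supps):
        m = build_draft_model(set(), small_template)
        gm = _medium(base, carbons=["c01_glucose"], supplements=supps)
        with pytest.raises(NoGrowthError):
            detect_essential_supplements(m, gm, supps)


class TestCharacterize:
    def test_cohort_recovery_and_partition(self, small_cohort, small_template,
                                           base, supps):
        """growth_class, combo and supplements match planted truth; the
        class assignment is a partition."""
        _, records, truth = small_cohort
        for r in records[:30]:
            entry = truth.entries[r.mag_id]
            m = instantiate_model(entry, small_template, r.mag_id)
            s = characterize_model(m, small_template.carbon_panel, base, supps)
            assert s.growth_class == entry.growth_class
            assert s.minimal_carbon_combo == entry.minimal_carbon_combo
            assert s.required_supplements == entry.required_supplements
            assert s.usable_alone == entry.singly_usable_carbons
            # partition: exactly one class consistent with the vector/combo
            if any(s.growth):
                assert s.growth_class == "single_carbon"
            elif s.minimal_carbon_combo:
                assert s.growth_class == "multi_carbon"
            else:
                assert s.growth_class == "no_growth"

    def test_spectrum_monotone_under_richer_media(self, small_template, base, supps):
        """A carbon supporting growth alone keeps supporting it in any
        superset medium."""
        usable = frozenset({"c01_glucose", "c04_mannose"})
        entry = GroundTruthEntry(True, usable, frozenset({"c01_glucose"}), frozenset())
        m = instantiate_model(entry, small_template)
        rich = _medium(base, carbons=sorted(usable) + ["c02_fructose"],
                       supplements=supps)
        assert check_growth(solve_fba(apply_medium(m, rich)))
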