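"""Candidate-media enumeration, greedy set cover, coverage reporting."""

import math

import numpy as np
import pytest

from hydroscreen.media import (
    CandidateMedium,
    CertificationError,
    coverage_report,
    enumerate_candidate_media,
    greedy_media_cover,
    medium_satisfies,
)
from hydroscreen.spectrum import UtilizationSpectrum

from oracles import brute_force_set_cover

PANEL = ("c1", "c2", "c3", "c4")


def spec(model_id, usable=(), combo=None, supplements=(), growth_class=None):
    usable = frozenset(usable)
    if combo is None:
        combo = frozenset({min(usable)}) if usable else frozenset()
    else:
        combo = frozenset(combo)
    if growth_class is None:
        if usable:
            growth_class = "single_carbon"
        elif combo:
            growth_class = "multi_carbon"
        else:
            growth_class = "no_growth"
    growth = tuple(c in usable for c in PANEL)
    return UtilizationSpectrum(model_id, PANEL, growth, combo,
                               frozenset(supplements), growth_class)


class TestEnumeration:
    def test_identical_requirements_deduplicate(self):
        spectra = [spec("m1", usable={"c1"}), spec("m2", usable={"c1"})]
        cands = enumerate_candidate_media(spectra)
        assert len(cands) == 1
        assert cands[0].covered == {"m1", "m2"}

    def test_subsumption_covers_less_demanding_mags(self):
        spectra = [
            spec("multi", combo={"c1", "c2"}, supplements={"v1"}),
            spec("simple", usable={"c1"}),
        ]
        cands = enumerate_candidate_media(spectra)
        big = next(c for c in cands if c.carbons == {"c1", "c2"})
        assert big.covered == {"multi", "simple"}

    def test_empty_spectra_warn_and_return_empty(self, caplog):
        with caplog.at_level("WARNING"):
            assert enumerate_candidate_media([]) == []
        assert "empty" in caplog.text

    @pytest.mark.parametrize("seed", range(6))
    def test_covered_sets_equal_brute_force_requirement_check(self, seed):
        rng = np.random.default_rng(seed)
        spectra = []
        for i in range(12):
            if rng.random() < 0.75:
                usable = {PANEL[j] for j in
                          rng.choice(4, size=int(rng.integers(1, 4)), replace=False)}
                s = spec(f"m{i}", usable=usable,
                         supplements={"v1"} if rng.random() < 0.4 else ())
            else:
                pair = rng.choice(4, size=2, replace=False)
                s = spec(f"m{i}", combo={PANEL[j] for j in pair},
                         supplements={"v2"} if rng.random() < 0.4 else ())
            spectra.append(s)
        for cand in enumerate_candidate_media(spectra):
            expected = {
                s.model_id for s in spectra
                if medium_satisfies(cand.carbons, cand.supplements, s)
            }
            # independent re-derivation of the subsumption rule
            manual = set()
            for s in spectra:
                if s.growth_class == "no_growth":
                    continue
                if not s.required_supplements <= cand.supplements:
                    continue
                if s.growth_class == "single_carbon":
                    if cand.carbons & s.usable_alone:
                        manual.add(s.model_id)
                elif s.minimal_carbon_combo <= cand.carbons:
                    manual.add(s.model_id)
            assert cand.covered == expected == manual


class TestGreedyCover:
    def test_classic_example_reaches_brute_force_optimum(self):
        cands = [
            CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"m1", "m2", "m3"})),
            CandidateMedium(frozenset({"c2"}), frozenset(), frozenset({"m3", "m4"})),
            CandidateMedium(frozenset({"c3"}), frozenset(), frozenset({"m4", "m5"})),
        ]
        forms, uncoverable = greedy_media_cover(cands, {"m1", "m2", "m3", "m4", "m5"})
        assert not uncoverable
        assert [sorted(f.carbons) for f in forms] == [["c1"], ["c3"]]
        assert len(forms) == brute_force_set_cover(
            [c.covered for c in cands], frozenset({"m1", "m2", "m3", "m4", "m5"}))

    def test_single_candidate_covering_everything(self):
        cands = [CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a", "b"}))]
        forms, _ = greedy_media_cover(cands, {"a", "b"})
        assert len(forms) == 1 and forms[0].covered == {"a", "b"}
        assert forms[0].selectivity == 1.0

    def test_empty_targets_empty_output(self):
        cands = [CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a"}))]
        assert greedy_media_cover(cands, set()) == ([], frozenset())

    def test_uncoverable_targets_reported_not_raised(self):
        cands = [CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a"}))]
        forms, uncoverable = greedy_media_cover(cands, {"a", "ghost"})
        assert uncoverable == {"ghost"}
        assert forms[0].covered == {"a"}

    def test_disjoint_singletons_need_one_medium_each(self):
        cands = [CandidateMedium(frozenset({f"c{i}"}), frozenset(),
                                 frozenset({f"m{i}"})) for i in range(5)]
        forms, _ = greedy_media_cover(cands, {f"m{i}" for i in range(5)})
        assert len(forms) == 5

    def test_tie_break_prefers_fewer_components_then_lexicographic(self):
        cands = [
            CandidateMedium(frozenset({"c2", "c3"}), frozenset(), frozenset({"a"})),
            CandidateMedium(frozenset({"c9"}), frozenset(), frozenset({"a"})),
            CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a"})),
        ]
        forms, _ = greedy_media_cover(cands, {"a"})
        assert forms[0].carbons == {"c1"}

    def test_failed_certification_raises(self):
        cands = [CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a"}))]
        with pytest.raises(CertificationError, match="a"):
            greedy_media_cover(cands, {"a"}, certifier=lambda *args: False)

    @pytest.mark.parametrize("seed", range(10))
    def test_harmonic_approximation_bound_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        universe = frozenset(f"m{i}" for i in range(int(rng.integers(4, 10))))
        n_cands = int(rng.integers(2, 9))
        cands = []
        for j in range(n_cands):
            size = int(rng.integers(1, len(universe) + 1))
            covered = frozenset(rng.choice(sorted(universe), size=size, replace=False))
            cands.append(CandidateMedium(frozenset({f"c{j}"}), frozenset(), covered))
        forms, uncoverable = greedy_media_cover(cands, universe)
        covered_union = frozenset().union(*(c.covered for c in cands))
        # completeness: everything coverable is covered
        got = frozenset().union(*(f.covered for f in forms)) if forms else frozenset()
        assert got == universe & covered_union
        assert uncoverable == universe - covered_union
        opt = brute_force_set_cover([c.covered for c in cands], universe)
        d = max(len(c.covered) for c in cands)
        h_d = sum(1.0 / k for k in range(1, d + 1))
        assert len(forms) <= math.ceil(h_d * opt) + 1e-9


class TestCoverageReport:
    def test_full_cover_fraction_one(self):
        cands = [CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a", "b"}))]
        forms, _ = greedy_media_cover(cands, {"a", "b"})
        report = coverage_report(forms, {"a", "b"})
        assert report.coverage_fraction == 1.0
        assert report.n_media == 1
        assert report.agreement is None

    def test_partial_cover_fraction(self):
        cands = [CandidateMedium(frozenset({"c1"}), frozenset(), frozenset({"a"}))]
        forms, _ = greedy_media_cover(cands, {"a", "ghost"})
        report = coverage_report(forms, {"a", "ghost"})
        assert report.coverage_fraction == 0.5
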