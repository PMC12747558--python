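"""Quality filtering, triad classification and Venn accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydroscreen.screening import (
    EC_AK,
    EC_BK,
    EC_FDH,
    TIER_FAIL,
    TIER_HIGH,
    TIER_MEDIUM,
    VENN_REGIONS,
    MagRecord,
    QualityThresholds,
    RecordValidationError,
    TriadResult,
    classify_triad,
    filter_by_quality,
    venn_summary,
)


def mag(mag_id="m1", completeness=85.0, contamination=5.0, ecs=(), domain="Bacteria"):
    return MagRecord(
        mag_id=mag_id, sample_id="YT",
        taxonomy={"domain": domain, "phylum": "Bacillota", "genus": "Clostridium"},
        completeness=completeness, contamination=contamination,
        ec_numbers=frozenset(ecs),
    )


class TestQualityFilter:
    @pytest.mark.parametrize("completeness,contamination,expected_tier", [
        (85.0, 5.0, TIER_MEDIUM),     # passes base gates only
        (95.0, 2.0, TIER_HIGH),       # passes high-quality gates
        (70.0, 5.0, TIER_FAIL),       # exactly at the completeness gate fails
        (85.0, 10.0, TIER_FAIL),      # exactly at the contamination gate fails
        (90.0, 2.0, TIER_MEDIUM),     # exactly at the HQ completeness gate: not HQ
        (95.0, 5.0, TIER_MEDIUM),     # exactly at the HQ contamination gate: not HQ
        (69.9, 0.0, TIER_FAIL),
    ])
    def test_strict_inequality_boundaries(self, completeness, contamination, expected_tier):
        _, tiers = filter_by_quality([mag(completeness=completeness,
                                          contamination=contamination)])
        assert tiers["m1"] == expected_tier

    def test_passing_preserves_input_order(self):
        records = [mag(f"m{i}", completeness=60.0 + i * 10) for i in range(5)]
        passing, _ = filter_by_quality(records)
        assert [r.mag_id for r in passing] == ["m2", "m3", "m4"]

    def test_random_cohort_matches_independent_recount(self):
        rng = np.random.default_rng(1)
        records = [
            mag(f"m{i}", completeness=float(rng.uniform(50, 100)),
                contamination=float(rng.uniform(0, 15)))
            for i in range(100)
        ]
        passing, tiers = filter_by_quality(records)
        # recount applying the two strict inequalities directly
        expected = [r for r in records if r.completeness > 70.0 and r.contamination < 10.0]
        assert [r.mag_id for r in passing] == [r.mag_id for r in expected]
        expected_hq = {r.mag_id for r in expected
                       if r.completeness > 90.0 and r.contamination < 5.0}
        assert {m for m, t in tiers.items() if t == TIER_HIGH} == expected_hq

    def test_invalid_metrics_are_reported_with_mag_ids(self):
        bad = [mag("ok"), mag("too_complete", completeness=101.0),
               mag("negative", contamination=-1.0)]
        with pytest.raises(RecordValidationError, match="too_complete.*negative"):
            filter_by_quality(bad)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            filter_by_quality([])

    def test_hq_thresholds_must_be_stricter(self):
        with pytest.raises(ValueError, match="stringent"):
            QualityThresholds(min_completeness=80.0, hq_min_completeness=75.0)

    @given(
        min_c=st.floats(50, 95), max_c=st.floats(1, 20),
        tighter_c=st.floats(0, 10), tighter_k=st.floats(0, 10),
        seed=st.integers(0, 100),
    )
    @settings(max_examples=30, deadline=None)
    def test_tightening_thresholds_never_gains_mags(self, min_c, max_c,
                                                    tighter_c, tighter_k, seed):
        rng = np.random.default_rng(seed)
        records = [mag(f"m{i}", completeness=float(rng.uniform(40, 100)),
                       contamination=float(rng.uniform(0, 25))) for i in range(30)]
        loose = QualityThresholds(min_c, max_c, max(min_c, 95.0), min(max_c, 1.0))
        tight = QualityThresholds(min(min_c + tighter_c, 100.0),
                                  max(max_c - tighter_k, 0.0),
                                  100.0, 0.0)
        n_loose = len(filter_by_quality(records, loose)[0])
        n_tight = len(filter_by_quality(records, tight)[0])
        assert n_tight <= n_loose


class TestTriadClassification:
    def test_full_triad_is_candidate_under_both_rules(self):
        r = mag(ecs={EC_FDH, EC_AK, EC_BK, "1.1.1.1"})
        for rule in ("any", "all"):
            res = classify_triad(r, rule)
            assert res.venn_region == "FDH&AK&BK"
            assert res.is_candidate

    def test_no_triad_enzyme_never_candidate(self):
        res = classify_triad(mag(ecs={"1.1.1.1", "2.7.1.1"}))
        assert res.venn_region == "none"
        assert not res.is_candidate
        assert not classify_triad(mag(ecs={"1.1.1.1"}), "all").is_candidate

    def test_single_enzyme_rule_dependence(self):
        r = mag(ecs={EC_AK})
        assert classify_triad(r, "any").is_candidate
        assert not classify_triad(r, "all").is_candidate

    def test_partial_ec_strings_do_not_match(self):
        res = classify_triad(mag(ecs={"2.7.2.-", "1.17.1.-"}))
        assert not res.is_candidate

    def test_malformed_ecs_warn_but_never_raise(self, caplog):
        with caplog.at_level("WARNING"):
            res = classify_triad(mag(ecs={"not-an-ec", EC_FDH}))
        assert res.has_fdh and res.is_candidate
        assert "malformed" in caplog.text

    def test_archaeal_flag_does_not_change_candidacy(self):
        bac = classify_triad(mag(ecs={EC_FDH}, domain="Bacteria"))
        arc = classify_triad(mag(ecs={EC_FDH}, domain="Archaea"))
        assert not bac.archaeal_flag and arc.archaeal_flag
        assert bac.is_candidate == arc.is_candidate


class TestVennSummary:
    def test_empty_input_all_zero(self):
        s = venn_summary([])
        assert s.total_screened == 0 and s.total_candidates == 0
        assert all(c == 0 for c in s.region_counts.values())

    def test_disjoint_singletons(self):
        results = [classify_triad(mag(f"m{i}", ecs={ec}))
                   for i, ec in enumerate((EC_FDH, EC_AK, EC_BK))]
        s = venn_summary(results)
        assert s.region_counts["FDH"] == s.region_counts["AK"] == s.region_counts["BK"] == 1
        assert s.total_candidates == 3

    def test_random_results_match_exhaustive_tally(self):
        rng = np.random.default_rng(7)
        results = []
        for i in range(500):
            flags = rng.random(3) < 0.5
            ecs = {ec for ec, f in zip((EC_FDH, EC_AK, EC_BK), flags) if f}
            results.append(classify_triad(mag(f"m{i}", ecs=ecs)))
        s = venn_summary(results)
        # brute-force tally over all 8 subsets
        for region in VENN_REGIONS:
            want = set(region.split("&")) if region != "none" else set()
            count = sum(
                1 for r in results
                if {n for n, h in zip(("FDH", "AK", "BK"),
                                      (r.has_fdh, r.has_ak, r.has_bk)) if h} == want
            )
            assert s.region_counts[region] == count
        # partition + inclusion-exclusion
        assert sum(s.region_counts.values()) == 500 == s.total_screened
        n_f = sum(r.has_fdh for r in results)
        n_a = sum(r.has_ak for r in results)
        n_b = sum(r.has_bk for r in results)
        n_fa = sum(r.has_fdh and r.has_ak for r in results)
        n_fb = sum(r.has_fdh and r.has_bk for r in results)
        n_ab = sum(r.has_ak and r.has_bk for r in results)
        n_fab = sum(r.has_fdh and r.has_ak and r.has_bk for r in results)
        union = n_f + n_a + n_b - n_fa - n_fb - n_ab + n_fab
        assert s.total_candidates == union
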