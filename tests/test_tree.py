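"""Decision-tree classifier: rule firing, ordering, synthetic recovery."""

import numpy as np
import pytest

from mosaicbench import (
    Category,
    ContextFlag,
    CurationLabel,
    DepthThresholds,
    EvidenceConfig,
    Technology,
    TreeConfig,
    Verdict,
    classify,
    classify_all,
    finalize_benchmark,
    pre_tree_gate,
    summarize,
    wilson_bound,
)
from mosaicbench.tree import MissingHiFiError
from conftest import make_evidence

T = Technology
EASY = {ContextFlag.EASY_TO_MAP}
NO_THRESH = DepthThresholds(0.0, 0.0, 0.0)
ORTHO = EvidenceConfig.orthogonal_only()


def summary_for(counts, cfg=ORTHO, pos=1000):
    return summarize(make_evidence(counts, pos=pos), cfg)


class TestRules:
    def test_tiny_upper_bound_is_reference_confident(self):
        # oracle check first: combined upper bound for (1, 342) at 0.99 is < 0.03
        assert wilson_bound(1, 342, 0.99).upper < 0.03
        s = summary_for({T.BGI: (0, 100), T.ELEMENT: (0, 136), T.HIFI: (2, 106)})
        assert s.combined_counts.x_ci <= 2
        r = classify(s, EASY, NO_THRESH)
        assert r.category is Category.REFERENCE_CONFIDENT
        assert r.reasons[0][0] == "upper_ci"

    def test_low_depth_excluded_when_below_quantile_threshold(self):
        s = summary_for({T.BGI: (20, 100), T.HIFI: (10, 50)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        thr = DepthThresholds(min_combined_reads=200.0, min_hifi_reads=10.0)
        r = classify(s, EASY, thr)
        assert r.category is Category.EXCLUDED_LOW_DEPTH

    def test_depth_at_threshold_is_kept(self):
        # "below the quantile" is strict: equality passes
        s = summary_for({T.BGI: (30, 100), T.HIFI: (15, 50)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        thr = DepthThresholds(min_combined_reads=150.0, min_hifi_reads=50.0)
        assert classify(s, EASY, thr).category is not Category.EXCLUDED_LOW_DEPTH

    def test_germline_indel_overlap_excluded(self):
        s = summary_for({T.BGI: (20, 100), T.HIFI: (20, 106)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        r = classify(s, EASY | {ContextFlag.OVERLAPS_GERMLINE_INDEL}, NO_THRESH)
        assert r.category is Category.EXCLUDED_GERMLINE_INDEL

    def test_alt_ratio_above_half_excluded(self):
        s = summary_for({T.BGI: (60, 100), T.HIFI: (60, 100)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        assert s.combined_counts.point == pytest.approx(0.6)
        r = classify(s, EASY, NO_THRESH)
        assert r.category is Category.EXCLUDED_HIGH_RATIO

    def test_ratio_exactly_half_is_kept(self):
        s = summary_for({T.BGI: (50, 100), T.HIFI: (53, 106)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        r = classify(s, EASY, NO_THRESH)
        assert r.category is not Category.EXCLUDED_HIGH_RATIO

    def test_easy_to_map_candidate_at_inclusive_lower_threshold(self):
        s = summary_for({T.BGI: (15, 100), T.ELEMENT: (20, 136), T.HIFI: (15, 106)})
        assert s.combined.lower >= 0.05  # confirms the premise
        r = classify(s, EASY, NO_THRESH)
        assert r.category is Category.CANDIDATE_FOR_CURATION

    def test_easy_to_map_weak_lower_bound_is_uncertain(self):
        s = summary_for({T.BGI: (5, 100), T.ELEMENT: (6, 136), T.HIFI: (6, 106)})
        assert 0.03 < s.combined.upper and s.combined.lower < 0.05
        r = classify(s, EASY, NO_THRESH)
        assert r.category is Category.UNCERTAIN_REMOVE_REGION

    def test_difficult_homopolymer_excluded(self):
        s = summary_for({T.BGI: (15, 100), T.HIFI: (15, 106)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        r = classify(s, {ContextFlag.HOMOPOLYMER}, NO_THRESH)
        assert r.category is Category.EXCLUDED_HOMOPOLYMER

    def test_difficult_nonhomopolymer_uses_hifi_lower_bound(self):
        s = summary_for({T.BGI: (30, 100), T.HIFI: (20, 106)},
                        EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        assert s.hifi.lower >= 0.05
        assert classify(s, set(), NO_THRESH).category is Category.CANDIDATE_FOR_CURATION
        s2 = summary_for({T.BGI: (30, 100), T.HIFI: (5, 106)},
                         EvidenceConfig(combined_techs=(T.BGI, T.HIFI)))
        assert s2.hifi.lower < 0.05
        assert classify(s2, set(), NO_THRESH).category is Category.UNCERTAIN_REMOVE_REGION

    def test_difficult_variant_without_hifi_support_errors(self):
        s = summary_for({T.BGI: (30, 100)}, EvidenceConfig(combined_techs=(T.BGI,)))
        with pytest.raises(MissingHiFiError):
            classify(s, set(), NO_THRESH)

    def test_determinism_and_reason_trail(self):
        s = summary_for({T.BGI: (15, 100), T.ELEMENT: (20, 136), T.HIFI: (15, 106)})
        r1 = classify(s, EASY, NO_THRESH)
        r2 = classify(s, EASY, NO_THRESH)
        assert r1 == r2
        assert r1.reasons[-1][0] == "combined_lower"


class TestPreTreeGate:
    def test_normal_detection_token_dropped(self):
        ev = make_evidence({T.BGI: (15, 100)}, caller_filter="VARIANT_DETECTED_IN_NORMAL",
                           tar_depth=20)
        assert pre_tree_gate([ev]) == []

    def test_tar_depth_gate_is_strict_above_five(self):
        keep = make_evidence({T.BGI: (15, 100)}, tar_depth=6)
        drop = make_evidence({T.BGI: (15, 100)}, pos=2000, tar_depth=5)
        assert pre_tree_gate([keep, drop]) == [keep]


class TestClassifyAll:
    def test_tally_conservation(self, small_db):
        _, db, _, strats = small_db
        results, tally = classify_all(db, strats)
        assert sum(tally.values()) == len(db)
        assert len(results) == len(db)

    def test_reference_class_dominates_null_variants(self):
        """Variants with zero true VAF at full depth are nearly all
        confidently reference (upper bound tiny)."""
        rng = np.random.default_rng(11)
        db = []
        for i in range(100):
            counts = {}
            for t, d in ((T.ILLUMINA, 300), (T.BGI, 100), (T.ELEMENT, 136), (T.HIFI, 106)):
                alt = int(rng.binomial(d, 3e-4))
                counts[t] = (alt, d)
            db.append(make_evidence(counts, pos=100 + i))
        results, tally = classify_all(db, {}, thresholds=DepthThresholds(0, 0, 0.0))
        assert tally[Category.REFERENCE_CONFIDENT] >= 98

    def test_strong_mosaics_all_become_candidates(self):
        """20 easy-to-map variants at true VAF 0.15 and full depth all pass:
        the combined lower bound exceeds 0.05 with overwhelming probability."""
        rng = np.random.default_rng(12)
        db = []
        for i in range(20):
            counts = {}
            for t, d in ((T.ILLUMINA, 300), (T.BGI, 100), (T.ELEMENT, 136), (T.HIFI, 106)):
                counts[t] = (int(rng.binomial(d, 0.15)), d)
            db.append(make_evidence(counts, pos=100 + i))
        results, tally = classify_all(db, {}, thresholds=DepthThresholds(0, 0, 0.0))
        assert tally[Category.CANDIDATE_FOR_CURATION] == 20

    def test_rule_order_soundness(self, small_db):
        """Disabling a later rule never changes variants whose trail ends
        before it: re-classify with the high-ratio rule disabled and check
        variants that never reached it are unchanged."""
        _, db, _, strats = small_db
        base_cfg = TreeConfig()
        relaxed = TreeConfig(ratio_max=1.0)  # effectively disables rule 4
        base_results, _ = classify_all(db, strats, base_cfg)
        relaxed_results, _ = classify_all(db, strats, relaxed)
        for r_base, r_relax in zip(base_results, relaxed_results):
            fired = [rid for rid, _ in r_base.reasons]
            if "high_ratio" not in fired:  # trail ended before the ratio rule
                assert r_relax.category is r_base.category
                assert r_relax.reasons == r_base.reasons


class TestFinalize:
    @staticmethod
    def candidate(pos, counts):
        ev = make_evidence(counts, pos=pos)
        s = summarize(ev, ORTHO)
        r = classify(s, EASY, NO_THRESH)
        return ev.key, s, r

    def test_keep_in_range_included(self):
        key, s, r = self.candidate(100, {T.BGI: (15, 100), T.ELEMENT: (20, 136), T.HIFI: (15, 106)})
        assert r.category is Category.CANDIDATE_FOR_CURATION
        sel = finalize_benchmark([r], {key: s}, [CurationLabel(key, Verdict.KEEP)])
        assert [k for k, _ in sel.benchmark] == [key]

    def test_uncertain_verdict_marks_bed_exclusion(self):
        key, s, r = self.candidate(100, {T.BGI: (15, 100), T.ELEMENT: (20, 136), T.HIFI: (15, 106)})
        sel = finalize_benchmark([r], {key: s}, [CurationLabel(key, Verdict.UNCERTAIN)])
        assert sel.benchmark == []
        assert sel.bed_exclusion_positions == [key]

    def test_remove_verdict_is_vcf_only_exclusion(self):
        key, s, r = self.candidate(100, {T.BGI: (15, 100), T.ELEMENT: (20, 136), T.HIFI: (15, 106)})
        sel = finalize_benchmark([r], {key: s}, [CurationLabel(key, Verdict.REMOVE)])
        assert sel.vcf_exclusions == [key]
        assert sel.bed_exclusion_positions == []

    def test_keep_out_of_vaf_range_flagged_not_included(self):
        key, s, r = self.candidate(100, {T.BGI: (42, 100), T.ELEMENT: (57, 136), T.HIFI: (44, 106)})
        assert r.category is Category.CANDIDATE_FOR_CURATION
        assert s.combined.point > 0.30
        sel = finalize_benchmark([r], {key: s}, [CurationLabel(key, Verdict.KEEP)])
        assert sel.benchmark == []
        assert [k for k, _ in sel.out_of_range] == [key]

    def test_unlabeled_candidate_raises_listing_key(self):
        key, s, r = self.candidate(100, {T.BGI: (15, 100), T.ELEMENT: (20, 136), T.HIFI: (15, 106)})
        with pytest.raises(ValueError, match=str(key.pos)):
            finalize_benchmark([r], {key: s}, [])

    def test_tree_uncertain_category_feeds_bed_exclusions(self):
        key, s, _ = self.candidate(100, {T.BGI: (5, 100), T.ELEMENT: (6, 136), T.HIFI: (6, 106)})
        r = classify(s, EASY, NO_THRESH)
        assert r.category is Category.UNCERTAIN_REMOVE_REGION
        sel = finalize_benchmark([r], {key: s}, [])
        assert sel.bed_exclusion_positions == [key]
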