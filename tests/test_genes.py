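"""Gene time-course classifiers: induction, tiers, potentiation, tolerance."""

import numpy as np
import pytest

from cytomem.genes import (
    GeneTimeCourse,
    call_ifng_induced_gene,
    call_lps_inducible,
    call_potentiated,
    call_tolerized,
    classify_basal,
    classify_genes,
    persistence_tier,
)

TINY = 1e-9  # effectively no pseudo-count, for exact-ratio fixtures


def tc(values, arm="ifng_media", times=(0, 1, 3, 6, 12)):
    return GeneTimeCourse("g", arm, dict(zip(times, values)))


class TestIfngInduced:
    @pytest.mark.parametrize(
        "cpm8,ref,expected",
        [(100, 10, True), (40, 10, False)],  # 10x induced, 4x not
    )
    def test_five_fold_rule(self, cpm8, ref, expected):
        assert call_ifng_induced_gene(cpm8, ref, prior=TINY) is expected

    def test_exact_five_fold_is_inclusive(self):
        # (52 + 0.5) / (10 + 0.5) is exactly 5 after the pseudo-count
        assert call_ifng_induced_gene(52, 10, prior=0.5)


class TestPersistenceTier:
    @pytest.mark.parametrize(
        "washout,tier", [(95, "ge90"), (50, "mid20_90"), (10, "lt20")]
    )
    def test_retention_tiers(self, washout, tier):
        assert persistence_tier(100, washout) == tier

    def test_boundaries_inclusive_downward(self):
        assert persistence_tier(100, 90, prior=TINY) == "ge90"
        assert persistence_tier(100, 20, prior=TINY) == "mid20_90"


class TestLpsInducible:
    def test_max_fold_rule(self):
        assert call_lps_inducible(tc([10, 12, 30, 60, 55]), 5, prior=TINY)

    def test_flat_course_not_inducible(self):
        assert not call_lps_inducible(tc([10] * 5), 5, prior=TINY)

    def test_rux_arm_exact_four_fold_inclusive(self):
        # (41.5 + 0.5) / (10 + 0.5) is exactly 4 after the pseudo-count
        assert call_lps_inducible(
            tc([10, 10, 41.5, 10, 10], arm="ifng_rux"), 4, prior=0.5
        )

    def test_missing_post_lps_timepoints_rejected(self):
        with pytest.raises(ValueError, match="post-LPS"):
            call_lps_inducible(GeneTimeCourse("g", "pbs_media", {0: 10}), 5)


class TestPotentiated:
    def _pair(self, ratios):
        pbs = [10.0] * 5
        ifng = [10.0 * r for r in ratios]
        return tc(ifng), tc(pbs, arm="pbs_media")

    def test_contiguous_pair_detected(self):
        a, b = self._pair([1.0, 1.5, 2.25, 2.17, 2.12])
        assert call_potentiated(a, b, prior=TINY)

    def test_alternating_ratios_do_not_count(self):
        a, b = self._pair([1.0, 2.5, 1.5, 2.5, 1.5])
        assert not call_potentiated(a, b, prior=TINY)

    def test_identical_arms_not_potentiated(self):
        a, b = self._pair([1.0] * 5)
        assert not call_potentiated(a, b, prior=TINY)

    def test_basal_elevation_alone_does_not_count(self):
        # 0 h is reserved for the basal classifier, not contiguity
        a, b = self._pair([4.0, 2.5, 1.0, 1.0, 2.5])
        assert not call_potentiated(a, b, prior=TINY)

    def test_mismatched_timepoints_rejected(self):
        a = tc([10, 20, 20, 20, 20])
        b = GeneTimeCourse("g", "pbs_media", {0: 10, 1: 10, 3: 10})
        with pytest.raises(ValueError, match="mismatched"):
            call_potentiated(a, b)


class TestBasal:
    def test_equal_baselines_unchanged(self):
        assert classify_basal(tc([10] * 5), tc([10] * 5, arm="pbs_media")) == "unchanged"

    def test_fourfold_baseline_elevated(self):
        assert (
            classify_basal(tc([40] + [10] * 4), tc([10] * 5, arm="pbs_media"), prior=TINY)
            == "elevated"
        )

    def test_exact_cutoff_goes_to_elevated(self):
        # exactly at the cutoff: (20.5 + 0.5)/(10 + 0.5) is a clean 2-fold
        a = tc([20.5] + [10] * 4)
        b = tc([10] * 5, arm="pbs_media")
        assert classify_basal(a, b, l2fc_cutoff=1.0, prior=0.5) == "elevated"
        assert classify_basal(b, b, l2fc_cutoff=1.0, prior=0.5) == "unchanged"


class TestTolerized:
    def _triple(self, ratios, rux_fold):
        pbs = [10.0, 30.0, 80.0, 100.0, 60.0]
        ifng = [p * r for p, r in zip(pbs, ratios)]
        rux = [10.0, 10.0 * rux_fold, 10.0, 10.0, 10.0]
        return (
            tc(ifng),
            tc(pbs, arm="pbs_media"),
            tc(rux, arm="ifng_rux"),
        )

    def test_contiguous_suppression_with_rux_confirmation(self):
        a, b, r = self._triple([1.0, 0.4, 0.45, 0.8, 0.9], rux_fold=6)
        assert call_tolerized(a, b, r, prior=TINY)

    def test_alternating_suppression_does_not_count(self):
        a, b, r = self._triple([1.0, 0.4, 0.8, 0.4, 0.8], rux_fold=6)
        assert not call_tolerized(a, b, r, prior=TINY)

    def test_insufficient_rux_induction_blocks_call(self):
        a, b, r = self._triple([1.0, 0.4, 0.45, 0.8, 0.9], rux_fold=3)
        assert not call_tolerized(a, b, r, prior=TINY)

    def test_missing_rux_arm_is_error(self):
        a, b, _ = self._triple([1.0, 0.4, 0.45, 0.8, 0.9], rux_fold=6)
        with pytest.raises(ValueError, match="ruxolitinib"):
            call_tolerized(a, b, None)


class TestClassifyGenes:
    def test_outputs_invariant_to_uniform_cpm_rescaling(self, small_gene_sim):
        from cytomem.matrix import CountMatrix

        _, matrix, design, _ = small_gene_sim
        res1 = classify_genes(matrix, design, prior=0.5)
        scaled = CountMatrix(
            counts=matrix.counts,
            feature_ids=matrix.feature_ids,
            sample_ids=matrix.sample_ids,
            library_sizes=matrix.library_sizes * 10,  # CPM / 10
        )
        res2 = classify_genes(scaled, design, prior=0.05)  # prior rescaled too
        cols = ["lps_inducible", "potentiated", "tolerized", "basal_class"]
        assert res1.calls[cols].equals(res2.calls[cols])

    def test_potentiated_and_tolerized_never_overlap(self, small_gene_sim):
        _, matrix, design, _ = small_gene_sim
        for criteria in ("media", "rux"):
            calls = classify_genes(matrix, design, criteria=criteria).calls
            assert not (calls["potentiated"] & calls["tolerized"]).any()

    def test_tier_only_for_induced_genes(self, small_gene_sim):
        _, matrix, design, _ = small_gene_sim
        calls = classify_genes(matrix, design).calls
        not_induced = calls[~calls["ifng_induced_8h"]]
        assert (not_induced["persistence_tier"] == "not_induced").all()
        induced = calls[calls["ifng_induced_8h"]]
        assert (induced["persistence_tier"] != "not_induced").all()
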