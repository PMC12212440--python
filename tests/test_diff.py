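"""CPM, fold changes, the NB likelihood-ratio test, BH, and filters."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import chi2

from cytomem.diff import (
    acute_abundance_filter,
    bh_adjust,
    call_induced,
    cpm_normalize,
    log2_fold_change,
    nb_test,
    run_contrast,
)
from cytomem.matrix import CountMatrix, SampleDesign


def _matrix(counts, lib=None, ids=None):
    counts = np.asarray(counts)
    return CountMatrix(
        counts=counts,
        feature_ids=ids or [f"f{i}" for i in range(counts.shape[0])],
        sample_ids=[f"s{j}" for j in range(counts.shape[1])],
        library_sizes=lib,
    )


class TestCPM:
    def test_direct_arithmetic(self):
        m = _matrix([[100], [300], [600]])
        cpm = cpm_normalize(m)
        assert np.allclose(cpm["s0"], [1e5, 3e5, 6e5])

    def test_columns_sum_to_one_million(self, small_peak_sim):
        _, matrix, _, _ = small_peak_sim
        # with default (column-sum) library sizes the identity is exact
        m = _matrix(matrix.counts[:, :4])
        sums = cpm_normalize(m).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_all_zero_feature_stays_zero(self):
        m = _matrix([[0, 0], [5, 7]])
        assert (cpm_normalize(m).iloc[0] == 0).all()

    def test_zero_library_size_names_sample(self):
        m = _matrix([[1, 0], [1, 0]], lib=[2.0, 0.0])
        with pytest.raises(ValueError, match="s1"):
            cpm_normalize(m)


class TestLog2FoldChange:
    def test_fourfold_is_two(self):
        assert log2_fold_change(40, 10, prior=1e-12) == pytest.approx(2.0)

    def test_zero_vs_zero_is_zero(self):
        assert log2_fold_change(0.0, 0.0, prior=0.5) == 0.0

    @given(
        a=st.floats(0, 1e6),
        b=st.floats(0, 1e6),
        prior=st.floats(1e-3, 10),
    )
    def test_antisymmetric(self, a, b, prior):
        assert log2_fold_change(b, a, prior) == pytest.approx(
            -log2_fold_change(a, b, prior), abs=1e-9
        )

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(ValueError):
            log2_fold_change(1, 1, prior=0)


class TestNBTest:
    def test_identical_groups_give_p_one(self):
        l2fc, p = nb_test([10, 10], [10, 10], [1e6] * 2, [1e6] * 2, dispersion=0.1)
        assert p == pytest.approx(1.0)
        assert l2fc == pytest.approx(0.0)

    def test_poisson_limit_matches_closed_form_lrt(self):
        # Poisson MLEs are closed form; twice the log-likelihood gap is
        # 2*(10 ln5 + 100 ln50 - 110 ln27.5) = 85.4724...
        _, p = nb_test([5, 5], [50, 50], [1e6] * 2, [1e6] * 2, dispersion=0.0)
        lrt = chi2.isf(p, df=1)
        assert lrt == pytest.approx(85.4724, abs=0.01)

    def test_all_zero_feature_is_defined_not_error(self):
        l2fc, p = nb_test([0, 0], [0, 0], [1e6] * 2, [1e6] * 2)
        assert (l2fc, p) == (0.0, 1.0)

    def test_matches_brute_force_likelihood_maximization(self, rng):
        """The Newton path agrees with a generic optimizer to 1e-6 in p."""
        from scipy.optimize import minimize

        from cytomem.diff import nb_loglik

        for _ in range(10):
            na, nb = int(rng.integers(2, 5)), int(rng.integers(2, 5))
            sa = rng.uniform(0.5e6, 2e6, na)
            sb = rng.uniform(0.5e6, 2e6, nb)
            mu = rng.uniform(1, 200)
            phi = rng.uniform(0.01, 0.5)
            ya = rng.poisson(mu * sa / 1e6)
            yb = rng.poisson(rng.uniform(0.3, 5) * mu * sb / 1e6)
            _, p = nb_test(ya, yb, sa, sb, dispersion=phi)

            def nll_alt(x):
                la, lb = np.exp(x)
                return -(nb_loglik(ya, la * sa, phi) + nb_loglik(yb, lb * sb, phi))

            def nll_null(x):
                l0 = np.exp(x[0])
                return -(nb_loglik(ya, l0 * sa, phi) + nb_loglik(yb, l0 * sb, phi))

            x0 = np.log((ya.sum() + yb.sum()) / (sa.sum() + sb.sum()) + 1e-12)
            alt = minimize(nll_alt, [x0, x0], method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            null = minimize(nll_null, [x0], method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12})
            p_oracle = chi2.sf(max(0.0, 2 * (null.fun - alt.fun)), df=1)
            assert p == pytest.approx(p_oracle, abs=1e-6)


class TestBHAdjust:
    def test_step_up_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_adjusted_at_least_raw_and_rank_monotone(self, rng):
        p = rng.uniform(size=1000)
        adj = bh_adjust(p)
        assert (adj >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_matches_independent_implementations(self, rng):
        from statsmodels.stats.multitest import multipletests

        def step_up(p):
            # independent transcription of the BH procedure
            m = len(p)
            idx = sorted(range(m), key=lambda i: p[i])
            out = [0.0] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = idx[rank - 1]
                running = min(running, p[i] * m / rank)
                out[i] = running
            return out

        for _ in range(100):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            adj = bh_adjust(p)
            assert np.allclose(adj, step_up(list(p)), atol=1e-12)
            assert np.allclose(
                adj, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )


class TestAbundanceFilter:
    def _design(self, n_reps=1):
        rows = []
        for cond in ("unstim", "ifng_8h", "lps_8h"):
            for r in range(n_reps):
                rows.append({"sample_id": f"{cond}_r{r}", "condition": cond})
        return SampleDesign(pd.DataFrame(rows))

    def test_median_rule_hand_example(self):
        # per-condition CPM proportional to [1, 2, 3, 4]: median 2.5
        counts = np.array([[1, 1, 1], [2, 2, 2], [3, 3, 3], [4, 4, 4]]) * 100
        m = _matrix(counts, lib=[1e6] * 3)
        m.sample_ids = ["unstim_r0", "ifng_8h_r0", "lps_8h_r0"]
        keep = acute_abundance_filter(m, self._design())
        assert list(keep) == [False, False, True, True]

    def test_all_identical_features_kept(self):
        m = _matrix(np.full((5, 3), 7), lib=[1e6] * 3)
        m.sample_ids = ["unstim_r0", "ifng_8h_r0", "lps_8h_r0"]
        assert acute_abundance_filter(m, self._design()).all()

    def test_above_median_in_single_condition_suffices(self):
        # feature 0 is weak everywhere except one acute condition
        counts = np.array(
            [[1, 900, 1], [500, 500, 500], [600, 600, 600], [700, 700, 700]]
        )
        m = _matrix(counts, lib=[1e6] * 3)
        m.sample_ids = ["unstim_r0", "ifng_8h_r0", "lps_8h_r0"]
        keep = acute_abundance_filter(m, self._design())
        assert keep[0]

    def test_missing_condition_is_error(self):
        m = _matrix([[1, 1, 1]], lib=[1e6] * 3)
        m.sample_ids = ["unstim_r0", "ifng_8h_r0", "lps_8h_r0"]
        with pytest.raises(Exception, match="lps_wash"):
            acute_abundance_filter(m, self._design(), ("unstim", "lps_wash_media"))


class TestCallInduced:
    @pytest.mark.parametrize(
        "l2fc,fdr,expected",
        [
            (2.5, 0.005, True),
            (2.5, 0.02, False),
            (2.0, 0.001, False),  # strict inequality on the fold cutoff
            (2.0001, 0.01, False),  # strict inequality on the FDR cutoff
            (1.9, 0.001, False),
        ],
    )
    def test_strict_cutoffs(self, l2fc, fdr, expected):
        assert bool(call_induced(l2fc, fdr)) is expected


class TestRunContrast:
    def test_cpm_and_l2fc_invariant_to_uniform_scaling(self, small_peak_sim):
        _, matrix, design, _ = small_peak_sim
        scaled = CountMatrix(
            counts=matrix.counts * 5,
            feature_ids=matrix.feature_ids,
            sample_ids=matrix.sample_ids,
            library_sizes=matrix.library_sizes * 5,
        )
        a = run_contrast(matrix, design, "ifng_8h", "unstim")
        b = run_contrast(scaled, design, "ifng_8h", "unstim")
        assert np.allclose(a["mean_cpm_a"], b["mean_cpm_a"])
        assert np.allclose(a["l2fc"], b["l2fc"])
        # induction calls on this fixture are far from the cutoffs
        assert np.array_equal(
            call_induced(a["l2fc"], a["fdr"]), call_induced(b["l2fc"], b["fdr"])
        )

    def test_missing_condition_raises(self, small_peak_sim):
        _, matrix, design, _ = small_peak_sim
        with pytest.raises(Exception, match="no samples"):
            run_contrast(matrix, design, "nonexistent", "unstim")
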