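"""Group-level inference: sign-flip permutation tests, Holm correction,
temporal cluster permutation, and Bayesian population prevalence."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prosodecode.stats import (
    cluster_permutation_test,
    holm_adjust,
    paired_permutation_test,
    prevalence_estimate,
)


class TestPairedPermutation:
    def test_all_zero_differences_give_p_one(self):
        res = paired_permutation_test(np.full(5, 0.5), 0.5)
        assert res.p == 1.0

    def test_three_subject_enumeration(self):
        """diffs [1,2,3], one-sided greater: only +++ reaches the observed
        mean, so p = 1/8."""
        res = paired_permutation_test(np.array([1.0, 2.0, 3.0]), 0.0, side="greater")
        assert res.exhaustive
        assert res.p == pytest.approx(1 / 8)

    def test_eleven_subjects_exhaustive_2048(self):
        rng = np.random.default_rng(0)
        res = paired_permutation_test(rng.normal(0.55, 0.05, 11), 0.5, n_perm=2048)
        assert res.exhaustive and res.n_permutations == 2048

    def test_exhaustive_matches_direct_enumeration(self):
        """Exhaustive p equals a brute-force loop over all sign patterns."""
        rng = np.random.default_rng(1)
        for n in (4, 7, 11):
            d = rng.normal(0.3, 1.0, n)
            res = paired_permutation_test(d, 0.0, side="greater")
            obs = d.mean()
            count = sum(
                np.mean(np.array(s) * d) >= obs - 1e-12
                for s in itertools.product([-1, 1], repeat=n)
            )
            assert res.p == pytest.approx(count / 2**n)

    def test_random_p_converges_to_exhaustive(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.4, 1.0, 8)
        exact = paired_permutation_test(d, 0.0, n_perm=256).p
        approx = paired_permutation_test(d, 0.0, n_perm=255, rng=3)
        assert not approx.exhaustive
        assert abs(approx.p - exact) < 0.05

    def test_sides(self):
        d = np.array([1.0, 2.0, 3.0])
        p_less = paired_permutation_test(d, 0.0, side="less").p
        p_two = paired_permutation_test(d, 0.0, side="two-sided").p
        assert p_less == 1.0
        assert p_two == pytest.approx(2 / 8)

    def test_length_validation(self):
        with pytest.raises(ValueError):
            paired_permutation_test(np.array([1.0]), 0.0)


class TestHolm:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(
            holm_adjust([0.01, 0.04, 0.03]), [0.03, 0.06, 0.06]
        )

    def test_single_p_unchanged(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])

    def test_dominance_and_order_preservation(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            p = rng.random(rng.integers(1, 10))
            adj = holm_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert np.all(adj <= 1.0)
            # significance ordering never reversed
            order = np.argsort(p, kind="stable")
            assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(5)
        p = rng.random(9)
        _, adj_sm, _, _ = multipletests(p, method="holm")
        np.testing.assert_allclose(holm_adjust(p), adj_sm)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_adjusted_dominates_raw(self, pvals):
        adj = holm_adjust(pvals)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0)


class TestClusterPermutation:
    def test_planted_effect_recovered(self):
        """A strong effect confined to samples 10..20 yields a significant
        cluster overlapping that window."""
        rng = np.random.default_rng(6)
        n, T = 11, 60
        d = rng.normal(0, 1, size=(n, T))
        d[:, 10:21] += 1.5
        res = cluster_permutation_test(d, rng=0)
        assert res.exhaustive and res.n_permutations == 2048
        sig = [c for c in res.clusters if c["p"] < 0.05]
        assert any(c["start"] <= 20 and c["end"] >= 10 for c in sig)

    def test_null_data_rarely_significant(self):
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(60):
            d = rng.normal(size=(8, 30))
            res = cluster_permutation_test(d, n_perm=256, rng=rng)
            hits += any(c["p"] < 0.05 for c in res.clusters)
        assert hits <= 9  # ~5% nominal

    def test_single_timepoint_reduces_to_pointwise(self):
        """With one timepoint, the cluster p equals the sign-flip
        permutation p of the t statistic, enumerated directly."""
        rng = np.random.default_rng(8)
        d = rng.normal(1.0, 0.5, size=(6, 1))
        res = cluster_permutation_test(d, threshold=0.0, rng=0)
        assert len(res.clusters) == 1

        def tstat(v):
            return v.mean() / (v.std(ddof=1) / np.sqrt(len(v)))

        t_obs = tstat(d[:, 0])
        null = [
            max(tstat(np.array(s) * d[:, 0]), 0.0)
            for s in itertools.product([-1, 1], repeat=6)
        ]
        expected = np.mean([t >= t_obs - 1e-12 for t in null])
        assert res.clusters[0]["p"] == pytest.approx(expected)

    def test_zero_variance_warns(self):
        d = np.ones((4, 5))
        d[:, 2] = [1.0, 2.0, -1.0, -2.0]
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            cluster_permutation_test(d, rng=0)

    def test_matches_mne_cluster_test(self):
        """Cross-check observed clusters and p-values against the MNE
        implementation of the one-sample cluster permutation test."""
        mne_stats = pytest.importorskip("mne.stats")
        rng = np.random.default_rng(9)
        n, T = 10, 40
        d = rng.normal(size=(n, T))
        d[:, 15:25] += 1.0
        res = cluster_permutation_test(d, n_perm=1024, rng=0)
        t_thresh = res.threshold
        _, clusters, pvals, _ = mne_stats.permutation_cluster_1samp_test(
            d, threshold=t_thresh, n_permutations=1024, tail=1, seed=0, out_type="mask",
            verbose="error",
        )
        def span_of(cl):
            # mne may return boolean masks or tuples of slices
            if isinstance(cl, tuple):
                sl = cl[0]
                return int(sl.start), int(sl.stop - 1)
            idx = np.nonzero(np.asarray(cl).ravel())[0]
            return int(idx[0]), int(idx[-1])

        mne_spans = sorted(span_of(m) for m in clusters)
        my_spans = sorted((c["start"], c["end"]) for c in res.clusters)
        assert my_spans == mne_spans
        # p-values agree within permutation noise for each cluster
        mine = {(c["start"], c["end"]): c["p"] for c in res.clusters}
        for m, p in zip(clusters, pvals):
            assert mine[span_of(m)] == pytest.approx(p, abs=0.05)

    def test_times_reported(self):
        rng = np.random.default_rng(10)
        d = rng.normal(size=(8, 20))
        d[:, 5:10] += 2.0
        times = np.linspace(-0.4, 0.4, 20)
        res = cluster_permutation_test(d, times=times, rng=0)
        for c in res.clusters:
            assert c["t_start"] == pytest.approx(times[c["start"]])


class TestPrevalence:
    def test_full_prevalence_closed_form(self):
        """k = n = 11 at alpha 0.05: MAP 1.00, HPDI lower bound
        (0.05^(1/12) - 0.05)/0.95, printed as 0.77."""
        res = prevalence_estimate(11, 11, alpha=0.05)
        assert res.map == pytest.approx(1.0)
        expected_lo = (0.05 ** (1 / 12) - 0.05) / 0.95
        assert res.hpdi[0] == pytest.approx(expected_lo, abs=1e-6)
        assert round(res.hpdi[0], 2) == 0.77
        assert res.hpdi[1] == pytest.approx(1.0)

    def test_zero_truncation(self):
        assert prevalence_estimate(0, 11).map == 0.0

    def test_seven_of_eleven(self):
        res = prevalence_estimate(7, 11, alpha=0.05)
        assert res.map == pytest.approx((7 / 11 - 0.05) / 0.95)
        assert round(res.map, 2) == 0.62

    def test_monotonicity_and_containment(self):
        maps = [prevalence_estimate(k, 11).map for k in range(12)]
        assert all(b >= a for a, b in zip(maps, maps[1:]))
        for k in range(12):
            res = prevalence_estimate(k, 11)
            assert res.hpdi[0] <= res.map <= res.hpdi[1]
            assert 0 <= res.hpdi[0] <= res.hpdi[1] <= 1
        # MAP non-increasing in alpha
        a_small = prevalence_estimate(8, 11, alpha=0.01).map
        a_large = prevalence_estimate(8, 11, alpha=0.2).map
        assert a_small >= a_large

    def test_validation(self):
        with pytest.raises(ValueError):
            prevalence_estimate(12, 11)
        with pytest.raises(ValueError):
            prevalence_estimate(3, 11, alpha=0.0)

    @settings(derandomize=True, max_examples=40)
    @given(
        st.integers(min_value=1, max_value=20),
        st.integers(min_value=0, max_value=20),
        st.floats(min_value=0.01, max_value=0.3),
    )
    def test_hpdi_contains_map_for_any_count(self, n, k, alpha):
        k = min(k, n)
        res = prevalence_estimate(k, n, alpha=alpha)
        assert 0.0 <= res.hpdi[0] <= res.map <= res.hpdi[1] <= 1.0
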