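"""Circular statistics: descriptive vectors, tests, von Mises MLE, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special, stats

from antiphase.circstats import (KAPPA_CAP, bonferroni, bootstrap_vm,
                                 circ_summary, mww_test, phase_histogram,
                                 rao_homogeneity, rao_homogeneity_posthoc,
                                 rayleigh_test, sample_von_mises,
                                 time_histogram, vm_mle)

TWO_PI = 2 * np.pi


class TestCircSummary:
    def test_identical_angles(self):
        s = circ_summary([np.pi / 2] * 3)
        assert s.mean_direction == pytest.approx(np.pi / 2)
        assert s.resultant_length == pytest.approx(3.0)
        assert s.mean_resultant == pytest.approx(1.0)
        assert s.angular_dispersion == pytest.approx(0.0)

    def test_antipodal_mean_undefined(self):
        s = circ_summary([0.0, np.pi])
        assert s.resultant_length == pytest.approx(0.0, abs=1e-12)
        assert not s.mean_defined
        assert np.isnan(s.mean_direction)

    def test_vonmises_mean_recovery(self):
        a = sample_von_mises(3 * np.pi / 2, 4.0, 10_000, seed=1)
        # independent oracle: direct summation of unit vectors
        mean = np.mod(np.arctan2(np.sin(a).sum(), np.cos(a).sum()), TWO_PI)
        s = circ_summary(a)
        assert s.mean_direction == pytest.approx(mean)
        assert abs(s.mean_direction - 3 * np.pi / 2) < 0.05

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            circ_summary([])


class TestRayleigh:
    def test_maximal_concentration(self):
        r = rayleigh_test([1.0] * 50)
        assert r.p_value < 1e-10

    def test_equally_spaced_angles_uniform(self):
        a = np.linspace(0, TWO_PI, 360, endpoint=False)
        r = rayleigh_test(a)
        assert r.extra["r_bar"] == pytest.approx(0.0, abs=1e-10)
        assert r.p_value > 0.99

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(0)
        n, nsim = 100, 2000
        rej = sum(
            rayleigh_test(rng.uniform(0, TWO_PI, n)).p_value < 0.05
            for _ in range(nsim)
        )
        assert abs(rej / nsim - 0.05) < 0.015


class TestVonMisesMLE:
    def test_uniformish_sample_kappa_near_zero(self):
        a = np.linspace(0, TWO_PI, 1000, endpoint=False)
        assert vm_mle(a).kappa == pytest.approx(0.0, abs=1e-6)

    def test_kappa_recovery_matches_grid_search_oracle(self):
        a = sample_von_mises(1.0, 2.0, 10_000, seed=42)
        fit = vm_mle(a)
        assert 1.9 <= fit.kappa <= 2.1
        # oracle: profile likelihood over a kappa grid at mu = circular mean
        mu = circ_summary(a).mean_direction
        grid = np.linspace(0.5, 4.0, 1401)
        ll = [
            k * np.cos(a - mu).sum()
            - len(a) * (np.log(TWO_PI) + np.log(special.i0e(k)) + k)
            for k in grid
        ]
        k_grid = grid[int(np.argmax(ll))]
        assert fit.kappa == pytest.approx(k_grid, abs=0.005)
        assert fit.log_likelihood >= max(ll) - 1e-6

    def test_degenerate_sample_hits_cap(self):
        fit = vm_mle([2.0] * 20)
        assert fit.kappa == KAPPA_CAP
        assert fit.kappa_capped

    def test_consistency_A_of_kappa_equals_rbar(self):
        for seed, kappa in [(1, 0.5), (2, 2.0), (3, 8.0)]:
            a = sample_von_mises(0.7, kappa, 500, seed=seed)
            fit = vm_mle(a)
            rbar = circ_summary(a).mean_resultant
            A = special.i1e(fit.kappa) / special.i0e(fit.kappa)
            assert abs(A - rbar) < 1e-8


class TestBootstrap:
    def test_default_is_1000_resamples(self):
        import inspect

        assert inspect.signature(bootstrap_vm).parameters["n_boot"].default == 1000

    def test_degenerate_sample_gives_identical_replicates(self):
        b = bootstrap_vm([1.3] * 20, n_boot=50, seed=0)
        assert np.allclose(b.mu, 1.3)

    def test_mu_ci_coverage(self):
        true_mu = 5.5  # near the 0/2*pi seam to exercise the recentering
        hits = 0
        n_data = 500
        for s in range(200):
            a = sample_von_mises(true_mu, 2.0, n_data, seed=s)
            b = bootstrap_vm(a, n_boot=500, seed=1000 + s)
            lo, hi = b.mu_ci
            d_lo = np.mod(true_mu - lo, TWO_PI)
            d_hi = np.mod(hi - true_mu, TWO_PI)
            # inside the (possibly wrapped) arc from lo to hi
            arc = np.mod(hi - lo, TWO_PI)
            if d_lo <= arc and d_hi <= arc:
                hits += 1
        assert hits / 200 >= 0.93


class TestMWW:
    def test_identical_distributions_type_one(self):
        rng = np.random.default_rng(1)
        rej = 0
        nsim = 1000
        for _ in range(nsim):
            x = np.mod(rng.vonmises(0, 2, 50), TWO_PI)
            y = np.mod(rng.vonmises(0, 2, 50), TWO_PI)
            rej += mww_test(x, y).p_value < 0.05
        assert abs(rej / nsim - 0.05) < 0.02

    def test_opposite_means_detected(self):
        x = sample_von_mises(0.0, 2.0, 500, seed=1)
        y = sample_von_mises(np.pi, 2.0, 500, seed=2)
        assert mww_test(x, y).p_value < 0.001

    def test_chi2_p_matches_permutation_oracle(self):
        x = sample_von_mises(0.0, 1.0, 15, seed=3)
        y = sample_von_mises(0.8, 1.0, 15, seed=4)
        res = mww_test(x, y)  # n = 15 >= 10: chi-square path
        assert res.extra["method"] == "chi2"
        # oracle: permutation null of the same statistic
        perm = mww_test(x[:9], y[:9], n_perm=4999, seed=0)
        assert perm.extra["method"] == "permutation"
        rng = np.random.default_rng(5)
        pooled = np.concatenate([x, y])
        stat_obs = res.statistic
        count = 0
        n_perm = 4000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            count += mww_test(pooled[:15], pooled[15:]).statistic >= stat_obs - 1e-12
        p_perm = (count + 1) / (n_perm + 1)
        assert abs(res.p_value - p_perm) < 0.03

    def test_needs_two_groups(self):
        with pytest.raises(ValueError):
            mww_test(np.ones(20))


class TestRaoHomogeneity:
    def test_identical_groups_not_significant_on_average(self):
        rng = np.random.default_rng(2)
        ps_m, ps_d = [], []
        for _ in range(300):
            x = np.mod(rng.vonmises(1.0, 3.0, 80), TWO_PI)
            y = np.mod(rng.vonmises(1.0, 3.0, 80), TWO_PI)
            m, d = rao_homogeneity(x, y)
            ps_m.append(m.p_value)
            ps_d.append(d.p_value)
        assert 0.35 < np.mean(ps_m) < 0.65  # uniform p-values under the null
        assert 0.35 < np.mean(ps_d) < 0.65

    def test_dispersion_difference_detected_means_not(self):
        x = sample_von_mises(1.0, 2.0, 1000, seed=5)
        y = sample_von_mises(1.0, 8.0, 1000, seed=6)
        means, disp = rao_homogeneity(x, y)
        assert disp.p_value < 0.001
        assert means.p_value > 0.05

    def test_posthoc_pair_count(self):
        rng = np.random.default_rng(3)
        groups = {
            c: np.mod(rng.vonmises(0.5, 2, 50), TWO_PI) for c in "abcd"
        }
        df = rao_homogeneity_posthoc(groups)
        assert len(df) == 6  # C(4, 2)
        assert np.all(df["means_p_adj"] >= df["means_p"] - 1e-15)
        assert np.all(df["means_p_adj"] <= np.minimum(1.0, 6 * df["means_p"]) + 1e-15)


class TestBonferroni:
    def test_scaling_and_cap(self):
        assert bonferroni(0.01, 3) == pytest.approx(0.03)
        assert bonferroni(0.5, 3) == 1.0

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=10))
    def test_order_preserved(self, ps):
        adj = bonferroni(np.asarray(ps), len(ps))
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestHistograms:
    def test_uniform_sample_flat_and_conserved(self):
        a = np.linspace(0, TWO_PI, 3000, endpoint=False)
        edges, dens = phase_histogram(a, 30)
        assert len(dens) == 30
        assert dens.sum() == pytest.approx(1.0)
        assert np.allclose(dens, 1 / 30, atol=1e-3)  # edge-value binning jitter

    def test_default_circular_bins_is_30(self):
        import inspect

        from antiphase.circstats import phase_histogram as ph

        assert inspect.signature(ph).parameters["n_bins"].default == 30

    def test_time_histogram_1ms_bins(self):
        a = np.array([0.0, np.pi])
        edges, dens = time_histogram(a, rate_hz=8.0, bin_ms=1.0)
        assert len(edges) == 126  # 125 ms cycle -> 125 one-ms bins
        assert dens.sum() == pytest.approx(1.0)


@settings(max_examples=25)
@given(
    theta=st.floats(min_value=0, max_value=TWO_PI - 1e-9),
    seed=st.integers(min_value=0, max_value=100),
)
def test_rotation_equivariance(theta, seed):
    """Rotating every angle shifts the mean and leaves everything else fixed."""
    a = sample_von_mises(1.0, 2.0, 120, seed=seed)
    b = np.mod(a + theta, TWO_PI)
    sa, sb = circ_summary(a), circ_summary(b)
    assert np.mod(sb.mean_direction - sa.mean_direction - theta + np.pi,
                  TWO_PI) - np.pi == pytest.approx(0.0, abs=1e-9)
    assert sb.resultant_length == pytest.approx(sa.resultant_length)
    assert vm_mle(b).kappa == pytest.approx(vm_mle(a).kappa, abs=1e-9)
    assert rayleigh_test(b).statistic == pytest.approx(rayleigh_test(a).statistic)
    c = sample_von_mises(2.0, 2.0, 120, seed=seed + 500)
    d = np.mod(c + theta, TWO_PI)
    assert mww_test(b, d).statistic == pytest.approx(mww_test(a, c).statistic)
    ma, da = rao_homogeneity(a, c)
    mb, db = rao_homogeneity(b, d)
    assert mb.statistic == pytest.approx(ma.statistic, rel=1e-8)
    assert db.statistic == pytest.approx(da.statistic, rel=1e-8)
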