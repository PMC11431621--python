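import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tsmi.mi import (MICurve, SamplePairs, ksg_mi, mi_curve_ensemble,
                     mi_curve_ensemble_groups, mi_curve_single,
                     mirror_combine, nats_to_bits, read_curve_csv,
                     write_curve_csv)
from tsmi.peaks import loess
from tsmi.simulate import LFConfig, simulate_independent_pair, simulate_lf_dyad


def gaussian_pairs(rho, n, seed):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    return z[:, 0], z[:, 1]


def plugin_mi(x, y, B=32):
    """Independent oracle: equal-frequency histogram plug-in MI with
    Miller-Madow bias correction."""
    n = len(x)
    qx = np.quantile(x, np.linspace(0, 1, B + 1))
    qy = np.quantile(y, np.linspace(0, 1, B + 1))
    qx[0] -= 1; qx[-1] += 1
    qy[0] -= 1; qy[-1] += 1
    ix = np.clip(np.searchsorted(qx, x, "right") - 1, 0, B - 1)
    iy = np.clip(np.searchsorted(qy, y, "right") - 1, 0, B - 1)
    joint = np.zeros((B, B))
    np.add.at(joint, (ix, iy), 1)
    pj = joint / n
    px, py = pj.sum(1), pj.sum(0)
    nz = pj > 0
    mi = np.sum(pj[nz] * np.log(pj[nz] / (px[:, None] * py[None, :])[nz]))
    return mi - (nz.sum() - 2 * B + 1) / (2 * n)


class TestKSG:
    def test_independent_samples_give_zero(self):
        vals = []
        for s in range(8):
            rng = np.random.default_rng(s)
            vals.append(ksg_mi(SamplePairs(rng.uniform(size=1000),
                                           rng.uniform(size=1000))))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_gaussian_closed_form(self, rho):
        x, y = gaussian_pairs(rho, 5000, seed=11)
        est = ksg_mi(SamplePairs(x, y))
        assert abs(est - (-0.5 * np.log(1 - rho ** 2))) < 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.5, 0.9])
    def test_against_histogram_plugin_oracle(self, rho):
        x, y = gaussian_pairs(rho, 5000, seed=23)
        assert abs(ksg_mi(SamplePairs(x, y)) - plugin_mi(x, y)) < 0.05

    def test_against_sklearn_implementation(self):
        """Cross-check against an independent KSG implementation."""
        from sklearn.feature_selection import mutual_info_regression
        x, y = gaussian_pairs(0.7, 2000, seed=5)
        ours = ksg_mi(SamplePairs(x, y), k=4)
        theirs = mutual_info_regression(x[:, None], y, n_neighbors=4,
                                        random_state=0)[0]
        assert abs(ours - theirs) < 0.02

    def test_permutation_null(self):
        x, y = gaussian_pairs(0.9, 2000, seed=3)
        vals = []
        for s in range(8):
            perm = np.random.default_rng(s).permutation(len(y))
            vals.append(ksg_mi(SamplePairs(x, y[perm])))
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals)) < 3 * se + 1e-3

    def test_monotone_marginal_transform_near_invariance(self):
        x, y = gaussian_pairs(0.5, 2000, seed=7)
        a = ksg_mi(SamplePairs(x, y))
        b = ksg_mi(SamplePairs(np.exp(x), y))
        assert abs(a - b) < 0.05

    def test_negative_estimates_not_clipped(self):
        # weak-sample independent data fluctuates below zero for some seeds
        vals = [ksg_mi(SamplePairs(*gaussian_pairs(0.0, 60, seed=s)))
                for s in range(40)]
        assert min(vals) < 0

    def test_input_validation(self):
        with pytest.raises(ValueError):
            ksg_mi(SamplePairs(np.arange(5.0), np.arange(5.0)), k=5)
        with pytest.raises(ValueError):
            SamplePairs(np.array([1.0, np.nan]), np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            SamplePairs(np.arange(3.0), np.arange(4.0))

    def test_exact_ties_handled(self):
        """Duplicate values (wrapped angles hit the same float) are fine."""
        rng = np.random.default_rng(0)
        x = np.repeat(rng.uniform(size=200), 5)
        y = x + rng.normal(0, 0.1, size=1000)
        est = ksg_mi(SamplePairs(x, y))
        assert np.isfinite(est) and est > 0.5

    def test_chord_embedding_accepts_2d(self):
        rng = np.random.default_rng(1)
        th = rng.uniform(0, 2 * np.pi, 800)
        x = np.column_stack([np.cos(th), np.sin(th)])
        noisy = th + rng.normal(0, 0.3, 800)
        y = np.column_stack([np.cos(noisy), np.sin(noisy)])
        assert ksg_mi(SamplePairs(x, y)) > 0.5

    def test_nats_to_bits(self):
        assert nats_to_bits(np.log(2)) == pytest.approx(1.0)


@pytest.fixture(scope="module")
def small_dyad_ensemble():
    return [simulate_lf_dyad(LFConfig(seed=3000 + i, n_steps=4100))
            for i in range(300)]


class TestMICurveEnsemble:
    def test_peak_at_reaction_delay(self, small_dyad_ensemble):
        grid = np.linspace(-1.5, 1.5, 31)
        curve = mi_curve_ensemble(small_dyad_ensemble, grid, t_star=4000,
                                  seed=1)
        assert curve.tau[int(np.argmax(curve.mi_mean))] == pytest.approx(0.5)

    def test_flat_for_noninteracting_pair(self, small_dyad_ensemble):
        """The independent-pair curve is flat relative to the dyad's peak."""
        grid = np.linspace(-1.5, 1.5, 31)
        reps = [simulate_independent_pair(
            LFConfig(seed=4000 + i, sigma=0.00039, phi=0.1, n_steps=4100))
            for i in range(300)]
        flat = mi_curve_ensemble(reps, grid, t_star=4000, seed=1)
        peaked = mi_curve_ensemble(small_dyad_ensemble, grid, t_star=4000,
                                   seed=1)
        # compare smoothed structure, not per-point estimator noise
        flat_sm = loess(grid, flat.mi_mean, f=0.3, degree=2)
        peaked_sm = loess(grid, peaked.mi_mean, f=0.3, degree=2)
        flat_range = flat_sm.max() - flat_sm.min()
        peaked_range = peaked_sm.max() - peaked_sm.min()
        assert flat_range < 0.25 * peaked_range

    def test_insufficient_replicates_rejected(self, small_dyad_ensemble):
        with pytest.raises(ValueError, match="subset_size"):
            mi_curve_ensemble(small_dyad_ensemble[:100], [0.0, 0.5],
                              t_star=4000)

    def test_tau_outside_replicates_rejected(self, small_dyad_ensemble):
        with pytest.raises(ValueError):
            mi_curve_ensemble(small_dyad_ensemble, [-5000.0, 0.0], t_star=4000)

    def test_smoothed_curve_decays_away_from_peak(self):
        """Data-processing argument: each extra leader step only adds
        unshared information, so MI falls monotonically in |tau - T| once
        the noise is large enough to kill periodic correlations."""
        groups = [[simulate_lf_dyad(LFConfig(sigma=0.1, seed=7000 + g * 250 + i,
                                             n_steps=760))
                   for i in range(250)] for g in range(10)]
        grid = np.linspace(-1.5, 1.5, 31)
        curve = mi_curve_ensemble_groups(groups, grid, t_star=700)
        sm = loess(curve.tau, curve.mi_mean, f=0.3, degree=2)
        i_peak = int(np.argmax(sm))
        assert abs(curve.tau[i_peak] - 0.5) <= 0.2
        tol = curve.mi_se
        right = sm[i_peak:]
        assert np.all(np.diff(right) <= tol[i_peak + 1:])
        left = sm[:i_peak + 1][::-1]
        assert np.all(np.diff(left) <= tol[:i_peak][::-1])


class TestMICurveSingle:
    def test_matches_ensemble_shape_on_dyad(self, small_dyad_ensemble):
        grid = np.linspace(-1.5, 1.5, 31)
        ens = mi_curve_ensemble(small_dyad_ensemble, grid, t_star=4000, seed=1)
        tr = simulate_lf_dyad(LFConfig(seed=99, n_steps=25000))
        single = mi_curve_single(tr.theta0, tr.theta1, grid, W=100,
                                 dt=tr.dt, seed=2)
        assert grid[int(np.argmax(single.mi_mean))] == pytest.approx(
            grid[int(np.argmax(ens.mi_mean))])

    def test_too_few_pairs_flagged_not_silent(self):
        rng = np.random.default_rng(0)
        th = rng.uniform(0, 2 * np.pi, 400)
        with pytest.warns(UserWarning, match="valid pairs"):
            curve = mi_curve_single(th, th, [9.9], W=395, n_resamples=3,
                                    dt=1.0, seed=0)
        assert np.isnan(curve.mi_mean[0])

    def test_masked_frames_dropped(self):
        tr = simulate_lf_dyad(LFConfig(seed=17, n_steps=6000))
        valid = np.ones(len(tr.theta0), bool)
        valid[::7] = False
        grid = np.array([0.0, 0.5])
        curve = mi_curve_single(tr.theta0, tr.theta1, grid, W=50, dt=tr.dt,
                                seed=3, valid0=valid, valid1=valid)
        full = mi_curve_single(tr.theta0, tr.theta1, grid, W=50, dt=tr.dt,
                               seed=3)
        assert np.all(curve.n_samples < full.n_samples)
        assert np.all(np.isfinite(curve.mi_mean))


class TestMirrorCombine:
    def _curve(self, tau, mi):
        n = len(tau)
        return MICurve(tau=np.asarray(tau, float), mi_mean=np.asarray(mi, float),
                       mi_se=np.full(n, 0.1), n_samples=np.full(n, 250))

    def test_combined_grid_and_placement(self):
        pos = self._curve([0.0, 0.5, 1.0], [1.0, 3.0, 1.5])
        swapped = self._curve([0.0, 0.5, 1.0], [2.0, 0.5, 0.25])
        comb = mirror_combine(pos, swapped)
        assert np.allclose(comb.tau, [-1.0, -0.5, 0.0, 0.5, 1.0])
        assert np.allclose(comb.mi_mean, [0.25, 0.5, 1.5, 3.0, 1.5])

    def test_symmetric_input_gives_symmetric_curve(self):
        pos = self._curve([0.0, 0.5, 1.0], [1.0, 3.0, 1.5])
        comb = mirror_combine(pos, pos)
        assert np.allclose(comb.mi_mean, comb.mi_mean[::-1])

    def test_one_sided_leadership_peaks_on_leader_branch(self):
        """alpha=0 with agent 0 leading: peak only where 0 is presumed
        leader (tau > 0)."""
        reps = [simulate_lf_dyad(LFConfig(seed=5000 + i, n_steps=4100))
                for i in range(300)]
        grid = np.linspace(0.0, 1.5, 16)
        fwd = mi_curve_ensemble(reps, grid, t_star=4000, seed=1)
        swapped = mi_curve_ensemble([(r.theta0, r.theta1) for r in reps],
                                    grid, t_star=4000, seed=1)
        comb = mirror_combine(fwd, swapped)
        assert comb.tau[int(np.argmax(comb.mi_mean))] == pytest.approx(0.5)

    def test_degenerate_single_point(self):
        a = self._curve([0.0], [1.0])
        b = self._curve([0.0], [2.0])
        comb = mirror_combine(a, b)
        assert len(comb) == 1 and comb.mi_mean[0] == pytest.approx(1.5)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            mirror_combine(self._curve([0.0, 0.5], [1, 1]),
                           self._curve([0.0, 0.6], [1, 1]))


class TestCurveIO:
    def test_roundtrip(self, tmp_path):
        curve = MICurve(tau=np.linspace(-1, 1, 5), mi_mean=np.arange(5.0),
                        mi_se=np.full(5, 0.1), n_samples=np.full(5, 250),
                        convention="agent 1 presumed leader on tau>0")
        path = tmp_path / "curve.csv"
        write_curve_csv(curve, path)
        back = read_curve_csv(path)
        assert np.allclose(back.tau, curve.tau)
        assert np.allclose(back.mi_mean, curve.mi_mean)
        assert back.convention == curve.convention


@given(st.integers(0, 10 ** 6))
def test_ksg_deterministic_given_data(seed):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=50)
    y = rng.normal(size=50)
    assert ksg_mi(SamplePairs(x, y)) == ksg_mi(SamplePairs(x, y))
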