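import numpy as np
import pytest
from scipy import linalg

from mipool import (
    Epochs,
    class_covariance,
    csp_features,
    fit_csp,
    fit_fbcsp,
    mibifs_select,
    mutual_information,
    pattern_table,
    select_filters,
)
from mipool.spatial_filters import _complement_index

from conftest import make_epochs


def gaussian_class_epochs(rng, cov1, cov2, n_per_class=40, T=500):
    """Trials drawn from zero-mean Gaussians with the given channel covariances."""
    C = cov1.shape[0]
    L1, L2 = np.linalg.cholesky(cov1), np.linalg.cholesky(cov2)
    trials = []
    for L in (L1, L2):
        x = rng.standard_normal((n_per_class, T, C)) @ L.T
        trials.append(np.transpose(x, (1, 2, 0)))
    data = np.concatenate(trials, axis=2)
    labels = np.repeat([1, 2], n_per_class)
    return Epochs(data, labels, 100.0, [f"ch{i}" for i in range(C)], 0.0)


class TestClassCovariance:
    def test_white_noise_recovers_identity(self, rng):
        """Law of large numbers: covariance of sigma^2-white trials tends to
        sigma^2 I as concatenated length grows (10^5 samples here)."""
        sigma = 1.5
        e = make_epochs(rng, T=1000, C=4, n_per_class=50)
        e.data *= sigma
        cov = class_covariance(e, 1)
        np.testing.assert_allclose(cov, sigma**2 * np.eye(4), atol=0.05)

    def test_constant_channel_gives_zero_row(self):
        rng = np.random.default_rng(1)
        e = make_epochs(rng, T=64, C=3, n_per_class=1)
        e.data[:, 1, :] = 7.0  # constant channel; removed by per-trial centering
        cov = class_covariance(e, 1)
        np.testing.assert_allclose(cov[1, :], 0.0, atol=1e-12)
        np.testing.assert_allclose(cov[:, 1], 0.0, atol=1e-12)

    def test_duplicating_trials_is_invariant(self, small_epochs):
        e = small_epochs
        doubled = Epochs(
            np.concatenate([e.data, e.data], axis=2),
            np.concatenate([e.labels, e.labels]),
            e.fs,
            e.channels,
        )
        np.testing.assert_allclose(
            class_covariance(e, 1), class_covariance(doubled, 1), rtol=1e-12
        )

    def test_missing_label_rejected(self, small_epochs):
        with pytest.raises(ValueError, match="label 3"):
            class_covariance(small_epochs, 3)


class TestFitCSP:
    def test_known_2x2_solution(self, rng):
        """Classes with covariances diag(2,1) and diag(1,2): the closed-form
        generalized eigensolution has d = (2/3, 1/3) and axis-aligned filters."""
        e = gaussian_class_epochs(
            rng, np.diag([2.0, 1.0]), np.diag([1.0, 2.0]), n_per_class=100, T=2000
        )
        model = fit_csp(e)
        np.testing.assert_allclose(model.d, [2 / 3, 1 / 3], atol=0.02)
        # filters align with coordinate axes up to sign
        for col in model.W.T:
            direction = np.abs(col) / np.linalg.norm(col)
            assert direction.max() > 0.99

    def test_identical_classes_give_half(self, rng):
        base = make_epochs(rng, T=128, C=3, n_per_class=6)
        data = np.concatenate([base.data[:, :, :6]] * 2, axis=2)
        e = Epochs(data, np.repeat([1, 2], 6), base.fs, base.channels)
        model = fit_csp(e)
        np.testing.assert_allclose(model.d, 0.5, atol=1e-12)

    def test_diagonalization_constraints(self, rng):
        e = make_epochs(rng, T=256, C=6, n_per_class=20, scale=(1, 2, 3, 1, 2, 3))
        model = fit_csp(e)
        s1, s2 = class_covariance(e, 1), class_covariance(e, 2)
        W = model.W
        np.testing.assert_allclose(W.T @ (s1 + s2) @ W, np.eye(6), atol=1e-8)
        np.testing.assert_allclose(W.T @ s1 @ W, np.diag(model.d), atol=1e-8)
        assert np.all(np.diff(model.d) <= 1e-12)

    def test_matches_generalized_eig_oracle(self, rng):
        """Direct scipy.linalg.eig on the (S1+S2)^-1 S1 pencil spans the same
        filters, up to sign, as the symmetric solver used internally."""
        e = make_epochs(rng, T=200, C=5, n_per_class=15, scale=(1, 3, 2, 1, 2))
        model = fit_csp(e)
        s1, s2 = class_covariance(e, 1), class_covariance(e, 2)
        evals, evecs = linalg.eig(np.linalg.solve(s1 + s2, s1))
        order = np.argsort(-evals.real)
        for k, idx in enumerate(order):
            v = evecs[:, idx].real
            w = model.W[:, k]
            cos = abs(v @ w) / (np.linalg.norm(v) * np.linalg.norm(w))
            assert cos > 1 - 1e-8

    def test_label_swap_reverses_spectrum(self, rng):
        e = make_epochs(rng, T=256, C=4, n_per_class=10, scale=(1, 2, 1, 2))
        m12 = fit_csp(e)
        swapped = Epochs(e.data, np.where(e.labels == 1, 2, 1), e.fs, e.channels)
        m21 = fit_csp(swapped)
        np.testing.assert_allclose(m21.d, (1 - m12.d)[::-1], atol=1e-10)
        np.testing.assert_allclose(np.abs(m21.W), np.abs(m12.W[:, ::-1]), atol=1e-8)

    def test_rank_deficient_raises_and_ridge_recovers(self, rng):
        e = make_epochs(rng, T=64, C=4, n_per_class=4)
        e.data[:, 3, :] = e.data[:, 0, :]  # duplicated channel
        with pytest.raises(np.linalg.LinAlgError, match="ridge"):
            fit_csp(e)
        model = fit_csp(e, ridge=1e-9)
        assert model.W.shape == (4, 4)


class TestSelectFilters:
    @pytest.mark.parametrize("m,expected", [(2, 4), (3, 6)])
    def test_filter_counts(self, rng, m, expected):
        e = make_epochs(rng, T=128, C=8, n_per_class=10)
        fset = select_filters(fit_csp(e), m)
        assert fset.filters.shape == (8, expected)

    def test_m_half_returns_all_columns(self, rng):
        e = make_epochs(rng, T=128, C=6, n_per_class=10)
        model = fit_csp(e)
        fset = select_filters(model, 3)
        np.testing.assert_array_equal(fset.filters, model.W)

    def test_too_many_pairs_rejected(self, rng):
        e = make_epochs(rng, T=128, C=4, n_per_class=10)
        with pytest.raises(ValueError):
            select_filters(fit_csp(e), 3)


class TestCSPFeatures:
    def test_normalization_sums_to_one(self, rng):
        e = make_epochs(rng, T=128, C=4, n_per_class=6)
        fset = select_filters(fit_csp(e), 2)
        feats = csp_features(fset, e)
        np.testing.assert_allclose(np.exp(feats).sum(axis=1), 1.0, rtol=1e-12)

    def test_trial_scale_invariance(self, rng):
        e = make_epochs(rng, T=128, C=4, n_per_class=6)
        fset = select_filters(fit_csp(e), 2)
        f0 = csp_features(fset, e)
        e.data[:, :, 0] *= 10.0
        f1 = csp_features(fset, e)
        np.testing.assert_allclose(f0[0], f1[0], rtol=1e-10)

    def test_rank_one_trial_concentrates_power(self, rng):
        e = make_epochs(rng, T=256, C=4, n_per_class=6, scale=(4, 1, 1, 1))
        model = fit_csp(e)
        fset = select_filters(model, 2)
        # trial living entirely along the first filter's source direction
        src = np.linalg.inv(model.W)[0]  # pattern of filter 1
        trial = np.outer(rng.standard_normal(256), src)
        e2 = Epochs(
            np.stack([trial, trial], axis=2), np.array([1, 2]), e.fs, e.channels
        )
        feats = csp_features(fset, e2)
        assert feats[0].argmax() == 0
        assert abs(np.exp(feats[0, 0]) - 1.0) < 1e-8

    def test_zero_variance_trial_identified(self, rng):
        e = make_epochs(rng, T=128, C=4, n_per_class=2)
        e.data[:, :, 2] = 0.0
        fset = select_filters(fit_csp(e), 2)
        with pytest.raises(ValueError, match=r"\[2\]"):
            csp_features(fset, e)


class TestMutualInformation:
    def test_perfect_predictor_is_one_bit(self):
        labels = np.repeat([1, 2], 50)
        f = labels.astype(float)
        assert mutual_information(f, labels) == pytest.approx(1.0, abs=1e-9)

    def test_independent_feature_near_zero(self, rng):
        labels = np.repeat([1, 2], 500)
        f = rng.standard_normal(1000)
        assert mutual_information(f, labels) < 0.02

    def test_constant_feature_zero(self):
        labels = np.repeat([1, 2], 10)
        assert mutual_information(np.ones(20), labels) == 0.0

    def test_discrete_joint_matches_hand_computation(self):
        """Feature takes 4 distinct values with known joint counts; the plug-in
        estimate must equal the direct sum p log2(p / (p_f p_c))."""
        # joint counts over (feature value, class): rows f0..f3
        counts = np.array([[8, 2], [6, 4], [3, 7], [1, 9]], dtype=float)
        f, labels = [], []
        for i, row in enumerate(counts):
            for c, k in zip((1, 2), row):
                f += [float(i)] * int(k)
                labels += [c] * int(k)
        f, labels = np.array(f), np.array(labels)
        p = counts / counts.sum()
        pf = p.sum(axis=1, keepdims=True)
        pc = p.sum(axis=0, keepdims=True)
        expected = np.sum(p * np.log2(p / (pf * pc)))
        got = mutual_information(f, labels, bins=4)
        assert got == pytest.approx(expected, abs=1e-12)


class TestMIBIFS:
    def test_informative_feature_brings_complement(self, rng):
        labels = np.repeat([1, 2], 30)
        feats = rng.standard_normal((60, 8))
        feats[:, 5] = labels  # only informative column
        sel = mibifs_select(feats, labels, k_pairs=1)
        assert set(sel) == {5, _complement_index(5)} == {5, 6}

    def test_all_pairs_selects_everything(self, rng):
        labels = np.repeat([1, 2], 20)
        feats = rng.standard_normal((40, 12))
        sel = mibifs_select(feats, labels, k_pairs=6)
        assert list(sel) == list(range(12))

    def test_matches_bruteforce_ranking_oracle(self, rng):
        """Walk-the-ranking-with-closure re-implemented independently."""
        labels = np.repeat([1, 2], 25)
        for _ in range(20):
            feats = rng.standard_normal((50, 12))
            feats[:, rng.integers(12)] += labels * rng.uniform(0.5, 2.0)
            k = int(rng.integers(1, 7))
            mi = [mutual_information(feats[:, j], labels) for j in range(12)]
            expected: set[int] = set()
            pairs = 0
            for j in sorted(range(12), key=lambda j: (-mi[j], j)):
                if j in expected:
                    continue
                band, pos = divmod(j, 4)
                expected |= {j, band * 4 + 3 - pos}
                pairs += 1
                if pairs == k:
                    break
            assert set(mibifs_select(feats, labels, k)) == expected

    def test_bad_width_or_k_rejected(self, rng):
        labels = np.repeat([1, 2], 10)
        with pytest.raises(ValueError):
            mibifs_select(rng.standard_normal((20, 10)), labels, 1)
        with pytest.raises(ValueError):
            mibifs_select(rng.standard_normal((20, 8)), labels, 5)


class TestFBCSP:
    def test_full_bank_feature_budget(self, rng):
        """15 bands x 2 pairs = 60 candidate features; k_pairs=30 keeps all."""
        e = make_epochs(rng, T=256, C=4, n_per_class=12, fs=128.0,
                        scale=(1, 2, 2, 1))
        model = fit_fbcsp(e, k_pairs=30)
        assert len(model.bands) == 15
        assert all(f.filters.shape == (4, 4) for f in model.per_band_filters)
        assert model.transform(e).shape == (24, 60)

    def test_narrowband_signal_selects_overlapping_bands(self, rng):
        """Class difference planted only at 10 Hz: every selected feature pair
        must come from a band containing 10 Hz."""
        fs, T, n = 128.0, 384, 20
        t = np.arange(T) / fs
        labels = np.repeat([1, 2], n)
        data = 0.5 * rng.standard_normal((T, 4, 2 * n))
        for i, lab in enumerate(labels):
            amp = 2.0 if lab == 1 else 0.5
            data[:, 0, i] += amp * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
            data[:, 1, i] += 0.3 * np.sin(2 * np.pi * 10 * t + rng.uniform(0, 2 * np.pi))
        e = Epochs(data, labels, fs, ["a", "b", "c", "d"], 0.0)
        model = fit_fbcsp(e, k_pairs=3)
        bands_hit = {int(j) // 4 for j in model.selected}
        for b in bands_hit:
            lo, hi = model.bands[b].low, model.bands[b].high
            assert lo <= 10 <= hi, f"selected band {lo}-{hi} Hz misses 10 Hz"


def test_pattern_table_zero_pads_missing_channels(rng):
    e = make_epochs(rng, T=128, C=4, n_per_class=8)
    model = fit_csp(e)
    tab = pattern_table(model, montage=e.channels + ["extra"])
    assert tab.shape == (5, 4)
    assert (tab.loc["extra"] == 0).all()
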