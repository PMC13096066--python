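"""NDTE estimator: entropies, model order, pairwise and matrix flows."""

import numpy as np
import pytest

from ndteflow import (
    DegenerateInputError,
    EpochSet,
    ValidationError,
    estimate_model_order,
    gaussian_entropy,
    generate_var_epochs,
    ndte_matrix,
    ndte_pair,
    simulate_trial_sequence,
)

from conftest import coupled_spec

LN_2PIE_HALF = 0.5 * np.log(2 * np.pi * np.e)  # 1.4189...


def simulate_var1(a, b, n, seed, x_drive=None):
    """y_t = a*x_{t-1} + b*y_{t-1} + e; x white noise unless x_drive given."""
    rng = np.random.default_rng(seed)
    x = x_drive if x_drive is not None else rng.normal(size=n + 1)
    y = np.zeros(n + 1)
    for t in range(1, n + 1):
        y[t] = a * x[t - 1] + b * y[t - 1] + rng.normal()
    return x[1:], y[1:]


class TestGaussianEntropy:
    @pytest.mark.parametrize(
        "cov, expected",
        [
            ([[1.0]], LN_2PIE_HALF),
            ([[1.0, 0.0], [0.0, 1.0]], 2 * LN_2PIE_HALF),
            ([[1.0, 0.6], [0.6, 1.0]], 2 * LN_2PIE_HALF + 0.5 * np.log(0.64)),
        ],
    )
    def test_hand_values(self, cov, expected):
        assert gaussian_entropy(cov) == pytest.approx(expected, abs=1e-6)

    def test_non_square_rejected(self):
        with pytest.raises(ValidationError):
            gaussian_entropy(np.ones((2, 3)))


class TestModelOrder:
    @staticmethod
    def _single(trace, fs=1000.0, max_lag=60):
        es = EpochSet(np.asarray(trace)[None, None, :], fs, 0.0, ["a"])
        return estimate_model_order(es, max_lag)

    def test_cosine_first_minimum_at_half_period(self):
        t = np.arange(4000)
        assert self._single(np.cos(2 * np.pi * t / 100)).lag_samples == 50

    def test_damped_oscillation(self):
        t = np.arange(2000)
        sig = np.exp(-t / 200) * np.cos(2 * np.pi * t / 60)
        assert self._single(sig, max_lag=80).lag_samples == pytest.approx(30, abs=1)

    def test_matches_bruteforce_scan_on_white_noise(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        got = self._single(x, max_lag=50).lag_samples
        # independent brute-force scan of the same sample ACF
        xc = x - x.mean()
        acf = np.array([xc[: 400 - k] @ xc[k:] for k in range(52)]) / (xc @ xc)
        brute = None
        descended = False
        for tau in range(1, 50):
            if acf[tau] <= acf[tau - 1]:
                descended = True
            if descended and acf[tau] < acf[tau + 1]:
                brute = tau
                break
        assert got == brute

    def test_constant_trace_degenerate(self):
        with pytest.raises(DegenerateInputError):
            self._single(np.ones(400))

    def test_averages_over_regions_and_trials(self, noise_epochs):
        mo = estimate_model_order(noise_epochs, 50)
        assert len(mo.per_unit_decays) == noise_epochs.n_trials * noise_epochs.n_regions
        assert mo.lag_samples == max(1, round(np.mean(mo.per_unit_decays)))
        assert mo.lag_ms == mo.lag_samples  # 1 kHz


class TestNdtePair:
    def test_var1_closed_form(self):
        """a=b=0.5, unit noises: F = ln(5/4)/ln(5/3) ~ 0.4368."""
        x, y = simulate_var1(0.5, 0.5, 20_000, seed=1)
        target = np.log(1.25) / np.log(5 / 3)
        assert ndte_pair(x, y, 1) == pytest.approx(target, abs=0.05)

    def test_pure_delay_saturates(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        y = np.roll(x, 1)
        assert ndte_pair(x, y, 1) > 0.95

    def test_bounds_and_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=(2, 400))
        f = ndte_pair(x, y, 3)
        assert 0.0 <= f <= 1.0
        f2 = ndte_pair(5.0 * x - 2.0, -0.3 * y + 7.0, 3)
        assert f2 == pytest.approx(f, abs=1e-4)

    def test_uncoupled_flow_below_coupled(self):
        x, y = simulate_var1(0.5, 0.5, 2000, seed=4)
        rng = np.random.default_rng(5)
        z = rng.normal(size=2000)
        assert ndte_pair(x, y, 1) > 10 * ndte_pair(z, y, 1)

    def test_equivalent_to_bruteforce_entropies(self):
        """Independent 4-entropy implementation agrees to 1e-10."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            T = int(rng.integers(1, 4))
            n = int(rng.integers(50, 120))
            x, y = rng.normal(size=(2, n))
            Z = np.vstack([
                y[T:],
                *[y[T - l: n - l][None, :] for l in range(1, T + 1)],
                *[x[T - l: n - l][None, :] for l in range(1, T + 1)],
            ])
            cov = np.cov(Z, bias=True)
            i_f, i_yp = [0], list(range(1, T + 1))
            i_xp = list(range(T + 1, 2 * T + 1))
            h = lambda idx: gaussian_entropy(cov[np.ix_(idx, idx)])
            num = h(i_f + i_yp) + h(i_yp + i_xp) - h(i_yp) - h(i_f + i_yp + i_xp)
            den = h(i_f) + h(i_yp + i_xp) - h(i_f + i_yp + i_xp)
            assert ndte_pair(x, y, T) == pytest.approx(num / den, abs=1e-10)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            ndte_pair(np.zeros(10), np.zeros(10), 4)


class TestGaussianMISanity:
    def test_bivariate_mi_closed_form(self):
        """I = -0.5 ln(1-rho^2) for rho=0.8 within 2% at n=50,000."""
        rng = np.random.default_rng(7)
        z = rng.multivariate_normal([0, 0], [[1, 0.8], [0.8, 1]], size=50_000)
        cov = np.cov(z.T, bias=True)
        mi = (gaussian_entropy(cov[:1, :1]) + gaussian_entropy(cov[1:, 1:])
              - gaussian_entropy(cov))
        assert mi == pytest.approx(-0.5 * np.log(1 - 0.64), rel=0.02)


class TestNdteMatrix:
    def test_orientation_contract(self, rng):
        data = rng.normal(size=(2, 300))
        M = ndte_matrix(data, 2).F
        assert M[1, 0] == pytest.approx(ndte_pair(data[0], data[1], 2), abs=1e-12)
        assert M[0, 1] == pytest.approx(ndte_pair(data[1], data[0], 2), abs=1e-12)
        assert M[0, 0] == M[1, 1] == 0.0

    def test_relabeling_equivariance(self, rng):
        data = rng.normal(size=(4, 300))
        perm = np.array([2, 0, 3, 1])
        M = ndte_matrix(data, 2).F
        Mp = ndte_matrix(data[perm], 2).F
        np.testing.assert_allclose(Mp, M[np.ix_(perm, perm)], atol=1e-10)

    def test_planted_chain_recovered(self):
        """Chain 0 -> 1 -> 2: planted directed pairs exceed unplanted ones."""
        base = np.zeros((5, 5, 1))
        for r in range(5):
            base[r, r, 0] = 0.4
        base[1, 0, 0] = 0.5
        base[2, 1, 0] = 0.5
        from ndteflow import GroundTruthSpec
        spec = GroundTruthSpec(5, 1000.0, 1, base, np.zeros_like(base),
                               (0, 1), seed=8)
        trials = simulate_trial_sequence(1, 1, 10, 0.8, 0.5, seed=8)
        es = generate_var_epochs(spec, trials, (0.0, 400.0))
        Ms = np.stack([ndte_matrix(es.data[t], 1).F for t in range(es.n_trials)])
        mean = Ms.mean(axis=0)
        planted = [mean[1, 0], mean[2, 1]]
        mask = ~np.eye(5, dtype=bool)
        mask[1, 0] = mask[2, 1] = False
        assert min(planted) > mean[mask].mean() * 3
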