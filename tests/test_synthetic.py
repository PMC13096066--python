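"""Synthetic generators: trial design, VAR ground truth, planted clubs, RTs."""

import numpy as np
import pandas as pd
import pytest

from ndteflow import (
    GroundTruthSpec,
    StationarityError,
    ValidationError,
    generate_phase_locked_epochs,
    generate_rt_table,
    generate_var_epochs,
    ndte_pair,
    plant_rich_club,
    simulate_trial_sequence,
)
from ndteflow.entrainment import morlet_itpc
from ndteflow.synthetic import NONPREDICTIVE, PREDICTIVE

from conftest import coupled_spec


class TestTrialSequence:
    def test_design_counts_match_study(self):
        """3 blocks x 50 trials per condition -> 300 trials, 150 per condition."""
        t = simulate_trial_sequence(1, 3, 50, 0.8, 0.5, seed=1)
        assert len(t) == 300
        assert (t["condition"].value_counts() == 150).all()

    def test_invariants(self):
        t = simulate_trial_sequence(3, 2, 10, 0.8, 0.5, seed=2)
        early = t["target_latency"] == "early"
        assert (t.loc[early, "cue_target_interval_ms"] == 1200).all()
        assert (t.loc[~early, "cue_target_interval_ms"] == 2400).all()
        assert t["iti_ms"].between(200, 1000).all()
        strata = t.groupby(["participant_id", "condition"]).size()
        assert (strata == 20).all()

    def test_degenerate_probability_forces_early(self):
        t = simulate_trial_sequence(1, 2, 25, 1.0, 0.5, seed=3)
        pred = t[t["condition"] == PREDICTIVE]
        assert (pred["target_latency"] == "early").all()

    def test_early_fraction_binomial(self):
        """Early fraction in the predictive stratum within 3 SE of 0.8."""
        t = simulate_trial_sequence(1, 40, 50, 0.8, 0.5, seed=7)
        pred = t[t["condition"] == PREDICTIVE]
        frac = (pred["target_latency"] == "early").mean()
        se = np.sqrt(0.8 * 0.2 / len(pred))
        assert abs(frac - 0.8) < 3 * se

    def test_determinism_and_validation(self):
        a = simulate_trial_sequence(2, 2, 5, 0.8, 0.5, seed=9)
        b = simulate_trial_sequence(2, 2, 5, 0.8, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValidationError):
            simulate_trial_sequence(1, 1, 1, 1.5, 0.5, seed=0)


class TestVarEpochs:
    def test_shape_contract(self):
        spec = coupled_spec(n_rois=5, seed=4)
        trials = simulate_trial_sequence(1, 1, 10, 0.8, 0.5, seed=4)
        es = generate_var_epochs(spec, trials, (0.0, 400.0))
        assert es.data.shape == (20, 5, 400)  # 2 conditions x 10 trials
        assert es.t0_ms == 0.0

    def test_lag1_cross_covariance_matches_coupling(self):
        """White-noise x driving y with weight 0.5 -> cov(y_t, x_{t-1}) -> 0.5."""
        base = np.zeros((2, 2, 1))
        base[1, 0, 0] = 0.5
        spec = GroundTruthSpec(2, 1000.0, 1, base, np.zeros_like(base),
                               (0, 1), seed=11)
        trials = simulate_trial_sequence(1, 1, 40, 0.8, 0.5, seed=11)
        es = generate_var_epochs(spec, trials, (0.0, 1000.0))
        x, y = es.data[:, 0, :], es.data[:, 1, :]
        c = np.mean([
            np.mean((y[t, 1:] - y[t, 1:].mean()) * (x[t, :-1] - x[t, :-1].mean()))
            for t in range(es.n_trials)
        ])
        assert c == pytest.approx(0.5, abs=0.05)

    def test_null_delta_gives_equal_conditions(self):
        """With condition_delta = 0, both conditions sample the same process."""
        spec = coupled_spec(coupling=0.4, seed=21, delta_pair=None)
        trials = simulate_trial_sequence(1, 1, 60, 0.8, 0.5, seed=21)
        es = generate_var_epochs(spec, trials, (0.0, 400.0))
        flows = {
            cond: [
                ndte_pair(es.data[t, 0], es.data[t, 1], 1)
                for t in np.flatnonzero(es.condition == cond)
            ]
            for cond in (PREDICTIVE, NONPREDICTIVE)
        }
        from scipy import stats
        _, p = stats.ttest_ind(flows[PREDICTIVE], flows[NONPREDICTIVE])
        assert p > 0.005

    def test_nonstationary_spec_rejected_with_radius(self):
        base = np.zeros((2, 2, 1))
        base[0, 0, 0] = base[1, 1, 0] = 1.05
        with pytest.raises(StationarityError) as err:
            GroundTruthSpec(2, 1000.0, 1, base, np.zeros_like(base), (0, 1))
        assert err.value.spectral_radius == pytest.approx(1.05, abs=1e-9)

    def test_determinism(self):
        spec = coupled_spec(seed=31)
        trials = simulate_trial_sequence(1, 1, 5, 0.8, 0.5, seed=31)
        a = generate_var_epochs(spec, trials, (0.0, 200.0))
        b = generate_var_epochs(coupled_spec(seed=31), trials, (0.0, 200.0))
        np.testing.assert_array_equal(a.data, b.data)


class TestPlantRichClub:
    def test_structure_and_diagonal(self):
        M = plant_rich_club(10, {0, 1, 2}, 5, 1, 1, seed=3)
        assert np.all(np.diag(M) == 0)
        member = np.zeros(10, bool)
        member[:3] = True
        # club rows elevated; everything else near background/out weight
        assert M[member][:, ~member].min() > 4.9
        assert M[~member].max() < 1.2

    def test_preconditions(self):
        with pytest.raises(ValidationError):
            plant_rich_club(5, {0, 7}, 5, 1, 1)
        with pytest.raises(ValidationError):
            plant_rich_club(5, {0}, 1, 1, 2)  # in_weight not > background
        with pytest.raises(ValidationError):
            plant_rich_club(5, {0}, 5, 6, 1)  # out_weight not < in_weight


class TestRtTable:
    @staticmethod
    def _deltas(table):
        out = []
        for _, grp in table.groupby("participant_id"):
            out.append(
                grp.loc[grp["condition"] == NONPREDICTIVE, "rt_ms"].mean()
                - grp.loc[grp["condition"] == PREDICTIVE, "rt_ms"].mean()
            )
        return np.array(out)

    def test_equal_means_center_on_zero(self):
        trials = simulate_trial_sequence(20, 2, 20, 0.8, 0.5, seed=5)
        rt = generate_rt_table(trials, 340, 340, 40, 20, seed=5)
        d = self._deltas(rt)
        assert abs(d.mean()) < 3 * d.std(ddof=1) / np.sqrt(len(d))

    def test_degenerate_noise_hits_condition_means(self):
        trials = simulate_trial_sequence(2, 1, 5, 0.8, 0.5, seed=6)
        rt = generate_rt_table(trials, 330, 360, 1e-9, 1e-9, seed=6)
        expected = rt["condition"].map({PREDICTIVE: 330.0, NONPREDICTIVE: 360.0})
        np.testing.assert_allclose(rt["rt_ms"], expected, atol=1e-6)

    def test_paired_effect_size_in_range(self):
        """20 participants, means 330/360, sds 40/20 -> Cohen's d in [0.4, 1.2]."""
        ds = []
        for rep in range(30):
            trials = simulate_trial_sequence(20, 1, 2, 0.8, 0.5, seed=100 + rep)
            rt = generate_rt_table(trials, 330, 360, 40, 20, seed=200 + rep)
            d = self._deltas(rt)
            ds.append(d.mean() / d.std(ddof=1))
        assert 0.4 < np.mean(ds) < 1.2


class TestPhaseLockedEpochs:
    def test_zero_jitter_gives_perfect_itpc(self):
        es = generate_phase_locked_epochs(8, 250.0, 10.0, 0.0, seed=1)
        itpc, freqs = morlet_itpc(es, 5, 20, 5, trim_edges=True)
        fi = np.argmin(np.abs(freqs - 10))
        center = itpc[0, fi, es.n_samples // 2]
        assert center == pytest.approx(1.0, abs=1e-6)

    def test_wrapped_gaussian_resultant(self):
        """Gaussian phase jitter sd=0.5 -> ITPC ~ exp(-sd^2/2) at f0."""
        es = generate_phase_locked_epochs(500, 250.0, 10.0, 0.5, seed=2)
        itpc, freqs = morlet_itpc(es, 5, 20, 5, trim_edges=True)
        fi = np.argmin(np.abs(freqs - 10))
        center = itpc[0, fi, es.n_samples // 2]
        assert center == pytest.approx(np.exp(-0.125), abs=0.05)

    def test_aliasing_rejected(self):
        with pytest.raises(ValidationError):
            generate_phase_locked_epochs(4, 100.0, 60.0, 0.0)
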