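"""Shared simulation helpers for the test suite."""

import numpy as np

from ndteflow import surrogate_pvalues


def simulate_coupled_participants(
    n_participants, n_trials, n_rois, coupling, n_surrogates, seed,
    n_samples=300, lag=1,
):
    """Per-participant VAR trials with a planted 0 -> 1 coupling, plus
    surrogate statistics per trial, ready for standardize_and_mask."""
    rng = np.random.default_rng(seed)
    flows, stats_list = [], []
    for _ in range(n_participants):
        F_trials, st_trials = [], []
        for _ in range(n_trials):
            data = np.zeros((n_rois, n_samples))
            eps = rng.normal(size=(n_rois, n_samples))
            for t in range(1, n_samples):
                data[:, t] = 0.3 * data[:, t - 1] + eps[:, t]
                data[1, t] += coupling * data[0, t - 1]
            raw, st = surrogate_pvalues(data, lag, n_surrogates, seed=rng)
            F_trials.append(raw.F)
            st_trials.append(st)
        flows.append(np.stack(F_trials))
        stats_list.append(st_trials)
    labels = [f"roi{i:02d}" for i in range(n_rois)]
    return flows, stats_list, labels
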