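import numpy as np
import pytest

from ndteflow import EpochSet, GroundTruthSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_epochs(rng):
    """White-noise epochs: 10 trials x 3 regions x 400 samples at 1 kHz."""
    return EpochSet(
        data=rng.normal(size=(10, 3, 400)),
        fs_hz=1000.0,
        t0_ms=-500.0,
        region_labels=["a", "b", "c"],
        condition=np.array(["predictive_80"] * 5 + ["nonpredictive_50"] * 5),
        participant_id=0,
    )


def coupled_spec(n_rois=2, coupling=0.5, seed=0, fs=1000.0, delta_pair=None,
                 delta=0.0, effect_window=(-1e9, 1e9)):
    """VAR(1) spec with self-coupling 0.5 and one planted cross-coupling."""
    base = np.zeros((n_rois, n_rois, 1))
    for r in range(n_rois):
        base[r, r, 0] = 0.5
    if coupling and n_rois >= 2:
        base[1, 0, 0] = coupling
    cdelta = np.zeros_like(base)
    if delta_pair is not None:
        cdelta[delta_pair[0], delta_pair[1], 0] = delta
    return GroundTruthSpec(
        n_rois=n_rois,
        fs_hz=fs,
        var_order=1,
        base_coupling=base,
        condition_delta=cdelta,
        effect_window_ms=effect_window,
        noise_sd=1.0,
        seed=seed,
    )
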