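"""Shared fixtures: small synthetic cohorts reused across test modules."""

import numpy as np
import pytest

import balancenet as bn
from balancenet.preprocess import downsample
from balancenet.tvmvar import TimeVaryingVAR

CHANS5 = ["Cz", "CPz", "O1", "Oz", "O2"]
PDC_FREQS = np.arange(2.0, 20.5, 0.5)


def small_config(seed=0, couple=True, n_subjects=2, n_trials=10, **kw):
    """Reduced 5-channel montage at the analysis rate directly (no EOG,
    no sway/impulse) — the minimal setting in which the planted coupling
    is identifiable."""
    couplings = [bn.Coupling("CPz", "Cz", (5, 7), 0.0, 0.4, lag=2)] if couple else []
    defaults = dict(
        n_subjects=n_subjects,
        n_trials=n_trials,
        channel_names=list(CHANS5),
        fs_raw=1000.0,
        fs_out=100.0,
        seed=seed,
        couplings=couplings,
        oscillators=[
            bn.Oscillator(("CPz", "Cz"), 6.0, 7.5),
            bn.Oscillator(("O1", "Oz", "O2"), 10.0, 10.0),
        ],
        include_eog=False,
        onset_impulse_amplitude=0.0,
        sway=bn.SwayInterference(amplitude=0.0),
        alpha_drop=(0.5, 2.0) if couple else (0.0, 1.0),
    )
    defaults.update(kw)
    return bn.SimulationConfig(**defaults)


def simulate_epochs(cfg):
    """Generator output pushed through the decimation stage."""
    rec = bn.simulate_dataset(cfg)
    factor = int(round(cfg.fs_raw / cfg.fs_out))
    return downsample(rec, factor) if factor > 1 else rec


def fit_cohort(cfg, order=8):
    rec = simulate_epochs(cfg)
    return [TimeVaryingVAR(rec.subject(s), order=order).fit() for s in range(rec.n_subjects)]


@pytest.fixture(scope="session")
def coupled_fits():
    """Two-subject fitted cohort with the planted CPz→Cz theta coupling."""
    return fit_cohort(small_config(seed=11, couple=True))


@pytest.fixture(scope="session")
def coupled_pdc(coupled_fits):
    return [f.gpdc(freqs=PDC_FREQS, t_step=5) for f in coupled_fits]


@pytest.fixture(scope="session")
def stationary_var1():
    """10 trials of a stationary bivariate VAR(1) with known coefficients."""
    rng = np.random.default_rng(0)
    A = np.array([[0.5, 0.0], [0.4, 0.5]])
    x = np.zeros((1, 10, 2, 800))
    for r in range(10):
        xx = np.zeros((2, 820))
        for t in range(1, 820):
            xx[:, t] = A @ xx[:, t - 1] + rng.standard_normal(2)
        x[0, r] = xx[:, 20:]
    rec = bn.MultiTrialRecording(x, 100.0, ["a", "b"])
    return rec, A
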