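import numpy as np
import pytest

from eegdecode import CohortConfig, EpochSet, generate_cohort


def make_epochs(data, fs=250.0, groups=None, subjects=None, tasks=None):
    """EpochSet from a raw (epochs, channels, samples) array with stub labels."""
    n, n_ch, _ = data.shape
    pos = np.zeros((n_ch, 3))
    pos[:, 2] = 1.0
    return EpochSet(
        data=data,
        fs=fs,
        ch_names=[f"E{i + 1:03d}" for i in range(n_ch)],
        ch_pos=pos,
        subject=subjects if subjects is not None else ["S01"] * n,
        group=groups if groups is not None else ["M"] * n,
        task=tasks if tasks is not None else ["verb"] * n,
    )


def random_spd(rng, n, cond=0.1):
    a = rng.standard_normal((n, n))
    return a @ a.T + cond * n * np.eye(n)


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small planted-effect cohort shared across modules (deterministic)."""
    cfg = CohortConfig(
        n_subjects_per_group=4,
        n_channels=12,
        n_epochs_per_subject_per_task=8,
        tasks=("verb",),
        band_effects={"alpha1": (2, 3.0)},
        seed=7,
    )
    epochs, fwd = generate_cohort(cfg)
    return cfg, epochs, fwd
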