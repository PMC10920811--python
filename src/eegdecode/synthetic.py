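"""Synthetic EEG cohorts with a known linear forward model.

The generator emulates the statistical structure the decoding analysis
assumes: band-limited cortical sources mixed linearly into sensors,
``x_i = A s_i + eps_i``, with a planted multiplicative group difference in
the variance of selected sources, per-subject lognormal variability of
source power, and white sensor noise. Because the mixing matrix and the
per-subject source variances are known exactly, every downstream claim
(band-power differences, CSP/pattern recovery, cluster localization,
classification accuracy) can be tested against ground truth.

Within each epoch the source traces are orthogonalized in generation
order and rescaled, so the empirical source covariance is *exactly*
``diag(var)``; with ``noise_sd=0`` the epoch's sensor covariance equals
``A diag(var) A^T`` to machine precision, which the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sp_signal

from .containers import DEFAULT_BANDS, EpochSet, TASKS, BandDefinition, default_bands

_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class Montage:
    """Sensor layout: unique channel names with unit-sphere 3-D positions."""

    ch_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, float)
        if len(self.ch_names) != len(set(self.ch_names)):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(self.ch_names), 3):
            raise ValueError("positions must be (n_channels, 3)")
        if not np.allclose(np.linalg.norm(pos, axis=1), 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")


def generate_montage(n_channels: int, seed: int = 0) -> Montage:
    """Quasi-uniform sensor positions on the upper unit hemisphere.

    A Fibonacci spiral covers the hemisphere evenly; the seed rotates the
    spiral so different montages are distinct but reproducible.
    """
    if n_channels < 4:
        raise ValueError("need at least 4 channels")
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    i = np.arange(n_channels)
    z = 1.0 - (i + 0.5) / n_channels  # in (0, 1): upper hemisphere
    r = np.sqrt(1.0 - z**2)
    theta = _GOLDEN_ANGLE * i + phase
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    names = tuple(f"E{k + 1:03d}" for k in range(n_channels))
    return Montage(names, pos)


@dataclass
class ForwardModel:
    """Ground-truth mixing: sensors = mixing @ sources.

    ``mixing`` is (n_channels, n_sources) with unit-norm columns;
    ``source_bands`` names the band each source oscillates in;
    ``effect_channels`` maps an effected source to the channel indices
    its (localized) mixing column loads, when localization was requested.
    """

    mixing: np.ndarray
    source_bands: list[str]
    effect_channels: dict[int, np.ndarray] = field(default_factory=dict)
    subjects: list[str] = field(default_factory=list)
    subject_variances: np.ndarray | None = None  # (n_subjects, n_sources)

    def __post_init__(self) -> None:
        if np.any(np.linalg.norm(self.mixing, axis=0) == 0):
            raise ValueError("mixing columns must be nonzero")

    def expected_band_power(self, source_vars: np.ndarray) -> dict[str, np.ndarray]:
        """Noiseless per-channel band power implied by source variances.

        Power at channel c in band b is ``sum_s A[c,s]^2 var_s`` over the
        sources assigned to b — the analytic oracle for planted effects.
        """
        out: dict[str, np.ndarray] = {}
        for b in set(self.source_bands):
            idx = [k for k, sb in enumerate(self.source_bands) if sb == b]
            out[b] = (self.mixing[:, idx] ** 2) @ np.asarray(source_vars)[idx]
        return out


@dataclass
class CohortConfig:
    """Study-design parameters for one synthetic cohort.

    The desk-scale defaults (10 subjects per group, 24 channels, 40
    epochs per subject and task at 250 Hz, 2-s epochs) mirror the kind of
    two-group cognitive-skill cohort the analysis is built for while
    keeping a full run tractable on one CPU. ``band_effects`` plants the
    group difference: ``{"alpha1": (2, 2.0)}`` makes source 2 an alpha1
    oscillator whose variance is 2x larger in group M than in group H.
    """

    n_subjects_per_group: int = 10
    n_channels: int = 24
    n_epochs_per_subject_per_task: int = 40
    fs: float = 250.0
    epoch_len: float = 2.0
    n_sources: int = 8
    band_effects: dict[str, tuple[int, float]] = field(
        default_factory=lambda: {"alpha1": (2, 2.0)}
    )
    subject_sd: float = 0.2
    noise_sd: float = 0.3
    seed: int = 0
    tasks: tuple[str, ...] = TASKS
    effect_channel_count: int | None = None
    subject_mixing_sd: float = 0.0
    bands: tuple = DEFAULT_BANDS

    def __post_init__(self) -> None:
        for name, v in (
            ("n_subjects_per_group", self.n_subjects_per_group),
            ("n_channels", self.n_channels),
            ("n_epochs_per_subject_per_task", self.n_epochs_per_subject_per_task),
            ("n_sources", self.n_sources),
        ):
            if v < 1:
                raise ValueError(f"{name} must be >= 1")
        hi = max(b[2] for b in self.bands)
        if self.fs <= 2.0 * hi:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band edge {hi}")
        band_names = [b[0] for b in self.bands]
        for bname, (src, ratio) in self.band_effects.items():
            if bname not in band_names:
                raise ValueError(f"band_effects references unknown band {bname!r}")
            if not (0 <= src < self.n_sources):
                raise ValueError(f"band_effects references unknown source {src}")
            if ratio <= 0:
                raise ValueError("power ratios must be > 0")

    def band_definitions(self) -> list[BandDefinition]:
        return [BandDefinition(n, lo, hi) for n, lo, hi in self.bands]


def _source_band_assignment(config: CohortConfig) -> list[str]:
    names = [b[0] for b in config.bands]
    assign = [names[k % len(names)] for k in range(config.n_sources)]
    for bname, (src, _ratio) in config.band_effects.items():
        assign[src] = bname  # effected source oscillates in its effect band
    return assign


def _band_sos(config: CohortConfig) -> dict[str, np.ndarray]:
    sos = {}
    for name, lo, hi in config.bands:
        sos[name] = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=config.fs, output="sos")
    return sos


def _build_forward_model(config: CohortConfig, montage: Montage, rng) -> ForwardModel:
    n_ch, n_src = config.n_channels, config.n_sources
    A = rng.standard_normal((n_ch, n_src))
    effect_channels: dict[int, np.ndarray] = {}
    if config.effect_channel_count is not None:
        k = config.effect_channel_count
        if not (1 <= k <= n_ch):
            raise ValueError("effect_channel_count out of range")
        d = np.linalg.norm(
            montage.positions[:, None, :] - montage.positions[None, :, :], axis=-1
        )
        for _band, (src, _r) in config.band_effects.items():
            seed_ch = rng.integers(n_ch)
            chans = np.argsort(d[seed_ch])[:k]  # seed + nearest neighbours
            col = np.zeros(n_ch)
            col[chans] = 0.5 + rng.random(k)
            A[:, src] = col
            effect_channels[src] = np.sort(chans)
    A /= np.linalg.norm(A, axis=0, keepdims=True)
    return ForwardModel(A, _source_band_assignment(config), effect_channels)


def subject_source_variances(config: CohortConfig, rng) -> tuple[list[str], list[str], np.ndarray]:
    """Draw per-subject source variances (subjects, groups, subj x source).

    Baseline source variance is 1; group M gets the planted ratio on the
    effected sources; every subject gets independent lognormal jitter
    with log-scale SD ``subject_sd``.
    """
    subjects, groups = [], []
    for g in ("M", "H"):
        for i in range(config.n_subjects_per_group):
            subjects.append(f"{g}{i + 1:02d}")
            groups.append(g)
    base = np.ones(config.n_sources)
    ratios = {src: r for _b, (src, r) in config.band_effects.items()}
    out = np.empty((len(subjects), config.n_sources))
    for si, g in enumerate(groups):
        v = base.copy()
        if g == "M":
            for src, r in ratios.items():
                v[src] *= r
        v *= np.exp(rng.normal(0.0, config.subject_sd, size=config.n_sources))
        out[si] = v
    return subjects, groups, out


def _orthogonalized_sources(raw: np.ndarray, variances: np.ndarray) -> np.ndarray:
    """Demean, Gram-Schmidt in source order, rescale to exact variances.

    ``raw`` is (n_sources, T) band-limited noise. Orthogonalization against
    the constant vector and the previous sources makes the empirical
    covariance exactly diagonal; each trace is then scaled so its sample
    variance (ddof=1) equals the target. Cross-band leakage introduced by
    the projection is O(1/sqrt(T)) in amplitude and negligible.
    """
    n_src, T = raw.shape
    out = np.empty_like(raw)
    basis = []  # orthonormal rows spanning previous sources
    for k in range(n_src):
        v = raw[k] - raw[k].mean()
        for u in basis:
            v = v - (v @ u) * u
        nrm = np.linalg.norm(v)
        if nrm < 1e-12 * np.sqrt(T):
            raise RuntimeError("degenerate source trace during orthogonalization")
        u = v / nrm
        basis.append(u)
        out[k] = u * np.sqrt(variances[k] * (T - 1))
    return out


def generate_cohort(config: CohortConfig) -> tuple[EpochSet, ForwardModel]:
    """Simulate a labelled two-group epoch cohort plus its ground truth.

    Returns the :class:`EpochSet` (epochs x channels x samples with
    subject/group/task labels) and the :class:`ForwardModel` used to mix
    it. Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    montage = generate_montage(config.n_channels, seed=config.seed)
    fwd = _build_forward_model(config, montage, rng)
    subjects, groups, subj_vars = subject_source_variances(config, rng)
    fwd.subjects = list(subjects)
    fwd.subject_variances = subj_vars
    sos = _band_sos(config)
    T = int(round(config.epoch_len * config.fs))
    n_ep_subj = config.n_epochs_per_subject_per_task * len(config.tasks)
    n_total = len(subjects) * n_ep_subj

    # band-limit all source noise in a few vectorized filter calls
    raw = rng.standard_normal((n_total, config.n_sources, T))
    for b in set(fwd.source_bands):
        idx = [k for k, sb in enumerate(fwd.source_bands) if sb == b]
        raw[:, idx, :] = sp_signal.sosfiltfilt(sos[b], raw[:, idx, :], axis=-1)

    data = np.empty((n_total, config.n_channels, T))
    subj_l, group_l, task_l = [], [], []
    ep = 0
    for si, (subj, g) in enumerate(zip(subjects, groups)):
        A = fwd.mixing
        if config.subject_mixing_sd > 0:
            P = rng.standard_normal(A.shape) * config.subject_mixing_sd
            A = A + P
            A = A / np.linalg.norm(A, axis=0, keepdims=True)
        for task in config.tasks:
            for _ in range(config.n_epochs_per_subject_per_task):
                s = _orthogonalized_sources(raw[ep], subj_vars[si])
                x = A @ s
                if config.noise_sd > 0:
                    x = x + config.noise_sd * rng.standard_normal(x.shape)
                data[ep] = x
                subj_l.append(subj)
                group_l.append(g)
                task_l.append(task)
                ep += 1

    epochs = EpochSet(
        data=data,
        fs=config.fs,
        ch_names=list(montage.ch_names),
        ch_pos=montage.positions,
        subject=subj_l,
        group=group_l,
        task=task_l,
        meta={"seed": config.seed, "generator": "eegdecode.synthetic"},
    )
    return epochs, fwd


def null_cohort(config: CohortConfig) -> EpochSet:
    """Same generative process with every planted ratio forced to 1.

    Group labels are then exchangeable by construction — the type-I-error
    harness for the cluster permutation test and classifier baselines.
    """
    null_effects = {b: (src, 1.0) for b, (src, _r) in config.band_effects.items()}
    epochs, _fwd = generate_cohort(replace(config, band_effects=null_effects))
    return epochs
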