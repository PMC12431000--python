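"""Synthetic hemodynamic datasets with class-conditional connectivity.

The generator emulates the regime of task-based fNIRS recordings: ~10 Hz
sampling, 10 s task windows separated by rest, a double-gamma hemodynamic
response to the task boxcar, physiological noise (slow drift, ~0.1 Hz
Mayer waves, respiratory and cardiac oscillations), and HbR traces that
are scaled, anti-correlated copies of HbO.

Class identity is carried by *connectivity*, not only amplitude: each
class has (a) a Cp×Cp latent-correlation template governing correlations
between channel pairs, and (b) a per-pair HbO–HbR coupling governing the
within-pair correlation that the graph features measure.  An
amplitude-only mode (identical coupling across classes, different task
amplitudes) exists for ablation experiments that must isolate the raw
signal pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import EpochSet, HemodynamicRecording, interleaved_channel_roles


class ConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """All knobs of the generator; defaults give a 2-class, 10-pair study.

    Amplitudes are in μmol/L-equivalent units.  ``class_templates`` is
    (K, Cp, Cp) symmetric PSD with unit diagonal; ``pair_coupling`` is
    (K, Cp) in [-1, 1].  ``hbr_scale`` scales the HbR trace relative to
    HbO (negative: physiological anti-correlation).
    """

    n_subjects: int = 2
    n_trials_per_class: int = 5
    n_classes: int = 2
    n_pairs: int = 10
    sampling_rate: float = 10.0
    trial_task_s: float = 10.0
    rest_s: float = 15.0
    epoch_length_s: float = 1.0
    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_ratio: float = 1.0 / 6.0
    class_templates: np.ndarray | None = None
    pair_coupling: np.ndarray | None = None
    task_amplitude: np.ndarray | float = 1.0
    latent_amplitude: float = 1.0
    latent_smooth_s: float = 0.3
    noise_white: float = 0.1
    noise_drift: float = 0.2
    noise_mayer: float = 0.1
    noise_resp: float = 0.05
    noise_cardiac: float = 0.05
    hbr_scale: float = -0.3
    shuffle_labels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_templates is None:
            self.class_templates = np.broadcast_to(
                np.eye(self.n_pairs), (self.n_classes, self.n_pairs, self.n_pairs)
            ).copy()
        self.class_templates = np.asarray(self.class_templates, dtype=float)
        if self.class_templates.shape != (self.n_classes, self.n_pairs, self.n_pairs):
            raise ConfigError("class_templates must be (K, Cp, Cp)")
        for k, tpl in enumerate(self.class_templates):
            if not np.allclose(tpl, tpl.T):
                raise ConfigError(f"class {k} template is not symmetric")
            if not np.allclose(np.diag(tpl), 1.0):
                raise ConfigError(f"class {k} template must have unit diagonal")
            if np.linalg.eigvalsh(tpl).min() < -1e-8:
                raise ConfigError(f"class {k} template is not positive semi-definite")
        if self.pair_coupling is None:
            self.pair_coupling = np.ones((self.n_classes, self.n_pairs))
        self.pair_coupling = np.asarray(self.pair_coupling, dtype=float)
        if self.pair_coupling.shape != (self.n_classes, self.n_pairs):
            raise ConfigError("pair_coupling must be (K, Cp)")
        if np.any(np.abs(self.pair_coupling) > 1):
            raise ConfigError("pair_coupling entries must lie in [-1, 1]")
        amp = np.asarray(self.task_amplitude, dtype=float)
        if amp.ndim == 0:
            amp = np.full((self.n_classes, self.n_pairs), float(amp))
        self.task_amplitude = amp
        for name in ("noise_white", "noise_drift", "noise_mayer", "noise_resp",
                     "noise_cardiac", "latent_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be ≥ 0")


@dataclass
class SimulatedDataset:
    """Per-subject recordings plus the generating configuration."""

    recordings: list[HemodynamicRecording]
    config: SimConfig
    true_labels: list[np.ndarray] = field(default_factory=list)


def blocked_correlation_template(n_pairs: int, block: slice, rho: float = 0.9) -> np.ndarray:
    """Unit-diagonal template with one correlated block of pairs."""
    tpl = np.eye(n_pairs)
    idx = np.arange(n_pairs)[block]
    for a in idx:
        for b in idx:
            if a != b:
                tpl[a, b] = rho
    return tpl


def two_class_block_config(
    n_pairs: int = 10,
    coupled_strength: float = 0.9,
    uncoupled_strength: float = 0.0,
    template_rho: float = 0.8,
    **overrides,
) -> SimConfig:
    """Two classes with disjoint coupling blocks over the channel pairs.

    Class 0 couples the first half of the pairs (within-pair HbO–HbR
    coupling ``coupled_strength`` and a correlated inter-pair block);
    class 1 couples the second half.  Task amplitudes are identical across
    classes, so the class signal lives in the covariance structure only.
    """
    half = n_pairs // 2
    coupling = np.full((2, n_pairs), uncoupled_strength)
    coupling[0, :half] = coupled_strength
    coupling[1, half:] = coupled_strength
    templates = np.stack(
        [
            blocked_correlation_template(n_pairs, slice(0, half), template_rho),
            blocked_correlation_template(n_pairs, slice(half, n_pairs), template_rho),
        ]
    )
    return SimConfig(
        n_pairs=n_pairs,
        class_templates=templates,
        pair_coupling=coupling,
        **overrides,
    )


def amplitude_only_config(n_pairs: int = 10, amp_hi: float = 1.5, amp_lo: float = 0.5,
                          **overrides) -> SimConfig:
    """Two classes differing only in mean task amplitude (shared coupling)."""
    amp = np.full((2, n_pairs), amp_lo)
    amp[0, : n_pairs // 2] = amp_hi
    amp[1, n_pairs // 2 :] = amp_hi
    return SimConfig(n_pairs=n_pairs, task_amplitude=amp, **overrides)


def canonical_hrf(cfg: SimConfig, duration_s: float = 32.0) -> np.ndarray:
    """Double-gamma hemodynamic response kernel, peak normalized to 1.

    Difference of two gamma densities with modes at ``hrf_peak_s`` and
    ``hrf_undershoot_s``; zero at t = 0 and ≥ 30 s long.
    """
    if cfg.sampling_rate <= 0:
        raise ConfigError("sampling_rate must be positive")
    duration_s = max(duration_s, 30.0)
    t = np.arange(0.0, duration_s, 1.0 / cfg.sampling_rate)
    peak = stats.gamma.pdf(t, a=cfg.hrf_peak_s + 1.0, scale=1.0)
    under = stats.gamma.pdf(t, a=cfg.hrf_undershoot_s + 1.0, scale=1.0)
    h = peak - cfg.hrf_ratio * under
    return h / h.max()


def _smooth_rows(x: np.ndarray, window: int) -> np.ndarray:
    """Moving-average each row; same filter per row preserves the
    cross-row correlation structure."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = np.convolve(x[i], kernel, mode="same")
    return out


def task_response(cfg: SimConfig, n_samples: int) -> np.ndarray:
    """Task boxcar convolved with the canonical HRF, peak-normalized to 1.

    ``task_amplitude`` then directly sets the peak concentration change of
    the evoked response in μmol/L-equivalent units.
    """
    hrf = canonical_hrf(cfg)
    boxcar = np.ones(n_samples)
    resp = np.convolve(boxcar, hrf)[:n_samples]
    return resp / resp.max()


def simulate_trial(
    class_k: int,
    cfg: SimConfig,
    rng: np.random.Generator,
    n_samples: int | None = None,
    include_noise: bool = True,
) -> np.ndarray:
    """One task window: (Cp, 2, T) with axis 1 = (HbO, HbR).

    HbO_i = a_ki·r(t) + u_i(t) + noise, where r is the HRF-convolved task
    boxcar and u is a smoothed latent whose inter-pair covariance is the
    class template.  HbR_i = hbr_scale·(a_ki·r + c_ki·u_i +
    √(1−c_ki²)·v_i) + noise with v an independent latent, so the per-pair
    HbO–HbR correlation is controlled by the coupling c_ki.
    """
    if not 0 <= class_k < cfg.n_classes:
        raise ConfigError(f"class {class_k} out of range")
    t = n_samples or int(round(cfg.trial_task_s * cfg.sampling_rate))
    cp = cfg.n_pairs
    tpl = cfg.class_templates[class_k]
    chol = np.linalg.cholesky(tpl + 1e-10 * np.eye(cp))
    window = max(1, int(round(cfg.latent_smooth_s * cfg.sampling_rate)))

    # moving-average smoothing divides the variance by ~window; the sqrt
    # factor restores unit scale while keeping the correlation structure
    u = _smooth_rows(chol @ rng.standard_normal((cp, t)), window) * np.sqrt(window)
    v = _smooth_rows(rng.standard_normal((cp, t)), window) * np.sqrt(window)

    amp = cfg.task_amplitude[class_k][:, None]
    r = task_response(cfg, t)[None, :]
    c = cfg.pair_coupling[class_k][:, None]
    hbo = amp * r + cfg.latent_amplitude * u
    hbr_core = amp * r + cfg.latent_amplitude * (c * u + np.sqrt(1.0 - c**2) * v)
    hbr = cfg.hbr_scale * hbr_core
    if include_noise and cfg.noise_white > 0:
        hbo = hbo + cfg.noise_white * rng.standard_normal((cp, t))
        hbr = hbr + cfg.noise_white * rng.standard_normal((cp, t))
    return np.stack([hbo, hbr], axis=1)


def _background_noise(cfg: SimConfig, n_channels: int, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Drift plus physiological oscillations plus white noise."""
    t = np.arange(n) / cfg.sampling_rate
    out = cfg.noise_white * rng.standard_normal((n_channels, n)) if cfg.noise_white else np.zeros((n_channels, n))
    for amp, freq in (
        (cfg.noise_mayer, 0.1),
        (cfg.noise_resp, 0.3),
        (cfg.noise_cardiac, 1.0),  # aliased at 10 Hz; amplitude is what matters
    ):
        if amp > 0:
            phase = rng.uniform(0, 2 * np.pi, size=n_channels)
            jitter = freq * (1.0 + 0.05 * rng.standard_normal(n_channels))
            out += amp * np.sin(
                2 * np.pi * jitter[:, None] * t[None, :] + phase[:, None]
            )
    if cfg.noise_drift > 0:
        drift_freq = rng.uniform(0.005, 0.02, size=n_channels)
        phase = rng.uniform(0, 2 * np.pi, size=n_channels)
        out += cfg.noise_drift * np.sin(
            2 * np.pi * drift_freq[:, None] * t[None, :] + phase[:, None]
        )
    return out


def simulate_dataset(cfg: SimConfig) -> SimulatedDataset:
    """Full multi-subject recording set, bit-reproducible from the config.

    Each subject's recording interleaves rest and task periods; trial
    order is a seeded shuffle of a balanced class sequence.  With
    ``shuffle_labels=True`` the *annotated* labels are permuted while the
    signals keep their true generating classes (null-control datasets);
    the true labels are retained in ``SimulatedDataset.true_labels``.
    """
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sampling_rate
    t_task = int(round(cfg.trial_task_s * fs))
    t_rest = int(round(cfg.rest_s * fs))
    n_trials = cfg.n_classes * cfg.n_trials_per_class
    n_total = t_rest + n_trials * (t_task + t_rest)
    roles = interleaved_channel_roles(cfg.n_pairs)
    recordings = []
    true_labels = []
    for subject in range(cfg.n_subjects):
        labels = np.repeat(np.arange(cfg.n_classes), cfg.n_trials_per_class)
        rng.shuffle(labels)
        signal = _background_noise(cfg, 2 * cfg.n_pairs, n_total, rng)
        annotations = []
        onset = t_rest
        for label in labels:
            trial = simulate_trial(int(label), cfg, rng, include_noise=False)
            hbo, hbr = trial[:, 0, :], trial[:, 1, :]
            signal[0::2, onset : onset + t_task] += hbo
            signal[1::2, onset : onset + t_task] += hbr
            annotations.append((onset, int(label)))
            onset += t_task + t_rest
        true = np.array([lab for _, lab in annotations])
        if cfg.shuffle_labels:
            perm = rng.permutation(len(annotations))
            annotations = [
                (annotations[i][0], annotations[j][1])
                for i, j in zip(range(len(annotations)), perm)
            ]
        recordings.append(
            HemodynamicRecording(
                signal=signal,
                sampling_rate=fs,
                channel_roles=roles,
                trial_annotations=annotations,
                subject_id=subject,
            )
        )
        true_labels.append(true)
    return SimulatedDataset(recordings, cfg, true_labels)


def shuffle_epoch_labels(ep: EpochSet, seed: int = 0) -> EpochSet:
    """Null-control copy: permute epoch labels within each subject.

    Permuting at the epoch level (rather than the trial level) makes the
    label/signal association fully random at the unit of classification,
    so any decoder's accuracy is binomial around chance.
    """
    rng = np.random.default_rng(seed)
    out = ep.subset(np.arange(ep.n_epochs))
    labels = out.labels.copy()
    for subject in np.unique(out.subject_ids):
        idx = np.flatnonzero(out.subject_ids == subject)
        labels[idx] = labels[idx[rng.permutation(len(idx))]]
    out.labels = labels
    return out


def expected_epoch_count(cfg: SimConfig) -> int:
    """N = subjects × classes × trials/class × ⌊task_s / epoch_s⌋."""
    per_trial = int(cfg.trial_task_s // cfg.epoch_length_s)
    return cfg.n_subjects * cfg.n_classes * cfg.n_trials_per_class * per_trial
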