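"""Signal preprocessing: MBLL conversion, filtering, resampling, epoching.

The stages mirror standard fNIRS practice: optical-density changes are
inverted to hemoglobin-concentration changes with the modified Beer--Lambert
law, band-limited with a zero-phase Butterworth filter, optionally
downsampled, cut into non-overlapping fixed-length epochs inside each task
window, and baseline-corrected against the pre-stimulus interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .data import (
    EpochSet,
    HemodynamicRecording,
    InvalidCoefficientsError,
    OpticalRecording,
    StructuralError,
    interleaved_channel_roles,
)


class ConfigError(ValueError):
    """Preprocessing configuration is inconsistent with the data."""


class BaselineError(ValueError):
    """One or more trials lack enough pre-stimulus samples."""

    def __init__(self, trials: list[int]):
        self.trials = trials
        super().__init__(
            f"insufficient pre-stimulus samples for trial(s) {trials}"
        )


@dataclass
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``band`` is ``(low, high)`` in Hz for a bandpass, or ``(0, cutoff)`` /
    a single cutoff for a lowpass.  ``task_duration_s`` is the task-window
    length following each annotated onset.  ``context_pad_s`` symmetrically
    extends every epoch by that much pre/post context (default 0, i.e.
    strictly non-overlapping task-window segmentation).
    """

    filter_kind: str = "bandpass"  # "bandpass" | "lowpass" | "none"
    band: tuple[float, float] = (0.01, 0.1)
    filter_order: int = 3
    target_rate: float | None = None
    epoch_length_s: float = 1.0
    task_duration_s: float = 10.0
    baseline_window_s: float = 1.0
    context_pad_s: float = 0.0
    trailing_partial_policy: str = "drop"  # "drop" | "pad"

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0:
            raise ConfigError("epoch_length_s must be positive")
        if self.filter_kind not in ("bandpass", "lowpass", "none"):
            raise ConfigError(f"unknown filter_kind {self.filter_kind!r}")
        if self.trailing_partial_policy not in ("drop", "pad"):
            raise ConfigError(
                f"unknown trailing_partial_policy {self.trailing_partial_policy!r}"
            )


def mbll_convert(rec: OpticalRecording) -> HemodynamicRecording:
    """Invert ΔOD at two wavelengths to (ΔHbO, ΔHbR) per optode.

    For each optode, ``[ΔHbO; ΔHbR] = E⁻¹ · [ΔOD(λ1); ΔOD(λ2)] / (d·l)``
    sample-wise, where ``E`` is the 2×2 extinction matrix, ``d`` the
    differential pathlength factor and ``l`` the source-detector separation.
    Output rows are interleaved (HbO0, HbR0, HbO1, …) with ``channel_roles``
    populated; concentrations are in the reciprocal units of ``E · d · l``.
    """
    e = rec.extinction_coeffs
    det = np.linalg.det(e)
    if abs(det) < 1e-12 * max(1.0, float(np.abs(e).max()) ** 2):
        raise InvalidCoefficientsError(
            "extinction matrix is singular; HbO/HbR cannot be separated"
        )
    e_inv = np.linalg.inv(e)
    scale = rec.pathlength_factor * rec.separation
    if scale <= 0:
        raise InvalidCoefficientsError("pathlength_factor · separation must be > 0")
    n_opt = rec.n_optodes
    od = rec.delta_od.reshape(n_opt, 2, -1)  # (optode, wavelength, time)
    hb = np.einsum("ij,njt->nit", e_inv, od) / scale  # (optode, species, time)
    out = hb.reshape(2 * n_opt, -1)
    return HemodynamicRecording(
        signal=out,
        sampling_rate=rec.sampling_rate,
        channel_roles=interleaved_channel_roles(n_opt),
    )


def mbll_forward(
    hbo: np.ndarray,
    hbr: np.ndarray,
    extinction: np.ndarray,
    pathlength_factor: float,
    separation: float,
) -> np.ndarray:
    """Forward model: concentrations → ΔOD rows (λ1, λ2) per optode.

    The exact inverse of :func:`mbll_convert`; used to synthesize optical
    recordings with known ground truth.
    """
    hbo = np.atleast_2d(hbo)
    hbr = np.atleast_2d(hbr)
    conc = np.stack([hbo, hbr], axis=1)  # (optode, species, time)
    od = np.einsum("ij,njt->nit", extinction, conc) * (
        pathlength_factor * separation
    )
    return od.reshape(-1, od.shape[-1])


def _design_sos(cfg: PreprocessConfig, fs: float) -> np.ndarray:
    nyq = fs / 2.0
    if cfg.filter_kind == "bandpass":
        low, high = cfg.band
        if not 0 < low < high < nyq:
            raise ConfigError(
                f"bandpass edges {cfg.band} invalid for Nyquist {nyq} Hz"
            )
        return sps.butter(cfg.filter_order, [low, high], btype="bandpass", fs=fs, output="sos")
    cutoff = cfg.band[1] if isinstance(cfg.band, (tuple, list)) else cfg.band
    if not 0 < cutoff < nyq:
        raise ConfigError(f"lowpass cutoff {cutoff} invalid for Nyquist {nyq} Hz")
    return sps.butter(cfg.filter_order, cutoff, btype="lowpass", fs=fs, output="sos")


def filter_signal(
    rec: HemodynamicRecording, cfg: PreprocessConfig
) -> HemodynamicRecording:
    """Zero-phase Butterworth filtering (forward-backward), same shape.

    A bandpass removes constant offsets and slow drift; a lowpass preserves
    DC.  Zero-phase application avoids shifting the sluggish hemodynamic
    response in time.
    """
    if cfg.filter_kind == "none":
        return rec.copy_with(signal=rec.signal.copy())
    sos = _design_sos(cfg, rec.sampling_rate)
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return rec.copy_with(signal=np.ascontiguousarray(filtered))


def resample(rec: HemodynamicRecording, target_rate: float) -> HemodynamicRecording:
    """Polyphase resampling to ``target_rate``; onsets rescaled to match."""
    if target_rate <= 0:
        raise ConfigError("target_rate must be positive")
    if target_rate > rec.sampling_rate:
        raise ConfigError("upsampling is not supported (target_rate > rate)")
    if target_rate == rec.sampling_rate:
        return rec.copy_with(signal=rec.signal.copy())
    frac = Fraction(target_rate / rec.sampling_rate).limit_denominator(1000)
    up, down = frac.numerator, frac.denominator
    out = sps.resample_poly(rec.signal, up, down, axis=1, padtype="line")
    ratio = target_rate / rec.sampling_rate
    annotations = [
        (int(round(onset * ratio)), label) for onset, label in rec.trial_annotations
    ]
    annotations = [
        (min(onset, out.shape[1] - 1), label) for onset, label in annotations
    ]
    return HemodynamicRecording(
        signal=out,
        sampling_rate=target_rate,
        channel_roles=list(rec.channel_roles),
        trial_annotations=annotations,
        subject_id=rec.subject_id,
    )


def segment_epochs(rec: HemodynamicRecording, cfg: PreprocessConfig) -> EpochSet:
    """Cut each task window into non-overlapping fixed-length epochs.

    Each trial's window ``[onset, onset + task_duration)`` yields
    ``⌊task_duration / epoch_length⌋`` epochs inheriting the trial's label
    and the recording's subject id.  A trailing partial segment is dropped
    or zero-padded per ``trailing_partial_policy``.  ``context_pad_s``
    extends each epoch symmetrically with surrounding context.
    """
    fs = rec.sampling_rate
    t_epoch = int(round(cfg.epoch_length_s * fs))
    if t_epoch < 1:
        raise ConfigError("epoch_length_s too short for the sampling rate")
    t_task = int(round(cfg.task_duration_s * fs))
    pad = int(round(cfg.context_pad_s * fs))
    n_total = rec.n_samples

    epochs, labels, onsets, trial_ids = [], [], [], []
    for trial_id, (onset, label) in enumerate(rec.trial_annotations):
        n_full = t_task // t_epoch
        if n_full == 0 and cfg.trailing_partial_policy == "drop":
            warnings.warn(
                f"trial {trial_id}: epoch length exceeds task window; "
                "no epochs produced",
                stacklevel=2,
            )
        n_segs = n_full
        if cfg.trailing_partial_policy == "pad" and t_task % t_epoch:
            n_segs += 1
        for j in range(n_segs):
            start = onset + j * t_epoch
            stop = start + t_epoch
            lo, hi = start - pad, stop + pad
            seg = np.zeros((rec.n_channels, t_epoch + 2 * pad))
            src_lo, src_hi = max(lo, 0), min(hi, n_total)
            seg[:, src_lo - lo : src_lo - lo + (src_hi - src_lo)] = rec.signal[
                :, src_lo:src_hi
            ]
            epochs.append(seg)
            labels.append(label)
            onsets.append(onset)
            trial_ids.append(trial_id)

    t_out = t_epoch + 2 * pad
    arr = (
        np.stack(epochs)
        if epochs
        else np.empty((0, rec.n_channels, t_out))
    )
    return EpochSet(
        epochs=arr,
        labels=np.asarray(labels, dtype=int),
        subject_ids=np.full(len(labels), rec.subject_id, dtype=int),
        sampling_rate=fs,
        epoch_length_s=cfg.epoch_length_s,
        channel_roles=list(rec.channel_roles),
        trial_onsets=np.asarray(onsets, dtype=int),
        trial_ids=np.asarray(trial_ids, dtype=int),
    )


def baseline_correct(
    ep: EpochSet, rec: HemodynamicRecording, cfg: PreprocessConfig
) -> EpochSet:
    """Subtract each parent trial's pre-stimulus mean, per channel.

    The reference interval is the ``baseline_window_s`` immediately before
    the trial onset.  Raises :class:`BaselineError` listing any trials with
    too few pre-onset samples.
    """
    if ep.trial_onsets is None:
        raise StructuralError("EpochSet lacks trial_onsets; segment first")
    n_base = int(round(cfg.baseline_window_s * rec.sampling_rate))
    if n_base < 1:
        raise ConfigError("baseline_window_s too short for the sampling rate")

    bad = sorted(
        {int(t) for o, t in zip(ep.trial_onsets, ep.trial_ids) if o - n_base < 0}
    )
    if bad:
        raise BaselineError(bad)

    corrected = ep.epochs.copy()
    means: dict[int, np.ndarray] = {}
    for i, onset in enumerate(ep.trial_onsets):
        onset = int(onset)
        if onset not in means:
            means[onset] = rec.signal[:, onset - n_base : onset].mean(axis=1)
        corrected[i] -= means[onset][:, None]
    out = ep.subset(np.arange(ep.n_epochs))
    out.epochs = corrected
    return out


def preprocess_recording(
    rec: HemodynamicRecording, cfg: PreprocessConfig
) -> EpochSet:
    """Full chain: (resample) → filter → segment → baseline-correct."""
    if cfg.target_rate is not None and cfg.target_rate != rec.sampling_rate:
        rec = resample(rec, cfg.target_rate)
    rec = filter_signal(rec, cfg)
    ep = segment_epochs(rec, cfg)
    return baseline_correct(ep, rec, cfg)
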