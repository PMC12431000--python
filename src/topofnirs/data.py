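"""Core data containers for multichannel fNIRS decoding.

The pipeline moves through three representations:

``OpticalRecording``
    Raw optical-density changes at two near-infrared wavelengths, plus the
    constants needed for the modified Beer--Lambert inversion.
``HemodynamicRecording``
    Continuous ΔHbO/ΔHbR concentration changes (μmol/L) with channel-pair
    metadata and trial annotations.
``EpochSet``
    Labeled, fixed-length segments (N × C × T) — the unit of classification.

Each optode channel yields one *channel pair*: its HbO and its HbR trace.
With ``Cp`` pairs the channel count is ``C = 2 * Cp``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HBO = "HbO"
HBR = "HbR"

#: Molar extinction coefficients (1/(mM·cm)) at 760 and 850 nm, rows are
#: wavelengths, columns are (HbO, HbR).  Commonly tabulated values; override
#: per instrument.
DEFAULT_EXTINCTION = np.array([[1.4866, 3.8437], [2.5264, 1.7986]])
DEFAULT_WAVELENGTHS = (760.0, 850.0)


class InvalidCoefficientsError(ValueError):
    """Extinction-coefficient matrix is singular or otherwise unusable."""


class StructuralError(ValueError):
    """Input arrays do not have the structure the operation requires."""


@dataclass
class OpticalRecording:
    """Continuous optical-density changes ΔOD(t, λ) for a set of optodes.

    ``delta_od`` has two rows per optode: row ``2k`` is ΔOD at ``wavelengths[0]``
    and row ``2k + 1`` is ΔOD at ``wavelengths[1]`` for optode ``k``.

    Parameters
    ----------
    delta_od : (2 * n_optodes, T) array
    wavelengths : (λ1, λ2) in nm
    sampling_rate : Hz
    pathlength_factor : dimensionless differential pathlength factor
    separation : source-detector distance in cm
    extinction_coeffs : 2×2 matrix, ``[[ε_HbO(λ1), ε_HbR(λ1)],
        [ε_HbO(λ2), ε_HbR(λ2)]]`` in 1/(mM·cm)
    """

    delta_od: np.ndarray
    sampling_rate: float
    wavelengths: tuple[float, float] = DEFAULT_WAVELENGTHS
    pathlength_factor: float = 6.0
    separation: float = 3.0
    extinction_coeffs: np.ndarray = field(
        default_factory=lambda: DEFAULT_EXTINCTION.copy()
    )

    def __post_init__(self) -> None:
        self.delta_od = np.asarray(self.delta_od, dtype=float)
        self.extinction_coeffs = np.asarray(self.extinction_coeffs, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.delta_od.ndim != 2:
            raise StructuralError("delta_od must be a 2-D (channels × time) array")
        if self.delta_od.shape[0] % 2 != 0:
            raise StructuralError(
                "delta_od needs two wavelength rows per optode; got an odd "
                f"number of rows ({self.delta_od.shape[0]})"
            )
        if self.extinction_coeffs.shape != (2, 2):
            raise InvalidCoefficientsError("extinction_coeffs must be 2×2")

    @property
    def n_optodes(self) -> int:
        return self.delta_od.shape[0] // 2


def interleaved_channel_roles(n_pairs: int) -> list[tuple[int, str]]:
    """Channel-role list for the canonical row order HbO0, HbR0, HbO1, …"""
    roles: list[tuple[int, str]] = []
    for i in range(n_pairs):
        roles.append((i, HBO))
        roles.append((i, HBR))
    return roles


@dataclass
class HemodynamicRecording:
    """Continuous hemoglobin-concentration changes with trial annotations.

    ``channel_roles[c]`` maps row ``c`` of ``signal`` to ``(pair_index,
    species)`` with species in {"HbO", "HbR"}; every pair index appears
    exactly once per species.  ``trial_annotations`` is a list of
    ``(onset_sample, label)`` marking task onsets.
    """

    signal: np.ndarray
    sampling_rate: float
    channel_roles: list[tuple[int, str]]
    trial_annotations: list[tuple[int, int]] = field(default_factory=list)
    subject_id: int = 0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise StructuralError("signal must be 2-D (channels × time)")
        c = self.signal.shape[0]
        if c != len(self.channel_roles):
            raise StructuralError("one channel_roles entry required per signal row")
        if c % 2 != 0:
            raise StructuralError("channel count must be even (C = 2·Cp)")
        seen: set[tuple[int, str]] = set()
        for pair, species in self.channel_roles:
            if species not in (HBO, HBR):
                raise StructuralError(f"unknown species {species!r}")
            if (pair, species) in seen:
                raise StructuralError(f"duplicate role ({pair}, {species})")
            seen.add((pair, species))
        for i in range(c // 2):
            if (i, HBO) not in seen or (i, HBR) not in seen:
                raise StructuralError(f"pair {i} missing an HbO or HbR row")
        n = self.signal.shape[1]
        for onset, _ in self.trial_annotations:
            if not 0 <= onset < n:
                raise StructuralError(f"trial onset {onset} outside signal")

    @property
    def n_pairs(self) -> int:
        return self.signal.shape[0] // 2

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def pair_rows(self) -> np.ndarray:
        """Row indices as an (n_pairs, 2) array of (HbO row, HbR row)."""
        rows = np.empty((self.n_pairs, 2), dtype=int)
        for c, (pair, species) in enumerate(self.channel_roles):
            rows[pair, 0 if species == HBO else 1] = c
        return rows

    def copy_with(self, **changes) -> "HemodynamicRecording":
        return replace(self, **changes)


@dataclass
class EpochSet:
    """N labeled epochs of shape C × T — the model's unit of classification.

    ``trial_onsets`` records, per epoch, the onset sample of the parent trial
    in the source recording (needed for pre-stimulus baseline correction);
    ``trial_ids`` identifies the parent trial.
    """

    epochs: np.ndarray
    labels: np.ndarray
    subject_ids: np.ndarray
    sampling_rate: float
    epoch_length_s: float
    channel_roles: list[tuple[int, str]]
    trial_onsets: np.ndarray | None = None
    trial_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.subject_ids = np.asarray(self.subject_ids, dtype=int)
        if self.epochs.ndim != 3:
            raise StructuralError("epochs must be N × C × T")
        n = self.epochs.shape[0]
        if len(self.labels) != n or len(self.subject_ids) != n:
            raise StructuralError("labels/subject_ids must match epoch count")
        if n and not np.isfinite(self.epochs).all():
            raise StructuralError("epochs contain non-finite values")
        if self.trial_onsets is not None:
            self.trial_onsets = np.asarray(self.trial_onsets, dtype=int)
        if self.trial_ids is not None:
            self.trial_ids = np.asarray(self.trial_ids, dtype=int)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]

    @property
    def n_pairs(self) -> int:
        return self.epochs.shape[1] // 2

    @property
    def n_timepoints(self) -> int:
        return self.epochs.shape[2]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1 if self.n_epochs else 0

    def pair_rows(self) -> np.ndarray:
        rows = np.empty((self.n_pairs, 2), dtype=int)
        for c, (pair, species) in enumerate(self.channel_roles):
            rows[pair, 0 if species == HBO else 1] = c
        return rows

    def subset(self, idx) -> "EpochSet":
        idx = np.asarray(idx)
        return EpochSet(
            epochs=self.epochs[idx],
            labels=self.labels[idx],
            subject_ids=self.subject_ids[idx],
            sampling_rate=self.sampling_rate,
            epoch_length_s=self.epoch_length_s,
            channel_roles=list(self.channel_roles),
            trial_onsets=None if self.trial_onsets is None else self.trial_onsets[idx],
            trial_ids=None if self.trial_ids is None else self.trial_ids[idx],
        )


def concatenate_epoch_sets(sets: list[EpochSet]) -> EpochSet:
    """Stack epoch sets from several recordings (e.g. one per subject)."""
    if not sets:
        raise ValueError("no epoch sets to concatenate")
    first = sets[0]
    for s in sets[1:]:
        if s.epochs.shape[1:] != first.epochs.shape[1:]:
            raise StructuralError("epoch sets have incompatible shapes")
        if s.sampling_rate != first.sampling_rate:
            raise StructuralError("epoch sets have different sampling rates")
    has_onsets = all(s.trial_onsets is not None for s in sets)
    has_ids = all(s.trial_ids is not None for s in sets)
    return EpochSet(
        epochs=np.concatenate([s.epochs for s in sets]),
        labels=np.concatenate([s.labels for s in sets]),
        subject_ids=np.concatenate([s.subject_ids for s in sets]),
        sampling_rate=first.sampling_rate,
        epoch_length_s=first.epoch_length_s,
        channel_roles=list(first.channel_roles),
        trial_onsets=(
            np.concatenate([s.trial_onsets for s in sets]) if has_onsets else None
        ),
        trial_ids=np.concatenate([s.trial_ids for s in sets]) if has_ids else None,
    )
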