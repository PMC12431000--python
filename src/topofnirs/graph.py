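"""Graph-theoretic connectivity features for epoched fNIRS signals.

Per epoch, three local features describe each HbO/HbR channel pair:

* connection strength ``s = (ρ + 1) / 2`` — the normalized Pearson
  correlation of the pair,
* connection density ``Sd`` — the fraction of length-``L`` sliding windows
  whose within-pair correlation exceeds a significance threshold,
* RFSMD — the reciprocal of the mean absolute difference between the two
  traces (plus a small ε), a proxy for information-transfer efficiency.

Globally, a binary adjacency over all ``C`` channels (edges where the
between-channel correlation exceeds a threshold) yields the network's
global efficiency: the mean inverse shortest-path length over node pairs.
Everything is fused with the flattened raw epoch into a single vector
``f3 = [f1; f2; e]`` of dimension ``C·T + 3·Cp + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .data import EpochSet, StructuralError


class ConfigError(ValueError):
    pass


@dataclass
class FeatureConfig:
    """Thresholds and window length for the connectivity features.

    ``thresholds_signed=True`` compares the signed correlation against the
    threshold (edges require ρ > threshold); set it to ``False`` to use
    |ρ|, which matters when HbO and HbR are strongly anti-correlated.
    """

    density_threshold: float = 0.3
    adjacency_threshold: float = 0.3
    window_length_s: float = 1.0
    epsilon: float = 1e-6
    thresholds_signed: bool = True

    def __post_init__(self) -> None:
        for name in ("density_threshold", "adjacency_threshold"):
            v = getattr(self, name)
            if not -1.0 < v < 1.0:
                raise ConfigError(f"{name} must lie in (-1, 1); got {v}")
        if self.epsilon <= 0:
            raise ConfigError("epsilon must be positive")

    def window_samples(self, sampling_rate: float, n_timepoints: int) -> int:
        length = int(round(self.window_length_s * sampling_rate))
        length = min(length, n_timepoints)
        if length < 2:
            raise ConfigError(
                "window_length_s yields fewer than 2 samples at "
                f"{sampling_rate} Hz"
            )
        return length


@dataclass
class PairFeatures:
    """Local features per channel pair, each of length Cp."""

    strength: np.ndarray
    density: np.ndarray
    rfsmd: np.ndarray
    degenerate: np.ndarray  # True where the full-epoch correlation was undefined

    def stacked(self) -> np.ndarray:
        """f2: (s_1, Sd_1, RFSMD_1, …, s_Cp, Sd_Cp, RFSMD_Cp)."""
        return np.column_stack([self.strength, self.density, self.rfsmd]).ravel()

    def as_matrix(self) -> np.ndarray:
        """(Cp, 3) matrix with columns (s, Sd, RFSMD)."""
        return np.column_stack([self.strength, self.density, self.rfsmd])


@dataclass
class ConnectivityGraph:
    adjacency: np.ndarray
    global_efficiency: float


@dataclass
class FusedFeature:
    f1: np.ndarray
    f2: np.ndarray
    efficiency: float

    @property
    def f3(self) -> np.ndarray:
        return np.concatenate([self.f1, self.f2, [self.efficiency]])


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    xc = x - x.mean()
    yc = y - y.mean()
    vx = float(xc @ xc)
    vy = float(yc @ yc)
    if vx == 0.0 or vy == 0.0:
        return 0.0, True
    r = float(xc @ yc) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0)), False


def pearson_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; 0 if either series has zero variance.

    Degenerate (zero-variance) inputs are mapped to 0 rather than NaN so
    that downstream window counts stay well defined; use
    :func:`pearson_corr_flagged` to detect that case.
    """
    return pearson_corr_flagged(x, y)[0]


def pearson_corr_flagged(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise StructuralError("series must have equal length")
    if x.size < 2:
        raise StructuralError("series must have length ≥ 2")
    return _pearson(x, y)


def connection_strength(x_hbo: np.ndarray, x_hbr: np.ndarray) -> float:
    """Normalized correlation ``(ρ + 1) / 2`` of a channel pair, in [0, 1]."""
    rho = pearson_corr(x_hbo, x_hbr)
    return (rho + 1.0) / 2.0


def _windowed_correlations(
    x: np.ndarray, y: np.ndarray, window: int
) -> np.ndarray:
    """Pearson ρ in every length-``window`` sliding window (stride 1)."""
    xw = np.lib.stride_tricks.sliding_window_view(x, window)
    yw = np.lib.stride_tricks.sliding_window_view(y, window)
    xc = xw - xw.mean(axis=1, keepdims=True)
    yc = yw - yw.mean(axis=1, keepdims=True)
    vx = (xc * xc).sum(axis=1)
    vy = (yc * yc).sum(axis=1)
    num = (xc * yc).sum(axis=1)
    denom = np.sqrt(vx * vy)
    rho = np.zeros_like(num)
    ok = denom > 0
    rho[ok] = num[ok] / denom[ok]
    return np.clip(rho, -1.0, 1.0)


def connection_density(
    x_hbo: np.ndarray, x_hbr: np.ndarray, cfg: FeatureConfig, sampling_rate: float
) -> float:
    """Fraction of sliding windows with ρ above the significance threshold.

    Windows slide by one sample, giving ``T - L + 1`` windows; with
    ``L = T`` the density is the indicator of the full-epoch correlation
    exceeding the threshold.
    """
    x = np.asarray(x_hbo, dtype=float).ravel()
    y = np.asarray(x_hbr, dtype=float).ravel()
    if x.shape != y.shape:
        raise StructuralError("series must have equal length")
    window = cfg.window_samples(sampling_rate, x.size)
    rho = _windowed_correlations(x, y, window)
    if not cfg.thresholds_signed:
        rho = np.abs(rho)
    return float(np.mean(rho > cfg.density_threshold))


def rfsmd(x_hbo: np.ndarray, x_hbr: np.ndarray, cfg: FeatureConfig) -> float:
    """Reciprocal of the mean absolute pair difference (+ ε)."""
    x = np.asarray(x_hbo, dtype=float).ravel()
    y = np.asarray(x_hbr, dtype=float).ravel()
    if x.shape != y.shape:
        raise StructuralError("series must have equal length")
    return 1.0 / (float(np.mean(np.abs(x - y))) + cfg.epsilon)


def build_adjacency(epoch: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Binary symmetric adjacency over all C channels (HbO and HbR rows).

    ``A[c1, c2] = 1`` iff the between-channel correlation exceeds the
    global connection threshold; diagonal zero.  Zero-variance channels
    contribute no edges.
    """
    epoch = np.asarray(epoch, dtype=float)
    c = epoch.shape[0]
    if c < 2:
        raise ConfigError("need at least two channels")
    centered = epoch - epoch.mean(axis=1, keepdims=True)
    var = (centered * centered).sum(axis=1)
    denom = np.sqrt(np.outer(var, var))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, centered @ centered.T / np.where(denom > 0, denom, 1.0), 0.0)
    corr = np.clip(corr, -1.0, 1.0)
    if not cfg.thresholds_signed:
        corr = np.abs(corr)
    adj = (corr > cfg.adjacency_threshold).astype(int)
    np.fill_diagonal(adj, 0)
    return adj


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean inverse shortest-path length over all ordered node pairs.

    Distances come from breadth-first search on the unweighted graph;
    disconnected pairs contribute 0.  Equals 1 for a complete graph and 0
    for an empty one.
    """
    a = np.asarray(adjacency)
    c = a.shape[0]
    if a.ndim != 2 or a.shape[1] != c:
        raise StructuralError("adjacency must be square")
    if c < 2:
        raise ConfigError("global efficiency needs at least two nodes")
    if not np.array_equal(a, a.T):
        raise StructuralError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise StructuralError("adjacency must have a zero diagonal")
    dist = shortest_path(a, method="D", unweighted=True, directed=False)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (c * (c - 1)))


def compute_pair_features(
    epoch: np.ndarray,
    pair_rows: np.ndarray,
    cfg: FeatureConfig,
    sampling_rate: float,
) -> PairFeatures:
    """All three local features for every channel pair of one epoch."""
    n_pairs = pair_rows.shape[0]
    strength = np.empty(n_pairs)
    density = np.empty(n_pairs)
    rec_diff = np.empty(n_pairs)
    degenerate = np.zeros(n_pairs, dtype=bool)
    for i, (row_o, row_r) in enumerate(pair_rows):
        x, y = epoch[row_o], epoch[row_r]
        rho, degen = pearson_corr_flagged(x, y)
        strength[i] = (rho + 1.0) / 2.0
        degenerate[i] = degen
        density[i] = connection_density(x, y, cfg, sampling_rate)
        rec_diff[i] = rfsmd(x, y, cfg)
    return PairFeatures(strength, density, rec_diff, degenerate)


def assemble_features(
    epoch: np.ndarray,
    pair_rows: np.ndarray,
    cfg: FeatureConfig,
    sampling_rate: float,
) -> tuple[PairFeatures, ConnectivityGraph, FusedFeature]:
    """Local features, thresholded graph, efficiency, and the fused vector.

    ``f1`` flattens the epoch column-wise (time-major), ``f2`` stacks
    (s, Sd, RFSMD) per pair, and ``f3 = [f1; f2; e]`` has dimension
    ``C·T + 3·Cp + 1``.
    """
    epoch = np.asarray(epoch, dtype=float)
    pair = compute_pair_features(epoch, pair_rows, cfg, sampling_rate)
    adj = build_adjacency(epoch, cfg)
    eff = global_efficiency(adj)
    fused = FusedFeature(
        f1=epoch.ravel(order="F"), f2=pair.stacked(), efficiency=eff
    )
    return pair, ConnectivityGraph(adj, eff), fused


def epoch_set_features(
    ep: EpochSet, cfg: FeatureConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized feature extraction over an EpochSet.

    Returns ``(pair_feats, f3, efficiency)`` with shapes
    ``(N, Cp, 3)``, ``(N, D)`` and ``(N,)``.
    """
    rows = ep.pair_rows()
    n = ep.n_epochs
    d = ep.n_channels * ep.n_timepoints + 3 * ep.n_pairs + 1
    pair_feats = np.empty((n, ep.n_pairs, 3))
    f3 = np.empty((n, d))
    eff = np.empty(n)
    for i in range(n):
        pair, graph, fused = assemble_features(
            ep.epochs[i], rows, cfg, ep.sampling_rate
        )
        pair_feats[i] = pair.as_matrix()
        f3[i] = fused.f3
        eff[i] = graph.global_efficiency
    return pair_feats, f3, eff


def average_efficiency(ep: EpochSet, cfg: FeatureConfig) -> float:
    """Mean global efficiency over epochs, as a percentage in [0, 100]."""
    if ep.n_epochs == 0:
        raise ValueError("average_efficiency needs at least one epoch")
    effs = [
        global_efficiency(build_adjacency(ep.epochs[i], cfg))
        for i in range(ep.n_epochs)
    ]
    return 100.0 * float(np.mean(effs))
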