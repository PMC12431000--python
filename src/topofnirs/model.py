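"""Topology-gated temporal network for epoched fNIRS classification.

Architecture, per epoch:

1. each HbO/HbR channel pair's 2-dimensional time series is linearly
   projected into ``d_model`` dimensions and encoded by a Transformer
   layer along time (shared weights across pairs);
2. temporal average pooling gives one ``d_model`` vector per pair;
3. the fused feature vector ``f3`` (raw signal + pair features + global
   efficiency) is projected to ``d_model`` and concatenated onto every
   pair's pooled vector, forming a length-``Cp`` sequence;
4. a softmax attention over pairs, computed from the graph features
   (strength, density, RFSMD), is injected into every gate of a
   bidirectional LSTM that runs over the pair sequence;
5. an MLP head classifies ``[f3; h_final]``.

The network is pure NumPy on the :mod:`topofnirs.autodiff` tape; see
``docs/methods.md`` for the design decisions (sequence axis, attention
injection mode, initialization).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, log_softmax, softmax
from .data import StructuralError

VARIANTS = ("full", "no_graph_features", "no_GAM", "no_BiLSTM", "no_GAM_no_BiLSTM")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    ``alpha_mode`` chooses how the pair-attention weights enter the LSTM
    gates: ``"scalar_per_step"`` feeds step ``i`` its own weight α_i (one
    scalar per gate input), ``"full_vector"`` feeds the whole α vector to
    every step.
    """

    d_model: int = 64
    n_heads: int = 4
    n_encoder_layers: int = 1
    ffn_dim: int = 128
    lstm_hidden: int = 64
    mlp_hidden: int = 128
    n_classes: int = 2
    dropout_temporal: float = 0.1
    dropout_mlp: float = 0.2
    alpha_mode: str = "scalar_per_step"
    lstm_output: str = "last"  # "last" | "mean_pooled"

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")
        if self.alpha_mode not in ("scalar_per_step", "full_vector"):
            raise ValueError(f"unknown alpha_mode {self.alpha_mode!r}")
        if self.lstm_output not in ("last", "mean_pooled"):
            raise ValueError(f"unknown lstm_output {self.lstm_output!r}")
        for name in (
            "d_model",
            "n_heads",
            "n_encoder_layers",
            "ffn_dim",
            "lstm_hidden",
            "mlp_hidden",
            "n_classes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# initialization helpers


def _xavier(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _lstm_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def sinusoidal_positional_encoding(n_positions: int, d_model: int) -> np.ndarray:
    """Standard sin/cos positional encoding, shape (n_positions, d_model)."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    pe = np.zeros((n_positions, d_model))
    pe[:, 0::2] = np.sin(angle[:, 0::2])
    pe[:, 1::2] = np.cos(angle[:, 1::2])
    return pe


def _layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return gamma * (xc / ((var + eps) ** 0.5)) + beta


def _dropout(x: Tensor, p: float, train: bool, rng: np.random.Generator | None) -> Tensor:
    if not train or p <= 0.0:
        return x
    if rng is None:
        raise ValueError("training-mode forward needs an rng for dropout")
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(mask)


# ---------------------------------------------------------------------------
# standalone building blocks (also exercised directly by the tests)


def input_projection(pair_signals: Tensor, wp: Tensor, bp: Tensor) -> Tensor:
    """Map each (HbO_t, HbR_t) 2-vector into d_model dimensions.

    ``pair_signals`` is (..., Cp, T, 2); the projection is shared across
    pairs and time points.
    """
    if pair_signals.shape[-1] != 2:
        raise StructuralError("pair_signals must end in an (HbO, HbR) axis of size 2")
    return pair_signals @ wp + bp


def temporal_pool(z: Tensor) -> Tensor:
    """Average over the time axis of a (..., T, d_model) encoding."""
    return z.mean(axis=-2)


def graph_attention(pair_feats: Tensor, w_alpha: Tensor) -> Tensor:
    """Softmax attention over channel pairs from (s, Sd, RFSMD).

    ``pair_feats`` is (..., Cp, 3); returns (..., Cp) on the simplex.
    """
    logits = (pair_feats @ w_alpha).reshape(pair_feats.shape[:-1])
    return softmax(logits, axis=-1)


def build_pair_sequence(f_t: Tensor, f_proj: Tensor) -> Tensor:
    """Concatenate the projected fused feature onto every pair's pooled
    temporal vector: E_i = [F_t[i]; f_proj], shape (B, Cp, 2·d_model)."""
    b, cp = f_t.shape[0], f_t.shape[1]
    d = f_proj.shape[-1]
    f_proj_seq = f_proj.reshape(b, 1, d) * Tensor(np.ones((1, cp, 1)))
    return concat([f_t, f_proj_seq], axis=-1)


def attention_lstm_cell(
    h_prev: Tensor,
    c_prev: Tensor,
    e_i: Tensor,
    alpha_i: Tensor,
    params: dict[str, Tensor],
) -> tuple[Tensor, Tensor]:
    """One LSTM step whose every gate sees the attention weight.

    The gate input is ``[h_prev, E_i, α_i]``; with all-zero parameters the
    gates sit at 0.5 and the candidate at 0, so ``c = 0.5·c_prev`` and
    ``h = 0.5·tanh(c)``.
    """
    z = concat([h_prev, e_i, alpha_i], axis=-1)
    g = (z @ params["Wg"] + params["bf"]).sigmoid()
    i = (z @ params["Wi"] + params["bi"]).sigmoid()
    c_tilde = (z @ params["Wc"] + params["bc"]).tanh()
    c = g * c_prev + i * c_tilde
    o = (z @ params["Wo"] + params["bo"]).sigmoid()
    h = o * c.tanh()
    return h, c


def bilstm_sequence(
    e_seq: Tensor,
    alpha: Tensor,
    fwd: dict[str, Tensor],
    bwd: dict[str, Tensor],
    hidden: int,
    alpha_mode: str = "scalar_per_step",
    output: str = "last",
) -> Tensor:
    """Run the attention-modulated Bi-LSTM over the pair sequence.

    ``e_seq`` is (B, Cp, 2·d_model), ``alpha`` is (B, Cp).  Both directions
    start from zero states; the result concatenates the final forward and
    final backward hidden states (or, with ``output="mean_pooled"``, the
    per-step concatenations averaged over steps).
    """
    b, n_steps = e_seq.shape[0], e_seq.shape[1]
    zeros = Tensor(np.zeros((b, hidden)))

    def run(order, params):
        h, c = zeros, zeros
        states = []
        for i in order:
            a_i = alpha[:, i : i + 1] if alpha_mode == "scalar_per_step" else alpha
            h, c = attention_lstm_cell(h, c, e_seq[:, i, :], a_i, params)
            states.append(h)
        return h, states

    h_f, states_f = run(range(n_steps), fwd)
    h_b, states_b = run(range(n_steps - 1, -1, -1), bwd)
    if output == "last":
        return concat([h_f, h_b], axis=-1)
    per_step = [
        concat([hf, hb], axis=-1) for hf, hb in zip(states_f, reversed(states_b))
    ]
    total = per_step[0]
    for s in per_step[1:]:
        total = total + s
    return total * (1.0 / n_steps)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean negative log-likelihood of integer labels under softmax logits."""
    lp = log_softmax(logits, axis=-1)
    picked = lp[np.arange(len(labels)), np.asarray(labels, dtype=int)]
    return -picked.mean()


def pairs_from_epochs(epochs: np.ndarray, pair_rows: np.ndarray) -> np.ndarray:
    """Arrange (N, C, T) epochs as (N, Cp, T, 2) with an (HbO, HbR) axis."""
    return np.stack(
        [epochs[:, pair_rows[:, 0], :], epochs[:, pair_rows[:, 1], :]], axis=-1
    )


# ---------------------------------------------------------------------------
# the full network


class GraphTemporalNet:
    """The full topology-gated temporal classifier.

    Parameters
    ----------
    n_pairs, n_timepoints
        Geometry of the input epochs (Cp pairs, T samples).
    feature_dim
        Dimension D of the fused vector ``f3`` (= 2·Cp·T + 3·Cp + 1).
    config
        :class:`ModelConfig`.
    seed
        Seeds parameter initialization (and nothing else).
    variant
        Ablation variant: ``full``, ``no_graph_features`` (f2 and e zeroed
        everywhere, attention degenerates to uniform), ``no_GAM`` (α fixed
        at 1/Cp), ``no_BiLSTM`` (mean-pooled pair sequence fed straight to
        the classifier), or ``no_GAM_no_BiLSTM``.
    """

    def __init__(
        self,
        n_pairs: int,
        n_timepoints: int,
        feature_dim: int,
        config: ModelConfig | None = None,
        seed: int = 0,
        variant: str = "full",
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown variant {variant!r}")
        cfg = config or ModelConfig()
        self.config = cfg
        self.variant = variant
        self.n_pairs = n_pairs
        self.n_timepoints = n_timepoints
        self.feature_dim = feature_dim
        self.seed = seed
        self.use_lstm = variant not in ("no_BiLSTM", "no_GAM_no_BiLSTM")
        self.use_gam = variant in ("full", "no_BiLSTM")
        self.last_attention: np.ndarray | None = None

        rng = np.random.default_rng(seed)
        d, h = cfg.d_model, cfg.lstm_hidden
        p: dict[str, Tensor] = {}

        p["Wp"] = Tensor(_xavier(rng, 2, d))
        p["bp"] = Tensor(np.zeros(d))
        for layer in range(cfg.n_encoder_layers):
            pre = f"enc{layer}_"
            for name in ("Wq", "Wk", "Wv", "Wo"):
                p[pre + name] = Tensor(_xavier(rng, d, d))
                p[pre + name.replace("W", "b")] = Tensor(np.zeros(d))
            p[pre + "W1"] = Tensor(_xavier(rng, d, cfg.ffn_dim))
            p[pre + "b1"] = Tensor(np.zeros(cfg.ffn_dim))
            p[pre + "W2"] = Tensor(_xavier(rng, cfg.ffn_dim, d))
            p[pre + "b2"] = Tensor(np.zeros(d))
            for ln in ("ln1", "ln2"):
                p[pre + ln + "_g"] = Tensor(np.ones(d))
                p[pre + ln + "_b"] = Tensor(np.zeros(d))
        p["Ww"] = Tensor(_xavier(rng, feature_dim, d))
        p["bw"] = Tensor(np.zeros(d))
        p["Walpha"] = Tensor(_xavier(rng, 3, 1))

        alpha_dim = 1 if cfg.alpha_mode == "scalar_per_step" else n_pairs
        gate_in = h + 2 * d + alpha_dim
        for direction in ("fwd", "bwd"):
            for gate, bias in (("Wg", "bf"), ("Wi", "bi"), ("Wc", "bc"), ("Wo", "bo")):
                p[f"{direction}_{gate}"] = Tensor(_lstm_uniform(rng, gate_in, h))
                p[f"{direction}_{bias}"] = Tensor(np.zeros(h))

        seq_out = 2 * h if self.use_lstm else 2 * d
        cls_in = feature_dim + seq_out
        p["W1"] = Tensor(_xavier(rng, cls_in, cfg.mlp_hidden))
        p["b1"] = Tensor(np.zeros(cfg.mlp_hidden))
        p["W2"] = Tensor(_xavier(rng, cfg.mlp_hidden, cfg.n_classes))
        p["b2"] = Tensor(np.zeros(cfg.n_classes))
        self.params = p

        self._posenc = sinusoidal_positional_encoding(n_timepoints, d)
        # slices of f3 blocks: f1 = C·T raw samples, f2 = 3·Cp pair features, e
        c_t = 2 * n_pairs * n_timepoints
        self._f2_slice = slice(c_t, c_t + 3 * n_pairs)
        self._e_slice = slice(c_t + 3 * n_pairs, c_t + 3 * n_pairs + 1)

    # -- parameter plumbing ---------------------------------------------
    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=float).copy()

    def save(self, path) -> None:
        """Single-file checkpoint: parameter tensors + config + seed."""
        meta = json.dumps(
            {
                "config": asdict(self.config),
                "variant": self.variant,
                "n_pairs": self.n_pairs,
                "n_timepoints": self.n_timepoints,
                "feature_dim": self.feature_dim,
                "seed": self.seed,
            }
        )
        buf = {k: v.data for k, v in self.params.items()}
        np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **buf)

    @classmethod
    def load(cls, path) -> "GraphTemporalNet":
        with np.load(path) as archive:
            meta = json.loads(bytes(archive["__meta__"]).decode())
            state = {k: archive[k] for k in archive.files if k != "__meta__"}
        model = cls(
            n_pairs=meta["n_pairs"],
            n_timepoints=meta["n_timepoints"],
            feature_dim=meta["feature_dim"],
            config=ModelConfig(**meta["config"]),
            seed=meta["seed"],
            variant=meta["variant"],
        )
        model.load_state_dict(state)
        return model

    # -- forward pieces --------------------------------------------------
    def _encode(self, z: Tensor, train: bool, rng) -> Tensor:
        """Transformer encoder along time, weights shared across pairs."""
        cfg = self.config
        b_cp = z.shape[0]
        t, d = self.n_timepoints, cfg.d_model
        heads, dk = cfg.n_heads, d // cfg.n_heads
        x = z + Tensor(self._posenc)
        for layer in range(cfg.n_encoder_layers):
            p = {k[len(f"enc{layer}_") :]: v for k, v in self.params.items()
                 if k.startswith(f"enc{layer}_")}
            q = (x @ p["Wq"] + p["bq"]).reshape(b_cp, t, heads, dk).transpose(0, 2, 1, 3)
            k = (x @ p["Wk"] + p["bk"]).reshape(b_cp, t, heads, dk).transpose(0, 2, 1, 3)
            v = (x @ p["Wv"] + p["bv"]).reshape(b_cp, t, heads, dk).transpose(0, 2, 1, 3)
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dk))
            attn = softmax(scores, axis=-1)
            self.last_attention = attn.data
            ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(b_cp, t, d)
            x = _layer_norm(x + (ctx @ p["Wo"] + p["bo"]), p["ln1_g"], p["ln1_b"])
            ffn = ((x @ p["W1"] + p["b1"]).relu()) @ p["W2"] + p["b2"]
            x = _layer_norm(x + ffn, p["ln2_g"], p["ln2_b"])
        return x

    def _strip_graph_blocks(self, pair_feats: np.ndarray, f3: np.ndarray):
        pair_feats = np.zeros_like(pair_feats)
        f3 = f3.copy()
        f3[:, self._f2_slice] = 0.0
        f3[:, self._e_slice] = 0.0
        return pair_feats, f3

    def forward(
        self,
        pair_signals: np.ndarray,
        pair_feats: np.ndarray,
        f3: np.ndarray,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> Tensor:
        """Return class logits, shape (B, K).

        ``pair_signals`` is (B, Cp, T, 2), ``pair_feats`` (B, Cp, 3) and
        ``f3`` (B, D).  Deterministic in eval mode (``train=False``).
        """
        cfg = self.config
        pair_signals = np.asarray(pair_signals, dtype=float)
        pair_feats = np.asarray(pair_feats, dtype=float)
        f3 = np.asarray(f3, dtype=float)
        if pair_signals.ndim != 4 or pair_signals.shape[3] != 2:
            raise StructuralError("pair_signals must be (B, Cp, T, 2)")
        if f3.shape[1] != self.feature_dim:
            raise StructuralError(
                f"f3 has dimension {f3.shape[1]}, expected {self.feature_dim}"
            )
        if self.variant == "no_graph_features":
            pair_feats, f3 = self._strip_graph_blocks(pair_feats, f3)
        b, cp = pair_signals.shape[:2]

        z0 = input_projection(Tensor(pair_signals), self.params["Wp"], self.params["bp"])
        z0_flat = z0.reshape(b * cp, self.n_timepoints, cfg.d_model)
        z1 = self._encode(z0_flat, train, rng)
        f_t = temporal_pool(z1).reshape(b, cp, cfg.d_model)

        f3_t = Tensor(f3)
        f_proj = f3_t @ self.params["Ww"] + self.params["bw"]
        f_proj = _dropout(f_proj, cfg.dropout_temporal, train, rng)
        e_seq = build_pair_sequence(f_t, f_proj)

        if self.use_gam:
            alpha = graph_attention(Tensor(pair_feats), self.params["Walpha"])
        else:
            alpha = Tensor(np.full((b, cp), 1.0 / cp))
        self.last_alpha = alpha.data

        if self.use_lstm:
            fwd = {k: self.params[f"fwd_{k}"] for k in ("Wg", "Wi", "Wc", "Wo")}
            fwd.update({k: self.params[f"fwd_{k}"] for k in ("bf", "bi", "bc", "bo")})
            bwd = {k: self.params[f"bwd_{k}"] for k in ("Wg", "Wi", "Wc", "Wo")}
            bwd.update({k: self.params[f"bwd_{k}"] for k in ("bf", "bi", "bc", "bo")})
            h_final = bilstm_sequence(
                e_seq, alpha, fwd, bwd, cfg.lstm_hidden,
                alpha_mode=cfg.alpha_mode, output=cfg.lstm_output,
            )
        else:
            h_final = e_seq.mean(axis=1)

        z = concat([f3_t, h_final], axis=-1)
        f_cls = z @ self.params["W1"] + self.params["b1"]
        f_act = _dropout(f_cls.relu(), cfg.dropout_mlp, train, rng)
        return f_act @ self.params["W2"] + self.params["b2"]

    def predict_proba(self, pair_signals, pair_feats, f3) -> np.ndarray:
        """Class probabilities ŷ on the K-simplex (eval mode)."""
        logits = self.forward(pair_signals, pair_feats, f3, train=False)
        return softmax(logits, axis=-1).data

    def predict(self, pair_signals, pair_feats, f3) -> np.ndarray:
        return np.argmax(self.predict_proba(pair_signals, pair_feats, f3), axis=1)
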