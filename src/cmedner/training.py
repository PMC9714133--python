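"""End-to-end model assembly, training loop and prediction.

Pipeline per batch: character embedding -> parallel BiLSTM and CNN feature
extraction -> project-and-add fusion -> multihead self-attention -> linear
emission projection -> linear-chain CRF.  Training minimizes the CRF
negative log-likelihood with AdamW; decoding is Viterbi restricted to real
character positions.

Defaults follow the reference configuration for this architecture on
Chinese clinical corpora: LSTM hidden width 100, batch size 32, learning
rate 5e-5, maximum sentence length 128, dropout keep-probability 0.9 and
50 epochs.  The 5e-5 rate suits fine-tuning on top of a pretrained
contextual encoder; self-contained runs with the small fallback embedding
table train well at 1e-3.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .autodiff import AdamW, Tensor, clip_grad_norm, no_grad
from .corpus import LabeledSequence, TagScheme, tags_to_entities
from .crf import CRFParams, nll_loss, viterbi_decode
from .encoder import FallbackEncoder, PretrainedEncoderAdapter, encode, make_fallback_encoder
from .layers import (
    CNNParams,
    FusionParams,
    LSTMParams,
    MHAParams,
    bilstm_encode,
    cnn_encode,
    dropout,
    fuse,
    multihead_attention,
)
from .metrics import entity_prf

__all__ = ["ModelConfig", "Model", "train", "predict", "save_checkpoint", "load_checkpoint"]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    """Hyperparameters of the hybrid model and its training loop."""

    entity_types: tuple[str, ...]
    lstm_dim: int = 100
    batch_size: int = 32
    learning_rate: float = 5e-5
    max_len: int = 128
    dropout_keep: float = 0.9
    epochs: int = 50
    heads: int = 4
    kernel_widths: tuple[int, ...] = (1, 3, 5)
    cnn_channels: int = 100
    fused_dim: int | None = None  # z; defaults to 2 * lstm_dim
    encoder_mode: str = "fallback"
    encoder_dim: int = 128
    seed: int = 0
    weight_decay: float = 0.01
    grad_clip: float | None = None  # off by default
    lr_schedule: str | None = None  # None or "linear"; off by default

    def __post_init__(self):
        self.entity_types = tuple(self.entity_types)
        self.kernel_widths = tuple(int(w) for w in self.kernel_widths)
        if self.fused_dim is None:
            self.fused_dim = 2 * self.lstm_dim
        for name in ("lstm_dim", "batch_size", "epochs", "heads", "cnn_channels",
                     "fused_dim", "encoder_dim"):
            if getattr(self, name) < (0 if name == "epochs" else 1):
                raise ValueError(f"{name} must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 < self.dropout_keep <= 1.0:
            raise ValueError("dropout_keep must be in (0, 1]")
        if self.max_len < 3:
            raise ValueError("max_len must be at least 3")
        if self.fused_dim % self.heads != 0:
            raise ValueError(
                f"fused width {self.fused_dim} must be divisible by {self.heads} heads"
            )
        if self.encoder_mode not in ("fallback", "pretrained-adapter"):
            raise ValueError(f"unknown encoder_mode {self.encoder_mode!r}")
        if self.lr_schedule not in (None, "linear"):
            raise ValueError(f"unknown lr_schedule {self.lr_schedule!r}")

    @property
    def scheme(self) -> TagScheme:
        return TagScheme(self.entity_types)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["entity_types"] = list(self.entity_types)
        d["kernel_widths"] = list(self.kernel_widths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


class Model:
    """All trainable parameters of the hybrid network, wired end to end."""

    def __init__(self, cfg: ModelConfig, encoder, rng: np.random.Generator):
        scheme = cfg.scheme
        t = encoder.dim
        z = cfg.fused_dim
        L = scheme.n_labels
        self.cfg = cfg
        self.scheme = scheme
        self.encoder = encoder
        self.lstm_fwd = LSTMParams.init(t, cfg.lstm_dim, rng)
        self.lstm_bwd = LSTMParams.init(t, cfg.lstm_dim, rng)
        self.cnn = CNNParams.init(t, cfg.kernel_widths, cfg.cnn_channels, rng)
        self.fusion = FusionParams.init(2 * cfg.lstm_dim, cfg.cnn_channels, z, rng)
        self.mha = MHAParams.init(z, cfg.heads, rng)
        self.emit_w = Tensor(rng.normal(0.0, 1.0 / np.sqrt(z), (z, L)), requires_grad=True)
        self.emit_b = Tensor(np.zeros(L), requires_grad=True)
        self.crf = CRFParams(L)

    # ------------------------------------------------------------------
    def named_parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        if isinstance(self.encoder, FallbackEncoder):
            params["encoder.table"] = self.encoder.table
        for prefix, lstm in (("lstm_fwd", self.lstm_fwd), ("lstm_bwd", self.lstm_bwd)):
            for gate in ("f", "i", "c", "o"):
                params[f"{prefix}.w_{gate}"] = getattr(lstm, f"w_{gate}")
                params[f"{prefix}.u_{gate}"] = getattr(lstm, f"u_{gate}")
                params[f"{prefix}.b_{gate}"] = getattr(lstm, f"b_{gate}")
        for i, k in enumerate(self.cnn.kernels):
            params[f"cnn.k{i}.weight"] = k.weight
            params[f"cnn.k{i}.bias"] = k.bias
        params["fusion.proj_b"] = self.fusion.proj_b
        params["fusion.proj_c"] = self.fusion.proj_c
        params["fusion.bias"] = self.fusion.bias
        for i in range(self.mha.h):
            params[f"mha.w_q{i}"] = self.mha.w_q[i]
            params[f"mha.w_k{i}"] = self.mha.w_k[i]
            params[f"mha.w_v{i}"] = self.mha.w_v[i]
        params["mha.w_o"] = self.mha.w_o
        params["emit.w"] = self.emit_w
        params["emit.b"] = self.emit_b
        params["crf.transitions"] = self.crf.transitions
        return params

    def parameters(self) -> list[Tensor]:
        return [p for p in self.named_parameters().values() if p.requires_grad]

    def snapshot(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters().items()}

    def restore(self, state: dict[str, np.ndarray]) -> None:
        for name, p in self.named_parameters().items():
            p.data = state[name].copy()

    # ------------------------------------------------------------------
    def forward(
        self,
        batch_chars: Sequence[Sequence[str]],
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[Tensor, np.ndarray]:
        """Emissions for the character positions of a batch.

        Returns ``(emissions, char_mask)`` where emissions is
        ``(B, m-2, L)`` covering the content region between CLS and SEP.
        Padding is tight per batch (up to ``cfg.max_len``).
        """
        longest = max((len(s) for s in batch_chars), default=0)
        width = min(self.cfg.max_len, longest + 2)
        width = max(width, 3)
        emb, char_mask, valid_mask = encode(batch_chars, self.encoder, width)
        vb = bilstm_encode(emb, valid_mask, self.lstm_fwd, self.lstm_bwd)
        vc = cnn_encode(emb, valid_mask, self.cnn)
        x = fuse(vb, vc, self.fusion).values
        if training and self.cfg.dropout_keep < 1.0:
            x = dropout(x, self.cfg.dropout_keep, rng)
        # Residual connection around the attention stage: near-uniform
        # attention at initialization would otherwise average away
        # position-specific features and stall optimization.
        y = x + multihead_attention(x, valid_mask, self.mha).values
        if training and self.cfg.dropout_keep < 1.0:
            y = dropout(y, self.cfg.dropout_keep, rng)
        em_all = (y @ self.emit_w) + self.emit_b  # (B, width, L)
        emissions = em_all[:, 1 : width - 1, :]
        return emissions, char_mask[:, 1 : width - 1]


def _tag_matrix(
    batch: Sequence[LabeledSequence], scheme: TagScheme, n_positions: int, max_chars: int
) -> np.ndarray:
    tags = np.zeros((len(batch), n_positions), dtype=np.intp)
    for b, seq in enumerate(batch):
        idxs = [scheme.index(t) for t in seq.tags[:max_chars]]
        tags[b, : len(idxs)] = idxs
    return tags


def train(
    corpus_train: Sequence[LabeledSequence],
    corpus_dev: Sequence[LabeledSequence],
    cfg: ModelConfig,
    encoder=None,
) -> tuple[Model, list[dict]]:
    """Train the hybrid model, returning the best-dev-F1 checkpoint.

    Shuffling, initialization and dropout all derive from ``cfg.seed``, so
    the per-epoch metric log is reproducible bit for bit on one platform.
    When a dev corpus is given, the parameters giving the best dev
    entity-level micro-F1 are restored before returning; otherwise the
    final parameters are kept.  ``epochs == 0`` returns the freshly
    initialized model with an empty log.
    """
    corpus_train = [s for s in corpus_train if len(s) > 0]
    if not corpus_train:
        raise ValueError("training corpus is empty")
    scheme = cfg.scheme
    for seq in list(corpus_train) + list(corpus_dev):
        seq.validate(scheme)

    rng = np.random.default_rng(cfg.seed)
    if encoder is None:
        if cfg.encoder_mode != "fallback":
            raise ValueError("pretrained-adapter mode requires an explicit encoder")
        encoder = make_fallback_encoder(corpus_train, cfg.encoder_dim, seed=cfg.seed)
    model = Model(cfg, encoder, rng)
    opt = AdamW(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    n = len(corpus_train)
    max_chars = cfg.max_len - 2
    log: list[dict] = []
    best_f1 = -1.0
    best_state: dict[str, np.ndarray] | None = None
    total_steps = max(1, cfg.epochs * ((n + cfg.batch_size - 1) // cfg.batch_size))
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for lo in range(0, n, cfg.batch_size):
            batch = [corpus_train[i] for i in order[lo : lo + cfg.batch_size]]
            chars = [seq.chars for seq in batch]
            emissions, cmask = model.forward(chars, training=True, rng=rng)
            tags = _tag_matrix(batch, scheme, emissions.shape[1], max_chars)
            loss = nll_loss(emissions, model.crf, tags, cmask, reduction="mean")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                clip_grad_norm(model.parameters(), cfg.grad_clip)
            if cfg.lr_schedule == "linear":
                opt.lr = cfg.learning_rate * (1.0 - step / total_steps)
            opt.step()
            step += 1
            epoch_loss += loss.item()
            n_batches += 1
        entry = {"epoch": epoch, "train_loss": epoch_loss / max(1, n_batches)}
        if corpus_dev:
            preds = [tags_ for tags_, _ in predict(model, [s.chars for s in corpus_dev])]
            entry["dev_f1"] = entity_prf(corpus_dev, preds, scheme).micro.f1
            if entry["dev_f1"] > best_f1:
                best_f1 = entry["dev_f1"]
                best_state = model.snapshot()
        log.append(entry)
    if best_state is not None:
        model.restore(best_state)
    return model, log


def predict(
    model: Model, sentences: Sequence[Sequence[str]]
) -> list[tuple[list[str], list]]:
    """Viterbi-decode tag sequences and entity mentions for raw sentences.

    Dropout is disabled; decoding covers only real character positions.
    Characters beyond ``max_len - 2`` are tagged ``O`` (the model never saw
    them), keeping output length equal to input length.  An empty sentence
    yields empty outputs.
    """
    results: list[tuple[list[str], list] | None] = [None] * len(sentences)
    live = [i for i, s in enumerate(sentences) if len(s) > 0]
    for i, s in enumerate(sentences):
        if len(s) == 0:
            results[i] = ([], [])
    bs = model.cfg.batch_size
    for lo in range(0, len(live), bs):
        idxs = live[lo : lo + bs]
        chars = [list(sentences[i]) for i in idxs]
        with no_grad():
            emissions, cmask = model.forward(chars, training=False)
        for row, i in enumerate(idxs):
            n_i = int(cmask[row].sum())
            P = emissions.data[row, :n_i]
            path, _ = viterbi_decode(P, model.crf)
            tags = [model.scheme.label(j) for j in path]
            tags += ["O"] * (len(chars[row]) - len(tags))  # truncated overflow
            seq = LabeledSequence(chars[row], tags)
            results[i] = (tags, tags_to_entities(seq))
    return results  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: Model, path) -> None:
    """Serialize parameters + config (+ fallback vocabulary) to one archive.

    The archive is a NumPy ``.npz`` with a JSON metadata entry; it is
    self-describing and versioned.  Adapter-mode models store no encoder
    weights — the adapter must be supplied again at load time.
    """
    meta = {
        "version": CHECKPOINT_VERSION,
        "config": model.cfg.to_dict(),
        "encoder_mode": model.encoder.mode,
    }
    if isinstance(model.encoder, FallbackEncoder):
        meta["vocab"] = model.encoder.ordered_chars()
    arrays = {name.replace(".", "__"): p.data for name, p in model.named_parameters().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode("utf-8"), dtype=np.uint8),
             **arrays)


def load_checkpoint(path, adapter: PretrainedEncoderAdapter | None = None) -> Model:
    """Rebuild a model from :func:`save_checkpoint` output."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode("utf-8"))
        arrays = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta["version"] != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['version']}")
    cfg = ModelConfig.from_dict(meta["config"])
    rng = np.random.default_rng(cfg.seed)
    if meta["encoder_mode"] == "fallback":
        vocab = {ch: i + 4 for i, ch in enumerate(meta["vocab"])}
        table = Tensor(arrays["encoder__table"], requires_grad=True)
        enc = FallbackEncoder(vocab, table)
    else:
        if adapter is None:
            raise ValueError("checkpoint was trained with an adapter; pass adapter=")
        enc = adapter
    model = Model(cfg, enc, rng)
    state = {k.replace("__", "."): v for k, v in arrays.items()}
    model.restore(state)
    return model
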