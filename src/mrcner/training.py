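"""Losses, the fine-tuning loop, and inference drivers.

Both heads are trained jointly; the objective is the unweighted sum of the
start-head and end-head losses, each a mean over context positions.  Three
losses are available: focal, plain cross-entropy, and label smoothing.
Optimization is AdamW with 10% linear warmup followed by linear decay;
everything is deterministic given the config seed and encoder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import evaluation
from .corpus_io import EntitySpan, LabeledCorpus
from .mrc_dataset import (
    DEFAULT_MAX_LEN,
    DEFAULT_STRIDE,
    EncodedExample,
    TokenizerContract,
    WhitespaceTokenizer,
    build_triples,
    decode_predictions,
    encode_corpus,
)
from .query_bank import QuerySet
from .span_model import (
    BASE,
    CONDITIONED,
    HeadParams,
    forward,
    init_head_params,
    softmax_vjp,
)

_EPS = 1e-12

LOSSES = ("focal", "cross_entropy", "label_smoothing")


class DivergenceError(RuntimeError):
    pass


@dataclass
class TrainConfig:
    """Hyper-parameters; the defaults mirror the published fine-tuning setup
    (seq_len 512, batch size 8, learning rate 2e-5, focal loss)."""

    seq_len: int = 512
    batch_size: int = 8
    learning_rate: float = 2e-5
    loss: str = "focal"
    focal_gamma: float = 2.0
    focal_alpha: float | None = 0.25
    smoothing_eps: float = 0.1
    epochs: int = 20
    seed: int = 0
    runs: int = 3
    head_mode: str = CONDITIONED
    warmup_frac: float = 0.1
    weight_decay: float = 0.01
    stride: int = DEFAULT_STRIDE
    early_stop_f1: float | None = None  # stop once dev F1 reaches this

    def __post_init__(self) -> None:
        if self.loss not in LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}; expected one of {LOSSES}")
        if self.seq_len < 4 or self.batch_size < 1 or self.epochs < 1 or self.runs < 1:
            raise ValueError("counts must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.smoothing_eps < 1.0:
            raise ValueError("smoothing_eps must lie in [0, 1)")
        if self.focal_gamma < 0:
            raise ValueError("focal_gamma must be non-negative")
        if self.head_mode not in (CONDITIONED, BASE):
            raise ValueError(f"unknown head_mode {self.head_mode!r}")


@dataclass(frozen=True)
class LossValue:
    start_part: float
    end_part: float

    @property
    def total(self) -> float:
        return self.start_part + self.end_part


# ---------------------------------------------------------------------------
# Losses (scalar value + gradient wrt the probability matrix)
# ---------------------------------------------------------------------------


def _masked(probs, labels, mask):
    mask = np.asarray(mask, dtype=bool)
    idx = np.flatnonzero(mask)
    y = np.asarray(labels, dtype=np.int64)[idx]
    p_t = np.clip(probs[idx, y], _EPS, 1.0)
    p_o = np.clip(probs[idx, 1 - y], _EPS, 1.0)
    return idx, y, p_t, p_o


def _focal(probs, labels, mask, gamma, alpha, want_grad):
    idx, y, p_t, _ = _masked(probs, labels, mask)
    m = len(idx)
    if m == 0:
        return 0.0, np.zeros_like(probs) if want_grad else None
    alpha_t = np.ones(m) if alpha is None else np.where(y == 1, alpha, 1.0 - alpha)
    u = np.clip(1.0 - p_t, _EPS, 1.0)
    value = float(np.mean(-alpha_t * u**gamma * np.log(p_t)))
    if not want_grad:
        return value, None
    dprobs = np.zeros_like(probs)
    term1 = gamma * u ** (gamma - 1.0) * np.log(p_t) if gamma > 0 else 0.0
    dprobs[idx, y] = alpha_t * (term1 - u**gamma / p_t) / m
    return value, dprobs


def _cross_entropy(probs, labels, mask, eps, want_grad):
    idx, y, p_t, p_o = _masked(probs, labels, mask)
    m = len(idx)
    if m == 0:
        return 0.0, np.zeros_like(probs) if want_grad else None
    q_t, q_o = 1.0 - eps, eps
    value = float(np.mean(-(q_t * np.log(p_t) + q_o * np.log(p_o))))
    if not want_grad:
        return value, None
    dprobs = np.zeros_like(probs)
    dprobs[idx, y] = -q_t / p_t / m
    dprobs[idx, 1 - y] += -q_o / p_o / m
    return value, dprobs


def focal_loss(probs, labels, mask, gamma: float = 2.0, alpha: float | None = None) -> float:
    """Mean over masked positions of ``-alpha_t (1 - p_t)^gamma log p_t``.

    ``alpha=None`` weights both classes 1 (uniform); a float ``a`` weights
    the positive class ``a`` and the negative class ``1 - a``.
    """
    value, _ = _focal(probs, labels, mask, gamma, alpha, want_grad=False)
    return value


def cross_entropy_loss(probs, labels, mask, smoothing_eps: float = 0.0) -> float:
    """Mean masked NLL against labels softened to a (1-eps, eps) split."""
    if not 0.0 <= smoothing_eps < 1.0:
        raise ValueError("smoothing_eps must lie in [0, 1)")
    value, _ = _cross_entropy(probs, labels, mask, smoothing_eps, want_grad=False)
    return value


def _loss_and_grad(probs, labels, mask, cfg: TrainConfig):
    if cfg.loss == "focal":
        return _focal(probs, labels, mask, cfg.focal_gamma, cfg.focal_alpha, True)
    eps = cfg.smoothing_eps if cfg.loss == "label_smoothing" else 0.0
    return _cross_entropy(probs, labels, mask, eps, True)


# ---------------------------------------------------------------------------
# Per-example forward/backward
# ---------------------------------------------------------------------------


def example_loss_and_grads(
    example: EncodedExample, encoder, head: HeadParams, cfg: TrainConfig
) -> tuple[LossValue, dict[str, np.ndarray]]:
    """Joint loss and analytic gradients for every trainable array.

    The gradient flows through the conditioning path (the start probabilities
    fed to the end head), not only through the start loss.
    """
    from .span_model import predict_end, predict_start  # avoid cycle at import

    L, cache = encoder.forward(example.pieces)
    d = L.shape[1]
    P_s = predict_start(L, head)
    conditioned = head.mode == CONDITIONED
    P_e = predict_end(L, P_s if conditioned else None, head)

    loss_s, dPs_loss = _loss_and_grad(P_s, example.start_labels, example.context_mask, cfg)
    loss_e, dPe_loss = _loss_and_grad(P_e, example.end_labels, example.context_mask, cfg)

    dSe = softmax_vjp(P_e, dPe_loss)
    Z = np.concatenate([L, P_s], axis=1) if conditioned else L
    gQe = Z.T @ dSe
    dZ = dSe @ head.Q_end.T
    dL = dZ[:, :d].copy()
    dPs = dPs_loss + (dZ[:, d:] if conditioned else 0.0)
    dSs = softmax_vjp(P_s, dPs)
    gQs = L.T @ dSs
    dL += dSs @ head.Q_start.T

    grads = {"head.Q_start": gQs, "head.Q_end": gQe}
    for k, g in encoder.backward(cache, dL).items():
        grads[f"enc.{k}"] = g
    return LossValue(loss_s, loss_e), grads


# ---------------------------------------------------------------------------
# Optimizer and schedule
# ---------------------------------------------------------------------------


class AdamW:
    """Decoupled-weight-decay Adam over a dict of parameter arrays
    (updated in place); bias-like 1-D arrays are not decayed."""

    def __init__(self, params: dict[str, np.ndarray], weight_decay: float = 0.01,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.weight_decay = weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray], lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)
            if p.ndim > 1 and self.weight_decay:
                p -= lr * self.weight_decay * p


def lr_at(step: int, total_steps: int, base_lr: float, warmup_frac: float) -> float:
    """Linear warmup over the first ``warmup_frac`` of steps, then linear
    decay to zero at ``total_steps``."""
    warm = max(1, int(round(total_steps * warmup_frac)))
    if step < warm:
        return base_lr * (step + 1) / warm
    if total_steps <= warm:
        return base_lr
    return base_lr * max(0.0, (total_steps - step) / (total_steps - warm))


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainedModel:
    encoder: object
    head: HeadParams
    cfg: TrainConfig


def gold_by_sentence(examples: Sequence[EncodedExample]) -> dict[str, set[EntitySpan]]:
    gold: dict[str, set[EntitySpan]] = {}
    for ex in examples:
        gold.setdefault(ex.sentence_id, set()).update(ex.answers)
    return gold


def evaluate_on_examples(
    examples: Sequence[EncodedExample], encoder, head: HeadParams
) -> evaluation.EvalReport:
    """Forward every example, decode to word space, micro-F1 vs the gold
    spans the examples carry (window-boundary drops count as FN)."""
    preds = [forward(ex, encoder, head)[2] for ex in examples]
    decoded = decode_predictions(examples, preds)
    gold = gold_by_sentence(examples)
    sids = sorted(gold)
    return evaluation.evaluate(
        [decoded.get(sid, set()) for sid in sids], [gold[sid] for sid in sids]
    )


def train_model(
    train_examples: Sequence[EncodedExample],
    encoder,
    cfg: TrainConfig,
    dev_examples: Sequence[EncodedExample] | None = None,
) -> tuple[TrainedModel, list[dict]]:
    """Fine-tune heads + encoder; returns the best-dev-F1 state and a
    per-epoch history of losses and dev scores.

    Without a dev split the final state is kept.  Non-finite losses abort
    with diagnostics rather than silently continuing.
    """
    if not train_examples:
        raise ValueError("training split is empty")
    head = init_head_params(encoder.d, cfg.head_mode, seed=cfg.seed)
    params: dict[str, np.ndarray] = {
        "head.Q_start": head.Q_start,
        "head.Q_end": head.Q_end,
    }
    for k, v in encoder.params.items():
        params[f"enc.{k}"] = v

    n = len(train_examples)
    n_batches = math.ceil(n / cfg.batch_size)
    total_steps = cfg.epochs * n_batches
    opt = AdamW(params, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)

    history: list[dict] = []
    best_f1 = -1.0
    best_state: dict[str, np.ndarray] | None = None
    step = 0
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for b in range(n_batches):
            batch = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            acc: dict[str, np.ndarray] | None = None
            for i in batch:
                lv, grads = example_loss_and_grads(
                    train_examples[int(i)], encoder, head, cfg
                )
                if not math.isfinite(lv.total):
                    raise DivergenceError(
                        f"non-finite loss at epoch {epoch}, step {step}: "
                        f"start={lv.start_part}, end={lv.end_part}"
                    )
                epoch_loss += lv.total
                if acc is None:
                    acc = grads
                else:
                    for k in acc:
                        acc[k] += grads[k]
            scale = 1.0 / len(batch)
            for k in acc:
                acc[k] *= scale
            opt.step(acc, lr_at(step, total_steps, cfg.learning_rate, cfg.warmup_frac))
            step += 1

        row = {"epoch": epoch, "train_loss": epoch_loss / n}
        if dev_examples is not None:
            report = evaluate_on_examples(dev_examples, encoder, head)
            row.update(
                dev_precision=report.precision,
                dev_recall=report.recall,
                dev_f1=report.f1,
            )
            if report.f1 > best_f1:
                best_f1 = report.f1
                best_state = {k: v.copy() for k, v in params.items()}
        history.append(row)
        if (
            cfg.early_stop_f1 is not None
            and dev_examples is not None
            and best_f1 >= cfg.early_stop_f1
        ):
            break

    if best_state is not None:
        for k, v in params.items():
            v[...] = best_state[k]
    return TrainedModel(encoder, head, cfg), history


def format_history(history: Sequence[dict]) -> str:
    cols = ["epoch", "train_loss", "dev_precision", "dev_recall", "dev_f1"]
    present = [c for c in cols if any(c in row for row in history)]
    lines = ["\t".join(present)]
    for row in history:
        lines.append(
            "\t".join(
                f"{row[c]:.4f}" if isinstance(row.get(c), float) else str(row.get(c, ""))
                for c in present
            )
        )
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Inference driver and checkpoints
# ---------------------------------------------------------------------------


def predict_corpus(
    corpus: LabeledCorpus,
    qs: QuerySet,
    model: TrainedModel,
    tok: TokenizerContract | None = None,
) -> list[set[EntitySpan]]:
    """Run the full MRC pipeline over a corpus; one typed span set per
    sentence, unioned over the per-type queries."""
    tok = tok or WhitespaceTokenizer()
    triples = build_triples(corpus, qs)
    examples = encode_corpus(
        triples, tok, max_len=model.cfg.seq_len, stride=model.cfg.stride
    )
    preds = [forward(ex, model.encoder, model.head)[2] for ex in examples]
    decoded = decode_predictions(examples, preds)
    return [decoded.get(s.sentence_id, set()) for s in corpus.sentences]


def save_checkpoint(path, model: TrainedModel) -> None:
    import json

    from .span_model import TinyEncoder

    enc = model.encoder
    if not isinstance(enc, TinyEncoder):
        raise NotImplementedError("only tiny-encoder checkpoints are supported")
    meta = {
        "d": enc.d,
        "emb_dim": enc.emb_dim,
        "vocab_size": enc.vocab_size,
        "head_mode": model.head.mode,
        "cfg": {k: v for k, v in vars(model.cfg).items()},
    }
    arrays = {f"enc_{k}": v for k, v in enc.params.items()}
    arrays["head_Q_start"] = model.head.Q_start
    arrays["head_Q_end"] = model.head.Q_end
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> TrainedModel:
    import json

    from .span_model import TinyEncoder

    data = np.load(path)
    meta = json.loads(bytes(data["meta"]).decode())
    enc = TinyEncoder(d=meta["d"], emb_dim=meta["emb_dim"], vocab_size=meta["vocab_size"])
    for k in list(enc.params):
        enc.params[k] = data[f"enc_{k}"].copy()
    head = HeadParams(
        data["head_Q_start"].copy(), data["head_Q_end"].copy(), meta["head_mode"]
    )
    cfg_fields = meta["cfg"]
    cfg = TrainConfig(**cfg_fields)
    return TrainedModel(enc, head, cfg)
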