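"""Span-extraction model: encoder contract, start/end heads, span matching.

The heads are two-class (N x 2) softmax classifiers over encoded positions.
The conditioned end head receives the start-head probability rows
concatenated to the encoder representation; the base variant does not.
Positions whose row argmax is the positive class form the start/end index
sets, and each end index pairs with the nearest preceding start index
(starts are reusable, which is what permits nested spans sharing a start).
"""

from __future__ import annotations

import hashlib
from bisect import bisect_right
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .mrc_dataset import CLS, SEP, EncodedExample

CONDITIONED = "conditioned"
BASE = "base"


class ContractError(ValueError):
    pass


def row_softmax(logits: np.ndarray) -> np.ndarray:
    """Numerically stable row-wise softmax; empty input passes through."""
    if logits.size == 0:
        return logits.reshape(logits.shape).astype(float)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_vjp(probs: np.ndarray, dprobs: np.ndarray) -> np.ndarray:
    """Row-wise vector-Jacobian product of softmax: grad wrt logits."""
    inner = (dprobs * probs).sum(axis=1, keepdims=True)
    return probs * (dprobs - inner)


@dataclass
class HeadParams:
    Q_start: np.ndarray  # d x 2
    Q_end: np.ndarray  # (d + 2) x 2 conditioned, d x 2 base
    mode: str = CONDITIONED

    def __post_init__(self) -> None:
        if self.mode not in (CONDITIONED, BASE):
            raise ContractError(f"unknown head mode {self.mode!r}")
        d = self.Q_start.shape[0]
        expected = d + 2 if self.mode == CONDITIONED else d
        if self.Q_start.shape[1] != 2 or self.Q_end.shape != (expected, 2):
            raise ContractError(
                f"head shapes inconsistent with mode {self.mode!r}: "
                f"Q_start {self.Q_start.shape}, Q_end {self.Q_end.shape}"
            )

    @property
    def d(self) -> int:
        return self.Q_start.shape[0]

    def copy(self) -> "HeadParams":
        return HeadParams(self.Q_start.copy(), self.Q_end.copy(), self.mode)


def init_head_params(d: int, mode: str = CONDITIONED, seed: int = 0) -> HeadParams:
    rng = np.random.default_rng(seed)
    d_end = d + 2 if mode == CONDITIONED else d
    return HeadParams(
        Q_start=rng.normal(0.0, 0.02, (d, 2)),
        Q_end=rng.normal(0.0, 0.02, (d_end, 2)),
        mode=mode,
    )


def predict_start(L: np.ndarray, params: HeadParams) -> np.ndarray:
    """K_start = row-softmax(L @ Q_start), an N x 2 row-stochastic matrix."""
    if L.ndim != 2 or L.shape[1] != params.d:
        raise ContractError(f"L shape {L.shape} incompatible with d={params.d}")
    return row_softmax(L @ params.Q_start)


def predict_end(
    L: np.ndarray, K_start: np.ndarray | None, params: HeadParams
) -> np.ndarray:
    """Conditioned: K_end = row-softmax([L ; K_start] @ Q_end); base drops
    the conditioning columns."""
    if L.ndim != 2 or L.shape[1] != params.d:
        raise ContractError(f"L shape {L.shape} incompatible with d={params.d}")
    if params.mode == BASE:
        return row_softmax(L @ params.Q_end)
    if K_start is None or K_start.shape != (L.shape[0], 2):
        raise ContractError("conditioned mode requires K_start of shape (N, 2)")
    Z = np.concatenate([L, K_start], axis=1)
    return row_softmax(Z @ params.Q_end)


def extract_index_set(K: np.ndarray, mask: np.ndarray) -> list[int]:
    """Positions inside the context whose row argmax is class 1.

    Exact 0.5/0.5 ties resolve to class 0 (excluded)."""
    mask = np.asarray(mask, dtype=bool)
    hits = (K[:, 1] > K[:, 0]) & mask
    return [int(i) for i in np.flatnonzero(hits)]


@dataclass(frozen=True)
class PredictedSpan:
    start: int
    end: int
    label: str
    score: float = 1.0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"span start {self.start} exceeds end {self.end}")


def match_spans(
    I_start: Sequence[int],
    I_end: Sequence[int],
    label: str,
    K_start: np.ndarray | None = None,
    K_end: np.ndarray | None = None,
) -> set[PredictedSpan]:
    """Pair each end index with the nearest start index at or before it.

    Starts may serve several ends (nested spans sharing a start); starts with
    no end at or after them are dropped.  Span score is the product of the
    two positive-class probabilities when the score matrices are given.
    """
    starts = sorted(I_start)
    spans: set[PredictedSpan] = set()
    for e in sorted(I_end):
        k = bisect_right(starts, e)
        if k == 0:
            continue
        s = starts[k - 1]
        score = 1.0
        if K_start is not None and K_end is not None:
            score = float(K_start[s, 1] * K_end[e, 1])
        spans.add(PredictedSpan(s, e, label, score))
    return spans


def forward(
    example: EncodedExample, encoder: "EncoderContract", params: HeadParams
) -> tuple[np.ndarray, np.ndarray, set[PredictedSpan]]:
    """Full pass: encode, score both heads, extract index sets over the
    context mask only, and match starts to ends."""
    L, _ = encoder.forward(example.pieces)
    K_start = predict_start(L, params)
    K_end = predict_end(L, K_start if params.mode == CONDITIONED else None, params)
    I_start = extract_index_set(K_start, example.context_mask)
    I_end = extract_index_set(K_end, example.context_mask)
    spans = match_spans(I_start, I_end, example.entity_type, K_start, K_end)
    return K_start, K_end, spans


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------


def piece_id(piece: str, vocab_size: int) -> int:
    """Stable hash bucket for a piece string (deterministic across runs)."""
    digest = hashlib.blake2b(piece.encode("utf-8"), digest_size=8).digest()
    return int.from_bytes(digest, "big") % vocab_size


class TinyEncoder:
    """Small trainable contextualizer for desk-scale runs.

    Hash-bucketed piece embeddings pass through a one-hidden-layer tanh map
    over a +/-1 token window.  The mean query embedding qbar (the segment
    between [CLS] and the first [SEP]) and the elementwise product
    emb_i * qbar are appended to every position's input, so context scores
    can depend on — and interact with — which entity type is being asked for.
    """

    name = "tiny"

    def __init__(
        self, d: int = 64, emb_dim: int = 32, vocab_size: int = 4096, seed: int = 0
    ):
        rng = np.random.default_rng(seed)
        self.d = d
        self.emb_dim = emb_dim
        self.vocab_size = vocab_size
        self.params: dict[str, np.ndarray] = {
            "E": rng.normal(0.0, 0.5, (vocab_size, emb_dim)),
            "W": rng.normal(0.0, np.sqrt(1.0 / (5 * emb_dim)), (5 * emb_dim, d)),
            "b": np.zeros(d),
        }

    def piece_ids(self, pieces: Sequence[str]) -> np.ndarray:
        return np.array([piece_id(p, self.vocab_size) for p in pieces], dtype=np.int64)

    @staticmethod
    def _query_positions(pieces: Sequence[str]) -> list[int]:
        if not pieces or pieces[0] != CLS or SEP not in pieces:
            return []
        return list(range(1, pieces.index(SEP)))

    def forward(self, pieces: Sequence[str]) -> tuple[np.ndarray, dict]:
        ids = self.piece_ids(pieces)
        E, W, b = self.params["E"], self.params["W"], self.params["b"]
        emb = E[ids]
        n, de = emb.shape
        left = np.zeros_like(emb)
        right = np.zeros_like(emb)
        if n > 1:
            left[1:] = emb[:-1]
            right[:-1] = emb[1:]
        qpos = self._query_positions(pieces)
        qbar = emb[qpos].mean(axis=0) if qpos else np.zeros(de)
        X = np.concatenate(
            [left, emb, right, np.tile(qbar, (n, 1)), emb * qbar], axis=1
        )
        L = np.tanh(X @ W + b)
        cache = {"ids": ids, "X": X, "L": L, "qpos": qpos, "n": n, "emb": emb, "qbar": qbar}
        return L, cache

    def backward(self, cache: dict, dL: np.ndarray) -> dict[str, np.ndarray]:
        W = self.params["W"]
        de = self.emb_dim
        X, L, ids, qpos, n = (
            cache["X"], cache["L"], cache["ids"], cache["qpos"], cache["n"],
        )
        emb, qbar = cache["emb"], cache["qbar"]
        dpre = dL * (1.0 - L**2)
        grads = {
            "b": dpre.sum(axis=0),
            "W": X.T @ dpre,
            "E": np.zeros_like(self.params["E"]),
        }
        dX = dpre @ W.T
        demb = dX[:, de : 2 * de].copy()
        if n > 1:
            demb[:-1] += dX[1:, :de]  # left-neighbor path
            demb[1:] += dX[:-1, 2 * de : 3 * de]  # right-neighbor path
        dprod = dX[:, 4 * de :]
        demb += dprod * qbar
        if qpos:
            dqbar = dX[:, 3 * de : 4 * de].sum(axis=0) + (dprod * emb).sum(axis=0)
            demb[qpos] += dqbar / len(qpos)
        np.add.at(grads["E"], ids, demb)
        return grads


class PretrainedTransformerEncoder:
    """Plug-in for a pretrained transformer checkpoint (feature extraction).

    Requires the optional ``torch`` + ``transformers`` stack; constructing it
    without them raises immediately so desk-scale runs fail fast.
    """

    name = "pretrained"

    def __init__(self, checkpoint: str):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer  # noqa: F401
        except ImportError as exc:
            raise ImportError(
                "pretrained encoders need the 'torch' and 'transformers' "
                "packages; install them or use the 'tiny' encoder"
            ) from exc
        from transformers import AutoModel, AutoTokenizer

        self._tok = AutoTokenizer.from_pretrained(checkpoint)
        self._model = AutoModel.from_pretrained(checkpoint)
        self._model.eval()
        self.d = int(self._model.config.hidden_size)
        self.params: dict[str, np.ndarray] = {}

    def forward(self, pieces: Sequence[str]) -> tuple[np.ndarray, dict]:
        import torch

        ids = self._tok.convert_tokens_to_ids(list(pieces))
        with torch.no_grad():
            out = self._model(torch.tensor([ids]))
        return out.last_hidden_state[0].numpy().astype(float), {}

    def backward(self, cache: dict, dL: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError(
            "fine-tuning a pretrained encoder is not supported by the "
            "numpy training loop; it is a frozen feature extractor here"
        )


EncoderContract = TinyEncoder  # structural: forward/backward/params/d

ENCODER_REGISTRY: dict[str, Callable[..., object]] = {
    "tiny": TinyEncoder,
}


def get_encoder(name: str, **kwargs):
    """Resolve an encoder by registry name or ``pretrained:<checkpoint>``."""
    if name in ENCODER_REGISTRY:
        return ENCODER_REGISTRY[name](**kwargs)
    if name.startswith("pretrained:"):
        return PretrainedTransformerEncoder(name.split(":", 1)[1])
    raise KeyError(
        f"unknown encoder {name!r}; registered: {sorted(ENCODER_REGISTRY)} "
        "or 'pretrained:<checkpoint>'"
    )
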