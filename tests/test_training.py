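import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrcner.mrc_dataset import WhitespaceTokenizer, build_triples, encode_corpus
from mrcner.query_bank import build_query_set
from mrcner.span_model import TinyEncoder, init_head_params, row_softmax
from mrcner.synthetic_data import SynthConfig, generate_corpus
from mrcner.training import (
    AdamW,
    DivergenceError,
    LossValue,
    TrainConfig,
    cross_entropy_loss,
    evaluate_on_examples,
    example_loss_and_grads,
    focal_loss,
    load_checkpoint,
    lr_at,
    predict_corpus,
    save_checkpoint,
    train_model,
)


def random_probs(rng, n):
    return row_softmax(rng.normal(size=(n, 2)))


class TestFocalLoss:
    def test_gamma_zero_uniform_alpha_equals_cross_entropy(self):
        rng = np.random.default_rng(0)
        probs = random_probs(rng, 20)
        labels = rng.integers(0, 2, 20)
        mask = rng.random(20) < 0.7
        assert focal_loss(probs, labels, mask, gamma=0.0, alpha=None) == pytest.approx(
            cross_entropy_loss(probs, labels, mask), abs=1e-9
        )

    def test_perfect_prediction_zero_loss(self):
        labels = np.array([1, 0, 1])
        probs = np.array([[0.0, 1.0], [1.0, 0.0], [0.0, 1.0]])
        assert focal_loss(probs, labels, np.ones(3, bool), gamma=2.0) == pytest.approx(0.0)

    def test_closed_form_half_probability(self):
        # single positive position with p_t = 0.5: 0.25 * ln 2
        probs = np.array([[0.5, 0.5]])
        value = focal_loss(probs, np.array([1]), np.ones(1, bool), gamma=2.0, alpha=1.0)
        assert value == pytest.approx(0.25 * math.log(2), abs=1e-12)

    def test_alpha_weights_positive_class(self):
        probs = np.array([[0.5, 0.5]])
        pos = focal_loss(probs, np.array([1]), np.ones(1, bool), gamma=0.0, alpha=0.25)
        neg = focal_loss(probs, np.array([0]), np.ones(1, bool), gamma=0.0, alpha=0.25)
        assert pos == pytest.approx(0.25 * math.log(2))
        assert neg == pytest.approx(0.75 * math.log(2))

    def test_empty_mask_zero(self):
        probs = np.array([[0.5, 0.5]])
        assert focal_loss(probs, np.array([1]), np.zeros(1, bool)) == 0.0


class TestCrossEntropyLoss:
    def test_uniform_prediction_ln2(self):
        probs = np.full((4, 2), 0.5)
        labels = np.array([0, 1, 0, 1])
        value = cross_entropy_loss(probs, labels, np.ones(4, bool))
        assert value == pytest.approx(math.log(2), abs=1e-12)

    def test_smoothing_closed_form(self):
        # true-class prob 0.8, eps 0.1: -(0.9 ln 0.8 + 0.1 ln 0.2)
        probs = np.array([[0.2, 0.8]])
        value = cross_entropy_loss(probs, np.array([1]), np.ones(1, bool), smoothing_eps=0.1)
        expected = -(0.9 * math.log(0.8) + 0.1 * math.log(0.2))
        assert value == pytest.approx(expected, abs=1e-12)

    def test_bad_eps_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy_loss(np.full((1, 2), 0.5), np.array([0]), np.ones(1, bool), smoothing_eps=1.0)

    def test_zero_probability_clamped(self):
        probs = np.array([[1.0, 0.0]])
        value = cross_entropy_loss(probs, np.array([1]), np.ones(1, bool))
        assert math.isfinite(value)


@given(st.integers(0, 10_000), st.integers(1, 30))
@settings(max_examples=100, deadline=None)
def test_loss_equivalences_property(seed, n):
    rng = np.random.default_rng(seed)
    probs = random_probs(rng, n)
    labels = rng.integers(0, 2, n)
    mask = rng.random(n) < 0.8
    ce = cross_entropy_loss(probs, labels, mask, smoothing_eps=0.0)
    fo = focal_loss(probs, labels, mask, gamma=0.0, alpha=None)
    assert fo == pytest.approx(ce, abs=1e-9)
    assert ce >= 0.0


@given(st.integers(0, 10_000))
@settings(max_examples=50, deadline=None)
def test_loss_nonnegative_and_zero_iff_onehot(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, 5)
    onehot = np.zeros((5, 2))
    onehot[np.arange(5), labels] = 1.0
    assert cross_entropy_loss(onehot, labels, np.ones(5, bool)) == pytest.approx(0.0, abs=1e-9)
    probs = random_probs(rng, 5)
    value = cross_entropy_loss(probs, labels, np.ones(5, bool))
    if not np.allclose(probs[np.arange(5), labels], 1.0):
        assert value > 0.0


class TestLossValue:
    def test_total_is_sum(self):
        lv = LossValue(0.25, 0.5)
        assert lv.total == pytest.approx(0.75)


def _toy_example():
    corpus = generate_corpus(
        SynthConfig(n_sentences=2, seed=5, sentence_length=(3, 3), entity_density=1.0)
    )
    qs = build_query_set(corpus.label_set, "keywords")
    examples = encode_corpus(build_triples(corpus, qs), WhitespaceTokenizer(), max_len=32)
    return next(e for e in examples if e.start_labels.sum() > 0)


@pytest.mark.parametrize("mode", ["conditioned", "base"])
@pytest.mark.parametrize("loss", ["focal", "cross_entropy", "label_smoothing"])
def test_gradient_finite_difference(mode, loss):
    ex = _toy_example()
    enc = TinyEncoder(d=6, emb_dim=4, vocab_size=64, seed=1)
    head = init_head_params(enc.d, mode, seed=2)
    cfg = TrainConfig(loss=loss, head_mode=mode)
    _, grads = example_loss_and_grads(ex, enc, head, cfg)

    arrays = {
        "head.Q_start": head.Q_start,
        "head.Q_end": head.Q_end,
        "enc.E": enc.params["E"],
        "enc.W": enc.params["W"],
        "enc.b": enc.params["b"],
    }
    rng = np.random.default_rng(0)
    eps = 1e-6
    for name, arr in arrays.items():
        flat = arr.reshape(-1)
        if name == "enc.E":
            used = np.unique(enc.piece_ids(ex.pieces))
            coords = [int(i) * arr.shape[1] for i in used[:5]]
        else:
            coords = rng.choice(flat.size, size=min(8, flat.size), replace=False)
        for c in coords:
            orig = flat[c]
            flat[c] = orig + eps
            up = example_loss_and_grads(ex, enc, head, cfg)[0].total
            flat[c] = orig - eps
            down = example_loss_and_grads(ex, enc, head, cfg)[0].total
            flat[c] = orig
            fd = (up - down) / (2 * eps)
            assert grads[name].reshape(-1)[c] == pytest.approx(fd, abs=1e-4)


class TestSchedule:
    def test_warmup_then_decay(self):
        lrs = [lr_at(s, 100, 1.0, 0.1) for s in range(100)]
        assert lrs[0] == pytest.approx(0.1)
        assert lrs[9] == pytest.approx(1.0)
        assert lrs[-1] < 0.05
        assert max(lrs) == pytest.approx(1.0)

    def test_adamw_moves_params_toward_minimum(self):
        params = {"w": np.array([5.0, -3.0])}
        opt = AdamW(params, weight_decay=0.0)
        for _ in range(500):
            opt.step({"w": 2 * params["w"]}, lr=0.05)  # d/dw of w^2
        assert np.abs(params["w"]).max() < 1e-2


def _small_setup(n_train=60, n_dev=30, seed=13):
    tok = WhitespaceTokenizer()
    train_c = generate_corpus(SynthConfig(n_sentences=n_train, seed=seed))
    dev_c = generate_corpus(SynthConfig(n_sentences=n_dev, seed=seed + 1000))
    qs = build_query_set(train_c.label_set, "guideline")
    train_ex = encode_corpus(build_triples(train_c, qs), tok, max_len=64)
    dev_ex = encode_corpus(build_triples(dev_c, qs), tok, max_len=64)
    return train_c, dev_c, qs, train_ex, dev_ex, tok


class TestTrainModel:
    def test_defaults_match_published_setup(self):
        cfg = TrainConfig()
        assert cfg.seq_len == 512
        assert cfg.learning_rate == pytest.approx(2e-5)
        assert cfg.loss == "focal"
        assert cfg.batch_size == 8

    def test_determinism_same_seed_identical_history(self):
        _, _, _, train_ex, dev_ex, _ = _small_setup(n_train=12, n_dev=6)
        cfg = TrainConfig(learning_rate=0.01, epochs=2, seed=3)
        hists = []
        for _ in range(2):
            enc = TinyEncoder(seed=3)
            _, hist = train_model(train_ex, enc, cfg, dev_examples=dev_ex)
            hists.append(hist)
        assert hists[0] == hists[1]

    def test_empty_training_split_rejected(self):
        with pytest.raises(ValueError):
            train_model([], TinyEncoder(seed=0), TrainConfig())

    def test_learns_separable_corpus(self):
        _, _, _, train_ex, dev_ex, _ = _small_setup(n_train=120, n_dev=40)
        cfg = TrainConfig(
            learning_rate=0.01, epochs=12, seed=13, focal_alpha=0.75,
            early_stop_f1=0.95,
        )
        enc = TinyEncoder(seed=13)
        _, hist = train_model(train_ex, enc, cfg, dev_examples=dev_ex)
        assert max(h["dev_f1"] for h in hist) >= 0.9

    def test_history_contains_dev_metrics(self):
        _, _, _, train_ex, dev_ex, _ = _small_setup(n_train=8, n_dev=4)
        cfg = TrainConfig(learning_rate=0.01, epochs=1, seed=0)
        _, hist = train_model(train_ex, TinyEncoder(seed=0), cfg, dev_examples=dev_ex)
        assert {"epoch", "train_loss", "dev_f1"} <= set(hist[0])


class TestPredictCorpus:
    def test_empty_corpus(self):
        from mrcner.corpus_io import LabeledCorpus
        from mrcner.training import TrainedModel

        qs = build_query_set(("MAT",), "guideline")
        model = TrainedModel(TinyEncoder(seed=0), init_head_params(64, seed=0), TrainConfig())
        assert predict_corpus(LabeledCorpus([], [], ("MAT",)), qs, model) == []

    def test_overfit_run_reproduces_gold(self):
        train_c, _, qs, train_ex, _, tok = _small_setup(n_train=30)
        cfg = TrainConfig(
            learning_rate=0.01, epochs=25, seed=13, focal_alpha=0.75,
            early_stop_f1=1.0,
        )
        enc = TinyEncoder(seed=13)
        model, hist = train_model(train_ex, enc, cfg, dev_examples=train_ex)
        pred = predict_corpus(train_c, qs, model, tok)
        assert pred == list(train_c.annotations)


class TestCheckpoint:
    def test_round_trip(self, tmp_path):
        _, _, qs, train_ex, _, _ = _small_setup(n_train=6, n_dev=4)
        cfg = TrainConfig(learning_rate=0.01, epochs=1, seed=0)
        enc = TinyEncoder(seed=0)
        model, _ = train_model(train_ex, enc, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(path, model)
        again = load_checkpoint(path)
        np.testing.assert_array_equal(again.head.Q_start, model.head.Q_start)
        np.testing.assert_array_equal(again.encoder.params["E"], model.encoder.params["E"])
        assert again.cfg == model.cfg

    def test_loaded_model_predicts_identically(self, tmp_path):
        train_c, _, qs, train_ex, _, tok = _small_setup(n_train=10, n_dev=4)
        cfg = TrainConfig(learning_rate=0.01, epochs=2, seed=1)
        model, _ = train_model(train_ex, TinyEncoder(seed=1), cfg)
        save_checkpoint(tmp_path / "m.npz", model)
        again = load_checkpoint(tmp_path / "m.npz")
        assert predict_corpus(train_c, qs, again, tok) == predict_corpus(
            train_c, qs, model, tok
        )
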