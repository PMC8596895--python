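"""CRF scoring/decoding against brute-force enumeration; full-model contracts."""

from itertools import product

import numpy as np
import pytest

from clinevent import (CharEncoderConfig, EventTagger, LabeledSentence,
                       ModelConfig, SynthConfig, TagSchema, crf_log_partition,
                       crf_sequence_score, generate_corpus, nll_loss,
                       viterbi_decode)
from clinevent._autodiff import Tensor
from clinevent.sequence_model import (CrfParams, bioes_transition_penalty,
                                      crf_nll_batched)


def enumerate_scores(scores, crf):
    l, d_f = scores.shape
    return {y: crf_sequence_score(scores, list(y), crf)
            for y in product(range(d_f), repeat=l)}


def zero_crf(d_f):
    crf = CrfParams(d_f)
    crf.transitions.data[:] = 0
    return crf


class TestCrfOracles:
    def test_single_step_score_is_emission(self):
        crf = zero_crf(2)
        scores = np.array([[1.0, 0.0]])
        assert crf_sequence_score(scores, [0], crf) == 1.0
        assert crf_sequence_score(scores, [1], crf) == 0.0

    def test_all_zero_parameters_score_zero(self):
        crf = zero_crf(4)
        scores = np.zeros((3, 4))
        for y in product(range(4), repeat=3):
            assert crf_sequence_score(scores, list(y), crf) == 0.0

    def test_log_partition_two_label_closed_form(self):
        crf = zero_crf(2)
        scores = np.array([[1.0, 0.0]])
        assert abs(crf_log_partition(scores, crf)
                   - np.log(np.e + 1.0)) < 1e-12  # ~1.31326

    def test_uniform_log_partition_is_l_log_df(self):
        crf = zero_crf(5)
        assert abs(crf_log_partition(np.zeros((3, 5)), crf)
                   - np.log(125.0)) < 1e-12

    def test_forward_algorithm_matches_enumeration(self, rng):
        for _ in range(30):
            l = int(rng.integers(1, 6))
            d_f = int(rng.integers(2, 5))
            crf = CrfParams(d_f, rng)
            crf.start.data[:] = rng.normal(size=d_f)
            crf.stop.data[:] = rng.normal(size=d_f)
            scores = rng.normal(size=(l, d_f))
            table = enumerate_scores(scores, crf)
            brute = np.logaddexp.reduce(list(table.values()))
            assert abs(crf_log_partition(scores, crf) - brute) < 1e-8
            # probabilities over all sequences sum to 1
            log_z = crf_log_partition(scores, crf)
            assert abs(sum(np.exp(s - log_z) for s in table.values()) - 1) < 1e-8

    def test_viterbi_matches_enumerated_maximum(self, rng):
        for _ in range(30):
            l = int(rng.integers(1, 6))
            d_f = int(rng.integers(2, 5))
            crf = CrfParams(d_f, rng)
            scores = rng.normal(size=(l, d_f))
            table = enumerate_scores(scores, crf)
            best = crf_sequence_score(scores, viterbi_decode(scores, crf), crf)
            assert abs(best - max(table.values())) < 1e-12

    def test_viterbi_beats_random_sequences(self, rng):
        crf = CrfParams(6, rng)
        scores = rng.normal(size=(8, 6))
        best = crf_sequence_score(scores, viterbi_decode(scores, crf), crf)
        for _ in range(100):
            y = rng.integers(0, 6, size=8).tolist()
            assert best >= crf_sequence_score(scores, y, crf) - 1e-12

    def test_viterbi_tie_breaks_to_lowest_label(self):
        crf = zero_crf(3)
        assert viterbi_decode(np.zeros((4, 3)), crf) == [0, 0, 0, 0]

    def test_factorized_case_is_positionwise_argmax(self, rng):
        crf = zero_crf(4)
        crf.start.data[:] = 0
        crf.stop.data[:] = 0
        scores = rng.normal(size=(6, 4))
        assert viterbi_decode(scores, crf) == list(scores.argmax(axis=1))

    def test_label_out_of_range_rejected(self):
        crf = zero_crf(3)
        with pytest.raises(ValueError):
            crf_sequence_score(np.zeros((2, 3)), [0, 5], crf)


class TestNllLoss:
    def test_uniform_loss_is_l_log_df(self):
        crf = zero_crf(3)
        batch = [(np.zeros((2, 3)), [0, 1])]
        assert abs(nll_loss(batch, crf) - 2 * np.log(3.0)) < 1e-12

    def test_loss_nonnegative(self, rng):
        crf = CrfParams(4, rng)
        batch = [(rng.normal(size=(int(rng.integers(1, 6)), 4)),
                  rng.integers(0, 4, size=1).tolist() * 1) for _ in range(5)]
        batch = [(s, rng.integers(0, 4, size=len(s)).tolist()) for s, _ in batch]
        assert nll_loss(batch, crf) >= 0.0

    def test_batched_nll_equals_sum_of_singles(self, rng):
        crf = CrfParams(5, rng)
        lens = [3, 6, 1]
        ems = [rng.normal(size=(n, 5)) for n in lens]
        ys = [rng.integers(0, 5, size=n).tolist() for n in lens]
        single = nll_loss(list(zip(ems, ys)), crf)
        L = max(lens)
        E = np.zeros((3, L, 5))
        tags = np.zeros((3, L), dtype=np.intp)
        for b, (e, y) in enumerate(zip(ems, ys)):
            E[b, :len(y)] = e
            tags[b, :len(y)] = y
        batched = crf_nll_batched(Tensor(E), tags, np.array(lens), crf)
        assert abs(single - batched.item()) < 1e-9


@pytest.fixture(scope="module")
def small_model():
    schema = TagSchema()
    cfg = ModelConfig(char=CharEncoderConfig(cd=6, heads=3, cd_ff=8, layers=1),
                      wd=4, d_model=8, heads=2, layers=1)
    corpus = generate_corpus(SynthConfig(n_sentences=8, seed=3))
    return EventTagger.build(cfg, schema, corpus, seed=0), corpus


class TestEventTagger:
    def test_forward_features_shape(self, small_model):
        model, corpus = small_model
        scores = model.forward_features(corpus[0].tokens)
        assert scores.shape == (len(corpus[0]), 25)

    def test_forward_deterministic_in_inference(self, small_model):
        model, corpus = small_model
        a = model.forward_features(corpus[0].tokens)
        b = model.forward_features(corpus[0].tokens)
        assert np.array_equal(a, b)

    def test_empty_sentence_rejected(self, small_model):
        model, _ = small_model
        with pytest.raises(ValueError):
            model.forward_features([])

    def test_predict_emits_known_labels(self, small_model):
        model, corpus = small_model
        for tags in model.predict(corpus[:4]):
            assert all(t in model.schema.labels for t in tags)

    def test_batching_matches_single_sentence(self, small_model):
        model, corpus = small_model
        batched, _, lengths = model._forward_batch(
            [s.tokens for s in corpus[:3]])
        for b in range(3):
            single = model.forward_features(corpus[b].tokens)
            assert np.allclose(batched.data[b, :lengths[b]], single)

    def test_checkpoint_roundtrip(self, small_model, tmp_path):
        model, corpus = small_model
        path = tmp_path / "ckpt.npz"
        model.save(path)
        clone = EventTagger.load(path)
        assert clone.predict(corpus[:4]) == model.predict(corpus[:4])
        a = clone.forward_features(corpus[0].tokens)
        b = model.forward_features(corpus[0].tokens)
        assert np.array_equal(a, b)

    def test_zero_char_ablation_ignores_characters(self, small_model):
        model, corpus = small_model
        model.config.zero_char = True
        try:
            base = model.forward_features(["worda", "wordb"])
            # same word ids (both OOV) but different characters -> same scores
            other = model.forward_features(["xxxxx", "yyyyy"])
            assert np.allclose(base, other)
        finally:
            model.config.zero_char = False

    def test_constrained_decode_is_schema_valid(self, small_model):
        model, corpus = small_model
        model.config.constrained_decode = True
        try:
            for tags in model.predict(corpus):
                model.schema.validate_tags(tags)  # must not raise
        finally:
            model.config.constrained_decode = False


def test_bioes_transition_penalty_blocks_invalid_moves(schema):
    trans, start, stop = bioes_transition_penalty(schema)
    li = {lab: i for i, lab in enumerate(schema.labels)}
    assert trans[li["O"], li["I-test"]] < -1e29
    assert trans[li["B-test"], li["E-test"]] == 0
    assert trans[li["B-test"], li["E-problem"]] < -1e29
    assert start[li["E-test"]] < -1e29 and start[li["B-test"]] == 0
    assert stop[li["B-test"]] < -1e29 and stop[li["S-test"]] == 0
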