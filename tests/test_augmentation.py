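"""Label-preserving lexical augmentation."""

import pytest

from clinevent import (AugmentationMode, LabeledSentence, Lexicon,
                       SynthConfig, augment_corpus, augment_sentence,
                       find_replaceable, generate_corpus, generate_lexicon,
                       select_replacement)
from clinevent.synthetic import filler_vocabulary


class TestFindReplaceable:
    def test_worked_example_indices(self, example):
        sent, lex = example
        idx = find_replaceable(sent, lex)
        assert [sent.tokens[i] for i in idx] == ["has", "worked", "up"]

    def test_event_tokens_never_replaceable(self, example):
        _, lex = example
        sent = LabeledSentence(["worked", "up"], ["B-occurrence", "E-occurrence"])
        assert find_replaceable(sent, lex) == []

    def test_tokens_absent_from_lexicon(self, example):
        _, lex = example
        sent = LabeledSentence(["azithromycin", "given"], ["O", "O"])
        assert find_replaceable(sent, lex) == []

    def test_digit_and_punctuation_tokens_excluded(self):
        lex = Lexicon({"09/97": {"synonyms": ["x"]}, ".": {"synonyms": ["y"]}})
        sent = LabeledSentence(["09/97", "."], ["O", "O"])
        assert find_replaceable(sent, lex) == []


class TestSelectReplacement:
    def test_priority_order_picks_first_nonempty_list(self, example):
        _, lex = example
        assert select_replacement("worked", lex) == "set"  # hypernym wins

    def test_antonym_exclusion_leaves_nothing(self, example):
        _, lex = example
        assert select_replacement("up", lex, exclude_antonyms=True) is None
        assert select_replacement("up", lex, exclude_antonyms=False) == "down"

    def test_unknown_word_gives_none(self, example):
        _, lex = example
        assert select_replacement("enema", lex) is None

    def test_capitalization_mirrors_source(self, example):
        _, lex = example
        assert select_replacement("Worked", lex) == "Set"

    def test_lookup_case_insensitive(self):
        lex = Lexicon({"Has": {"synonyms": ["have"]}})
        assert select_replacement("has", lex) == "have"
        assert select_replacement("HAS", lex) == "Have"


class TestAugmentSentence:
    def test_all_mode_matches_worked_example(self, example):
        sent, lex = example
        out = augment_sentence(sent, lex, AugmentationMode.ALL)
        assert len(out) == 1
        assert out[0].text() == "She have been set down with barium enema 09/97 ."
        assert out[0].tags == sent.tags

    def test_all_no_ant_mode(self, example):
        sent, lex = example
        out = augment_sentence(sent, lex, AugmentationMode.ALL_NO_ANT)
        assert [s.text() for s in out] == \
            ["She have been set up with barium enema 09/97 ."]

    def test_one_no_ant_emits_one_sentence_per_changed_word(self, example):
        sent, lex = example
        out = augment_sentence(sent, lex, AugmentationMode.ONE_NO_ANT)
        assert [s.text() for s in out] == [
            "She have been worked up with barium enema 09/97 .",
            "She has been set up with barium enema 09/97 .",
        ]

    def test_no_change_suppressed(self):
        lex = Lexicon({"same": {"synonyms": ["same"]}})
        sent = LabeledSentence(["same"], ["O"])
        for mode in AugmentationMode:
            assert augment_sentence(sent, lex, mode) == []


class TestAugmentCorpus:
    def test_one_no_ant_corpus_size(self, example):
        sent, lex = example
        out = augment_corpus([sent], lex, AugmentationMode.ONE_NO_ANT)
        assert len(out) == 3  # original + 2 generated
        assert out[0] is sent or out[0].tokens == sent.tokens

    def test_empty_lexicon_is_identity(self, tiny_corpus):
        out = augment_corpus(tiny_corpus, Lexicon({}), AugmentationMode.ALL)
        assert [s.tokens for s in out] == [s.tokens for s in tiny_corpus]

    def test_subsampling_deterministic(self, example):
        sent, lex = example
        runs = [augment_corpus([sent] * 10, lex, AugmentationMode.ONE_NO_ANT,
                               sample_fraction=0.5, seed=3) for _ in range(2)]
        assert [s.tokens for s in runs[0]] == [s.tokens for s in runs[1]]
        assert len(runs[0]) == 10 + 10  # 20 generated, half kept

    def test_invalid_fraction_rejected(self, example):
        sent, lex = example
        with pytest.raises(ValueError):
            augment_corpus([sent], lex, AugmentationMode.ALL, sample_fraction=0.0)


class TestAugmentationProperties:
    """Invariants over randomly generated corpora and lexica."""

    @pytest.mark.parametrize("mode", list(AugmentationMode))
    def test_tags_and_length_preserved(self, mode):
        cfg = SynthConfig(n_sentences=40, seed=5, signal=0.8)
        corpus = generate_corpus(cfg)
        lex = generate_lexicon(filler_vocabulary(cfg), cfg)
        assert augment_corpus(corpus, lex, mode)[:len(corpus)] == corpus
        for sent in corpus:
            for gen in augment_sentence(sent, lex, mode):
                assert gen.tags == sent.tags
                assert len(gen.tokens) == len(sent.tokens)

    def test_all_mode_at_most_doubles(self):
        cfg = SynthConfig(n_sentences=30, seed=6)
        corpus = generate_corpus(cfg)
        lex = generate_lexicon(filler_vocabulary(cfg), cfg)
        out = augment_corpus(corpus, lex, AugmentationMode.ALL)
        assert len(corpus) <= len(out) <= 2 * len(corpus)

    def test_one_no_ant_size_formula(self):
        cfg = SynthConfig(n_sentences=30, seed=6)
        corpus = generate_corpus(cfg)
        lex = generate_lexicon(filler_vocabulary(cfg), cfg)
        expected = len(corpus)
        for sent in corpus:
            for i in find_replaceable(sent, lex):
                repl = select_replacement(sent.tokens[i], lex,
                                          exclude_antonyms=True)
                if repl is not None and repl != sent.tokens[i]:
                    expected += 1
        out = augment_corpus(corpus, lex, AugmentationMode.ONE_NO_ANT)
        assert len(out) == expected

    def test_all_no_ant_never_emits_antonyms(self):
        cfg = SynthConfig(n_sentences=40, seed=8)
        corpus = generate_corpus(cfg)
        lex = generate_lexicon(filler_vocabulary(cfg), cfg)
        antonyms = {a for e in lex.entries.values() for a in e["antonyms"]}
        # restrict to antonyms that no other relation could also produce
        other = {c for e in lex.entries.values()
                 for rel in ("synonyms", "hypernyms", "hyponyms", "related_words")
                 for c in e[rel]}
        pure_antonyms = antonyms - other
        for sent in corpus:
            for gen in augment_sentence(sent, lex, AugmentationMode.ALL_NO_ANT):
                changed = {new for old, new in zip(sent.tokens, gen.tokens)
                           if old != new}
                assert not changed & pure_antonyms
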