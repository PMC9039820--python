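import dataclasses

import numpy as np
import pytest

from certcoder.certificates import backward_concatenate
from certcoder.evaluation import corpus_metrics
from certcoder.model import (
    CoderResults,
    Seq2SeqCoder,
    TransformerConfig,
    confidence_score,
    ensemble_predict,
)
from certcoder.synthetic import NoiseConfig, build_grammar, generate_corpus

from conftest import make_cert, CHAIN_LINES, CHAIN_CODES_ALIGNED, CHAIN_FLAT_TARGET


@pytest.fixture(scope="module")
def small_corpus():
    grammar = build_grammar(160, 120, seed=2)
    corpus = generate_corpus(
        1600, grammar, NoiseConfig(), seed=4, split_fractions=(0.8, 0.1, 0.1)
    )
    return corpus


@pytest.fixture(scope="module")
def light_results(small_corpus):
    """A lightly trained coder shared by decoding/serialization tests."""
    train = [p.db_style for p in small_corpus.train]
    cfg = TransformerConfig(train_steps=500, batch_size=48, seed=0)
    return Seq2SeqCoder.from_corpus(train, config=cfg, code_frequency_threshold=5).fit()


@pytest.fixture(scope="module")
def untrained_coder(small_corpus):
    train = [p.db_style for p in small_corpus.train]
    cfg = TransformerConfig(train_steps=5, batch_size=16, seed=0)
    return Seq2SeqCoder.from_corpus(train, config=cfg, code_frequency_threshold=5)


class TestEncodeExample:
    def test_encoder_stream_structure(self, untrained_coder):
        cert = untrained_coder.train_certs[0]
        src, _ = untrained_coder.encode_example(cert)
        blocks, _ = backward_concatenate(cert)
        n_words = sum(len(b) for b in blocks)
        n_sep = len(blocks) - 1
        assert len(src) == 4 + n_words + n_sep + 2  # aux + words + SEPs + BOS/EOS

    def test_year_changes_exactly_one_position(self, untrained_coder):
        cert = untrained_coder.train_certs[0]
        other_year = next(y for y in untrained_coder.years if y != cert.aux.year)
        moved = dataclasses.replace(cert, aux=dataclasses.replace(cert.aux, year=other_year))
        a, _ = untrained_coder.encode_example(cert)
        b, _ = untrained_coder.encode_example(moved)
        assert sum(x != y for x, y in zip(a, b)) == 1 and len(a) == len(b)

    def test_target_round_trips_through_code_tokenizer(self):
        cert = make_cert(CHAIN_LINES, CHAIN_CODES_ALIGNED)
        coder = Seq2SeqCoder.from_corpus([cert], config=TransformerConfig(train_steps=1))
        _, tgt = coder.encode_example(cert)
        tokens = coder.code_vocab.decode_ids(tgt)
        decoded = coder.code_tokenizer.decode(tokens)
        assert [c.text for c in decoded] == CHAIN_FLAT_TARGET

    def test_overlong_target_names_certificate(self, small_corpus, untrained_coder):
        cfg = dataclasses.replace(untrained_coder.config, max_target_len=3)
        coder = Seq2SeqCoder(
            cfg,
            untrained_coder.text_vocab,
            untrained_coder.code_tokenizer,
            untrained_coder.years,
        )
        cert = untrained_coder.train_certs[0]
        with pytest.raises(ValueError, match=cert.id):
            coder.encode_example(cert)


class TestTraining:
    def test_memorizes_small_corpus(self, small_corpus):
        # overfit oracle: a tiny model must near-perfectly fit 200 examples
        train = [p.db_style for p in small_corpus.train[:200]]
        cfg = TransformerConfig(
            train_steps=900, batch_size=32, seed=1, dropout=0.0, warmup_steps=200
        )
        res = Seq2SeqCoder.from_corpus(train, config=cfg, code_frequency_threshold=5).fit()
        assert res.token_accuracy(train) >= 0.99

    def test_untrained_model_scores_near_zero(self, untrained_coder, small_corpus):
        coder = Seq2SeqCoder(
            dataclasses.replace(untrained_coder.config, train_steps=0),
            untrained_coder.text_vocab,
            untrained_coder.code_tokenizer,
            untrained_coder.years,
        )
        net = coder._build_transformer()
        res = CoderResults(coder, net, training_log=[])
        test = [p.db_style for p in small_corpus.test[:40]]
        preds = res.predict(test, beam_size=1)
        truths = {c.id: backward_concatenate(c)[1] for c in test}
        rep = corpus_metrics({p.id: p.codes for p in preds}, truths, B=10, seed=0)
        assert rep.f_measure < 0.3

    def test_divergence_detection(self, small_corpus):
        train = [p.db_style for p in small_corpus.train[:50]]
        cfg = TransformerConfig(
            train_steps=30, batch_size=16, seed=1, learning_rate_factor=1e20, warmup_steps=1
        )
        with np.errstate(all="ignore"), pytest.raises(RuntimeError, match="diverged"):
            Seq2SeqCoder.from_corpus(train, config=cfg).fit()


class TestDecoding:
    def test_beam_one_equals_greedy(self, light_results, small_corpus):
        test = [p.db_style for p in small_corpus.test[:25]]
        greedy = light_results.predict(test, beam_size=1)
        beam1 = [
            light_results._beam_decode([light_results.net], c, beam_size=1, length_penalty=0.0)
            for c in test
        ]
        assert [[c.text for c in p.codes] for p in greedy] == [
            [c.text for c in p.codes] for p in beam1
        ]

    def test_wider_beam_never_lowers_sequence_logprob(self, light_results, small_corpus):
        test = [p.db_style for p in small_corpus.test[:40]]
        for cert in test:
            g = light_results._beam_decode([light_results.net], cert, 1, length_penalty=0.0)
            b = light_results._beam_decode([light_results.net], cert, 4, length_penalty=0.0)
            assert sum(b.per_token_logprobs) >= sum(g.per_token_logprobs) - 1e-9

    def test_scores_lie_in_unit_interval(self, light_results, small_corpus):
        preds = light_results.predict([p.db_style for p in small_corpus.test[:30]], beam_size=1)
        assert all(0.0 <= p.score <= 1.0 for p in preds)


class TestConfidence:
    def test_certain_tokens_score_one(self):
        assert confidence_score([0.0, 0.0, 0.0]) == pytest.approx(1.0)

    def test_geometric_mean(self):
        assert confidence_score([np.log(0.5), np.log(0.5)]) == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confidence_score([])


@pytest.fixture(scope="module")
def members(small_corpus):
    train = [p.db_style for p in small_corpus.train]
    out = []
    for seed in (0, 1, 2):
        cfg = TransformerConfig(train_steps=350, batch_size=48, seed=seed)
        out.append(
            Seq2SeqCoder.from_corpus(train, config=cfg, code_frequency_threshold=5).fit()
        )
    return out


class TestEnsemble:
    def test_singleton_ensemble_reduces_to_member(self, members, small_corpus):
        test = [p.db_style for p in small_corpus.test[:20]]
        solo = members[0].predict(test, beam_size=2)
        ens = ensemble_predict(members[:1], test, beam_size=2)
        assert [[c.text for c in p.codes] for p in solo] == [
            [c.text for c in p.codes] for p in ens
        ]
        assert [p.score for p in solo] == pytest.approx([p.score for p in ens])

    def test_identical_members_equal_single_model(self, members, small_corpus):
        test = [p.db_style for p in small_corpus.test[:20]]
        tripled = [members[0], members[0], members[0]]
        single = members[0].predict(test, beam_size=1)
        ens = ensemble_predict(tripled, test, beam_size=1)
        assert [[c.text for c in p.codes] for p in single] == [
            [c.text for c in p.codes] for p in ens
        ]

    def test_ensemble_not_worse_than_best_member(self, members, small_corpus):
        test = [p.db_style for p in small_corpus.test]
        truths = {c.id: backward_concatenate(c)[1] for c in test}

        def f_of(preds):
            return corpus_metrics({p.id: p.codes for p in preds}, truths, B=10, seed=0).f_measure

        member_f = [f_of(m.predict(test, beam_size=1)) for m in members]
        ens_f = f_of(ensemble_predict(members, test, beam_size=1))
        assert ens_f >= max(member_f) - 0.01

    def test_vocabulary_mismatch_rejected(self, members, small_corpus):
        other_train = [p.db_style for p in small_corpus.test]
        cfg = TransformerConfig(train_steps=5, batch_size=16, seed=9)
        other = Seq2SeqCoder.from_corpus(other_train, config=cfg, code_frequency_threshold=1).fit()
        with pytest.raises(ValueError, match="vocabular"):
            ensemble_predict([members[0], other], other_train[:2], beam_size=1)


class TestSerialization:
    def test_save_load_greedy_identical(self, light_results, small_corpus, tmp_path):
        light_results.save(tmp_path / "ckpt")
        clone = CoderResults.load(tmp_path / "ckpt")
        test = [p.db_style for p in small_corpus.test[:100]]
        a = light_results.predict(test, beam_size=1)
        b = clone.predict(test, beam_size=1)
        assert [[c.text for c in p.codes] for p in a] == [[c.text for c in p.codes] for p in b]
        assert [p.score for p in a] == [p.score for p in b]

    def test_summary_mentions_configuration(self, light_results):
        s = light_results.summary()
        assert "train steps" in s and "Transformer" in s
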