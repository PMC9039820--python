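"""Auxiliary-conditioned Transformer coder: model and results objects.

The coder maps a death certificate — its backward-concatenated text plus
four auxiliary variables (gender, year, age class, origin) — to the flat
sequence of ICD-10 codes, factorized autoregressively over hierarchical
code tokens.  Auxiliary variables enter as four learned special tokens
prepended to the encoder stream.

Usage follows the model/results convention of statistical modelling
packages::

    coder = Seq2SeqCoder.from_corpus(train_certs, val_certs, config)
    results = coder.fit()
    preds = results.predict(test_certs)
    print(results.summary())

:class:`CoderResults` carries the fitted parameters, the training log and
prediction/evaluation methods; ensembles average member next-token
probability distributions at every decoding step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .certificates import (
    AGE_CLASSES,
    DeathCertificate,
    TextVocabulary,
    backward_concatenate,
    fit_text_vocab,
    tokenize_text,
)
from .icd10 import CodeDecodeError, CodeTokenizer, ICDCode, fit_code_tokenizer
from .nn import Adam, Transformer, label_smoothed_loss, noam_lr, softmax

__all__ = [
    "TransformerConfig",
    "full_size_config",
    "Prediction",
    "Seq2SeqCoder",
    "CoderResults",
    "ensemble_predict",
    "confidence_score",
]

ORIGIN_LEVELS = ("paper", "electronic")


@dataclass
class TransformerConfig:
    """Architecture, optimization and decoding settings.

    The defaults are a desk-scale configuration trainable on one CPU in
    minutes; :func:`full_size_config` returns the standard base setting.
    """

    n_layers: int = 2
    n_heads: int = 4
    model_width: int = 64
    feedforward_width: int = 128
    dropout: float = 0.1
    max_input_len: int = 96
    max_target_len: int = 48
    label_smoothing: float = 0.1
    warmup_steps: int = 400
    learning_rate_factor: float = 1.0
    batch_size: int = 64
    train_steps: int = 2000
    seed: int = 0
    beam_size: int = 4
    length_penalty: float = 0.6
    aux_fusion: str = "prepend"  # hook: "prepend" (tokens) or "add" (to every position)

    def __post_init__(self) -> None:
        if self.model_width % self.n_heads:
            raise ValueError("model_width must be divisible by n_heads")
        if self.aux_fusion != "prepend":
            raise NotImplementedError(
                "only 'prepend' auxiliary fusion is implemented; the field is "
                "a hook for alternative conditioning mechanisms"
            )


def full_size_config(**overrides) -> TransformerConfig:
    """The Transformer base setting; shipped for completeness, not for tests."""
    cfg = TransformerConfig(
        n_layers=6,
        n_heads=8,
        model_width=512,
        feedforward_width=2048,
        dropout=0.1,
        warmup_steps=4000,
        batch_size=256,
        train_steps=100_000,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    return cfg


@dataclass
class Prediction:
    """A decoded code sequence with its confidence score."""

    id: str
    codes: list[ICDCode]
    score: float
    per_token_logprobs: list[float] = field(default_factory=list)
    malformed: bool = False  # dangling/ill-placed code tokens were dropped


def confidence_score(per_token_logprobs: Sequence[float]) -> float:
    """Geometric mean of emitted-token probabilities, in [0, 1]."""
    if len(per_token_logprobs) == 0:
        raise ValueError("cannot score an empty token sequence")
    return float(np.exp(np.mean(per_token_logprobs)))


class _CodeTokenVocab:
    """Target-side vocabulary over hierarchical code tokens."""

    PAD, BOS, EOS = 0, 1, 2

    def __init__(self, tokens: Sequence[str]):
        self.tokens = list(tokens)
        self.token_to_id = {t: i + 3 for i, t in enumerate(self.tokens)}

    @property
    def size(self) -> int:
        return 3 + len(self.tokens)

    def encode(self, toks: Sequence[str]) -> list[int]:
        return [self.token_to_id[t] for t in toks]

    def decode_ids(self, ids: Sequence[int]) -> list[str]:
        return [self.tokens[i - 3] for i in ids if i >= 3]


def _lenient_decode(tok: CodeTokenizer, tokens: list[str]) -> tuple[list[ICDCode], bool]:
    """Decode token stream to codes, dropping malformed fragments."""
    try:
        return tok.decode(tokens), False
    except CodeDecodeError:
        pass
    codes: list[ICDCode] = []
    pending: str | None = None
    from .icd10 import END_MARK, parse_code

    for t in tokens:
        if t.endswith(END_MARK):
            body = t[: -len(END_MARK)]
            if len(body) >= 3:  # full-code token; drop any dangling stem
                codes.append(parse_code(body))
                pending = None
            elif pending is not None:
                codes.append(parse_code(pending + body))
                pending = None
            # else: suffix/bare marker with nothing pending — drop
        else:
            pending = t  # an open stem overwrites a dangling one
    return codes, True


class Seq2SeqCoder:
    """Model object: vocabularies, tokenizers and architecture for the coder.

    Build with :meth:`from_corpus`, then call :meth:`fit`.
    """

    def __init__(
        self,
        config: TransformerConfig,
        text_vocab: TextVocabulary,
        code_tokenizer: CodeTokenizer,
        years: Sequence[int],
        train_certs: Sequence[DeathCertificate] = (),
        val_certs: Sequence[DeathCertificate] = (),
    ):
        self.config = config
        self.text_vocab = text_vocab
        self.code_tokenizer = code_tokenizer
        self.years = tuple(int(y) for y in years)
        self.code_vocab = _CodeTokenVocab(code_tokenizer.token_vocabulary())
        self.train_certs = list(train_certs)
        self.val_certs = list(val_certs)
        # auxiliary special-token id layout, appended after the text vocab
        base = text_vocab.size
        self._aux_base = {
            "gender": base,
            "year": base + 2,
            "age": base + 2 + len(self.years),
            "origin": base + 2 + len(self.years) + len(AGE_CLASSES),
        }
        self.encoder_vocab_size = base + 2 + len(self.years) + len(AGE_CLASSES) + 2

    @classmethod
    def from_corpus(
        cls,
        train_certs: Sequence[DeathCertificate],
        val_certs: Sequence[DeathCertificate] = (),
        config: TransformerConfig | None = None,
        code_frequency_threshold: int = 10,
        max_text_vocab: int | None = None,
    ) -> "Seq2SeqCoder":
        config = config or TransformerConfig()
        text_vocab = fit_text_vocab(train_certs, max_text_vocab)
        code_seqs = [backward_concatenate(c)[1] for c in train_certs if c.codes is not None]
        code_tokenizer = fit_code_tokenizer(code_seqs, code_frequency_threshold)
        years = sorted({c.aux.year for c in train_certs})
        return cls(config, text_vocab, code_tokenizer, years, train_certs, val_certs)

    # -- example encoding ---------------------------------------------------

    def _aux_ids(self, cert: DeathCertificate) -> list[int]:
        a = cert.aux
        if a.year not in self.years:
            raise ValueError(f"certificate {cert.id}: year {a.year} unseen in training")
        return [
            self._aux_base["gender"] + (a.gender - 1),
            self._aux_base["year"] + self.years.index(a.year),
            self._aux_base["age"] + AGE_CLASSES.index(a.age_class),
            self._aux_base["origin"] + ORIGIN_LEVELS.index(a.origin),
        ]

    def encode_example(self, cert: DeathCertificate) -> tuple[list[int], list[int] | None]:
        """Encoder id stream and (if labelled) the target id stream.

        Encoder stream: four auxiliary tokens, then the BOS…EOS-framed,
        LINE_SEP-joined backward-concatenated text.  Target stream:
        BOS + hierarchical code tokens + EOS.
        """
        blocks, codes = backward_concatenate(cert)
        src = self._aux_ids(cert) + tokenize_text(self.text_vocab, blocks)
        if len(src) > self.config.max_input_len:
            src = src[: self.config.max_input_len - 1] + [self.text_vocab.EOS]
        tgt = None
        if cert.codes is not None:
            toks = self.code_tokenizer.encode(codes)
            tgt = [self.code_vocab.BOS] + self.code_vocab.encode(toks) + [self.code_vocab.EOS]
            if len(tgt) > self.config.max_target_len:
                raise ValueError(
                    f"certificate {cert.id}: target length {len(tgt)} exceeds "
                    f"max_target_len={self.config.max_target_len}"
                )
        return src, tgt

    def _pad_batch(self, seqs: list[list[int]]) -> np.ndarray:
        T = max(len(s) for s in seqs)
        out = np.zeros((len(seqs), T), dtype=np.int64)
        for i, s in enumerate(seqs):
            out[i, : len(s)] = s
        return out

    def _build_transformer(self) -> Transformer:
        c = self.config
        return Transformer(
            src_vocab=self.encoder_vocab_size,
            tgt_vocab=self.code_vocab.size,
            d_model=c.model_width,
            n_heads=c.n_heads,
            d_ff=c.feedforward_width,
            n_enc_layers=c.n_layers,
            n_dec_layers=c.n_layers,
            dropout=c.dropout,
            max_len=max(c.max_input_len, c.max_target_len) + 8,
            pad_id=0,
            seed=c.seed,
        )

    # -- fitting ------------------------------------------------------------

    def fit(self, verbose: bool = False) -> "CoderResults":
        """Train with teacher forcing under label-smoothed cross-entropy."""
        c = self.config
        examples = [self.encode_example(cert) for cert in self.train_certs]
        examples = [(s, t) for s, t in examples if t is not None]
        if not examples:
            raise ValueError("no labelled training certificates")
        net = self._build_transformer()
        opt = Adam(net.tensors())
        shuffle_rng = np.random.default_rng(c.seed + 1)
        order = shuffle_rng.permutation(len(examples))
        cursor = 0
        log: list[dict] = []
        for step in range(1, c.train_steps + 1):
            idx = []
            for _ in range(min(c.batch_size, len(examples))):
                if cursor >= len(order):
                    order = shuffle_rng.permutation(len(examples))
                    cursor = 0
                idx.append(order[cursor])
                cursor += 1
            src = self._pad_batch([examples[i][0] for i in idx])
            tgt = self._pad_batch([examples[i][1] for i in idx])
            tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
            logits = net.forward(src, tgt_in, train=True)
            loss, dlogits, acc = label_smoothed_loss(
                logits, tgt_out, pad_id=0, smoothing=c.label_smoothing
            )
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at step {step}: loss={loss}")
            net.zero_grads()
            net.backward(dlogits)
            opt.step(noam_lr(step, c.model_width, c.warmup_steps, c.learning_rate_factor))
            if step % 50 == 0 or step == c.train_steps:
                log.append({"step": step, "loss": loss, "token_accuracy": acc})
                if verbose:
                    print(f"step {step:6d}  loss {loss:.4f}  acc {acc:.4f}")
        results = CoderResults(self, net, training_log=log)
        if self.val_certs:
            results.val_token_accuracy = results.token_accuracy(self.val_certs)
        return results


class CoderResults:
    """Fitted coder: parameters, training log, prediction and evaluation."""

    def __init__(self, model: Seq2SeqCoder, net: Transformer, training_log: list[dict]):
        self.model = model
        self.net = net
        self.training_log = training_log
        self.val_token_accuracy: float | None = None

    # -- teacher-forced diagnostics ----------------------------------------

    def token_accuracy(self, certs: Sequence[DeathCertificate], batch_size: int = 128) -> float:
        """Next-token accuracy under teacher forcing (PAD excluded)."""
        m = self.model
        examples = [m.encode_example(c) for c in certs if c.codes is not None]
        correct = total = 0.0
        for i in range(0, len(examples), batch_size):
            chunk = examples[i : i + batch_size]
            src = m._pad_batch([s for s, _ in chunk])
            tgt = m._pad_batch([t for _, t in chunk])
            tgt_in, tgt_out = tgt[:, :-1], tgt[:, 1:]
            logits = self.net.forward(src, tgt_in, train=False)
            mask = tgt_out != 0
            correct += float(((logits.argmax(axis=-1) == tgt_out) & mask).sum())
            total += float(mask.sum())
        return correct / max(total, 1.0)

    # -- decoding -----------------------------------------------------------

    def _step_logprobs(self, enc_pack, prefixes: np.ndarray) -> np.ndarray:
        """Log of the (possibly ensemble-averaged) next-token distribution."""
        probs = None
        for net, (enc_out, enc_mask) in enc_pack:
            logits = net.decode(enc_out, enc_mask, prefixes, train=False)[:, -1, :]
            p = softmax(logits, axis=-1)
            probs = p if probs is None else probs + p
        probs /= len(enc_pack)
        return np.log(np.maximum(probs, 1e-30))

    def _encode_pack(self, nets, src: np.ndarray):
        return [(net, net.encode(src, train=False)) for net in nets]

    def _greedy_decode(self, nets, certs: Sequence[DeathCertificate]) -> list[Prediction]:
        m = self.model
        cv = m.code_vocab
        src = m._pad_batch([m.encode_example(c)[0] for c in certs])
        pack = self._encode_pack(nets, src)
        B = src.shape[0]
        prefixes = np.full((B, 1), cv.BOS, dtype=np.int64)
        done = np.zeros(B, dtype=bool)
        logprobs: list[list[float]] = [[] for _ in range(B)]
        for _ in range(m.config.max_target_len):
            lp = self._step_logprobs(pack, prefixes)
            nxt = lp.argmax(axis=-1)
            nxt[done] = cv.PAD
            for b in range(B):
                if not done[b]:
                    logprobs[b].append(float(lp[b, nxt[b]]))
            prefixes = np.concatenate([prefixes, nxt[:, None]], axis=1)
            done |= nxt == cv.EOS
            if done.all():
                break
        preds = []
        for b, cert in enumerate(certs):
            ids = [int(i) for i in prefixes[b, 1:] if i not in (cv.PAD,)]
            if cv.EOS in ids:
                ids = ids[: ids.index(cv.EOS)]
            codes, malformed = _lenient_decode(m.code_tokenizer, cv.decode_ids(ids))
            preds.append(
                Prediction(
                    id=cert.id,
                    codes=codes,
                    score=confidence_score(logprobs[b]) if logprobs[b] else 0.0,
                    per_token_logprobs=logprobs[b],
                    malformed=malformed,
                )
            )
        return preds

    def _beam_decode(
        self,
        nets,
        cert: DeathCertificate,
        beam_size: int,
        length_penalty: float,
    ) -> Prediction:
        m = self.model
        cv = m.code_vocab
        src = m._pad_batch([m.encode_example(cert)[0]])

        def lp_norm(logprob: float, length: int) -> float:
            if length_penalty == 0.0:
                return logprob
            return logprob / (((5.0 + length) / 6.0) ** length_penalty)

        base_pack = self._encode_pack(nets, src)  # encode once, tile per step

        # hypotheses: (token ids, per-token logprobs, finished)
        beams: list[tuple[list[int], list[float], bool]] = [([cv.BOS], [], False)]
        for _ in range(m.config.max_target_len):
            live = [b for b in beams if not b[2]]
            if not live:
                break
            prefixes = m._pad_batch([b[0] for b in live])
            pack = [
                (net, (np.repeat(eo, len(live), axis=0), np.repeat(em, len(live), axis=0)))
                for net, (eo, em) in base_pack
            ]
            lp = self._step_logprobs(pack, prefixes)
            candidates = [b for b in beams if b[2]]
            for i, (ids, lps, _) in enumerate(live):
                top = np.argsort(lp[i])[::-1][: beam_size + 1]
                for t in top:
                    candidates.append(
                        (ids + [int(t)], lps + [float(lp[i, t])], int(t) == cv.EOS)
                    )
            candidates.sort(key=lambda b: lp_norm(sum(b[1]), len(b[1])), reverse=True)
            beams = candidates[:beam_size]
            if all(b[2] for b in beams):
                break
        best = max(beams, key=lambda b: lp_norm(sum(b[1]), len(b[1])))
        ids, lps, _ = best
        body = ids[1:]
        if body and body[-1] == cv.EOS:
            body = body[:-1]
        codes, malformed = _lenient_decode(m.code_tokenizer, cv.decode_ids(body))
        return Prediction(
            id=cert.id,
            codes=codes,
            score=confidence_score(lps) if lps else 0.0,
            per_token_logprobs=lps,
            malformed=malformed,
        )

    def predict(
        self,
        certs: Sequence[DeathCertificate],
        beam_size: int | None = None,
        length_penalty: float | None = None,
        batch_size: int = 128,
        _nets=None,
    ) -> list[Prediction]:
        """Decode certificates to code-sequence predictions with scores.

        ``beam_size=1`` uses fast batched greedy decoding; larger beams run
        per certificate.
        """
        beam = self.model.config.beam_size if beam_size is None else beam_size
        lp = self.model.config.length_penalty if length_penalty is None else length_penalty
        nets = _nets or [self.net]
        if beam <= 1:
            out: list[Prediction] = []
            for i in range(0, len(certs), batch_size):
                out.extend(self._greedy_decode(nets, certs[i : i + batch_size]))
            return out
        return [self._beam_decode(nets, c, beam, lp) for c in certs]

    # -- evaluation ---------------------------------------------------------

    def evaluate(
        self,
        certs: Sequence[DeathCertificate],
        beam_size: int | None = None,
        bootstrap: int = 1000,
        seed: int = 0,
    ):
        """Predict ``certs`` and score against their stored code sequences."""
        from .evaluation import corpus_metrics

        preds = self.predict(certs, beam_size=beam_size)
        truths = {c.id: list(backward_concatenate(c)[1]) for c in certs}
        return corpus_metrics({p.id: p.codes for p in preds}, truths, B=bootstrap, seed=seed)

    def summary(self) -> str:
        c = self.model.config
        lines = [
            "Auxiliary-conditioned Transformer ICD-10 coder",
            "=" * 47,
            f"encoder/decoder layers : {c.n_layers}/{c.n_layers}",
            f"width / ff / heads     : {c.model_width}/{c.feedforward_width}/{c.n_heads}",
            f"text vocab / code vocab: {self.model.encoder_vocab_size}/{self.model.code_vocab.size}",
            f"train certificates     : {len(self.model.train_certs)}",
            f"train steps            : {c.train_steps} (batch {c.batch_size})",
        ]
        if self.training_log:
            last = self.training_log[-1]
            lines.append(
                f"final train loss/acc   : {last['loss']:.4f}/{last['token_accuracy']:.4f}"
            )
        if self.val_token_accuracy is not None:
            lines.append(f"val token accuracy     : {self.val_token_accuracy:.4f}")
        return "\n".join(lines)

    # -- serialization ------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        m = self.model
        meta = {
            "config": asdict(m.config),
            "years": list(m.years),
            "val_token_accuracy": self.val_token_accuracy,
            "training_log": self.training_log,
        }
        (d / "config.json").write_text(json.dumps(meta, indent=1))
        (d / "text_vocab.json").write_text(m.text_vocab.to_json())
        (d / "code_tokenizer.json").write_text(m.code_tokenizer.to_json())
        np.savez(d / "weights.npz", *self.net.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "CoderResults":
        d = Path(directory)
        meta = json.loads((d / "config.json").read_text())
        config = TransformerConfig(**meta["config"])
        text_vocab = TextVocabulary.from_json((d / "text_vocab.json").read_text())
        code_tok = CodeTokenizer.from_json((d / "code_tokenizer.json").read_text())
        model = Seq2SeqCoder(config, text_vocab, code_tok, meta["years"])
        net = model._build_transformer()
        with np.load(d / "weights.npz") as z:
            net.set_weights([z[k] for k in z.files])
        res = cls(model, net, training_log=meta.get("training_log", []))
        res.val_token_accuracy = meta.get("val_token_accuracy")
        return res


def ensemble_predict(
    members: Sequence[CoderResults],
    certs: Sequence[DeathCertificate],
    beam_size: int | None = None,
    length_penalty: float | None = None,
) -> list[Prediction]:
    """Decode with per-step arithmetic averaging of member distributions.

    All members must share text vocabulary, code tokenizer and year table;
    an ensemble of one is exactly that member's own decoding.
    """
    if not members:
        raise ValueError("empty ensemble")
    head = members[0].model
    for m in members[1:]:
        if (
            m.model.text_vocab.token_to_id != head.text_vocab.token_to_id
            or m.model.code_vocab.tokens != head.code_vocab.tokens
            or m.model.years != head.years
        ):
            raise ValueError("ensemble members must share vocabularies")
    return members[0].predict(
        certs,
        beam_size=beam_size,
        length_penalty=length_penalty,
        _nets=[m.net for m in members],
    )
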