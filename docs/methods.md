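# Methods

This note documents the models and procedures implemented in `certcoder`,
the choices made where the design was genuinely open, and what the
synthetic benchmark does and does not establish.

## Data model

A certificate carries six text lines (five for part 1 of the WHO
causal-chain form, one for part 2), four auxiliary variables, and — when
labelled — one ICD-10 code sequence per line, capped at 20 codes total.

* **Gender**: categorical {1, 2}.
* **Year of death**: categorical over the corpus years (default 2011–2016).
* **Age class**: 22 ordinal categories — `<28d`, `28d–<1y`, `1–4`, then
  5-year bins `5–9` … `90–94`, and `95+`.  Only the two infant classes and
  the 5-year width are externally fixed; the bin edges and the open top bin
  are this package's choice, made so the number of classes matches the
  model's declared age cardinality of 22.
* **Origin**: `paper` or `electronic`.  Text normalization (lowercasing,
  accent folding, punctuation stripping with `!` preserved, whitespace
  collapse) is deliberately identical for both origins; the distributional
  shift between the two entry pipelines is left to the model, which
  receives origin as a feature.

**Backward concatenation.**  Model input and target use the line order
part 2 → line 5 → … → line 1.  If a line's codes are moved to the front of
the immediately preceding coded line (the misalignment artifact), the
backward-flattened code sequence is unchanged: the moved block simply
crosses a line boundary it was already adjacent to in backward order.  This
is an identity, not an approximation, for single-hop front-moves — the only
pattern modelled, because it is the only one consistent with how the
artifact arises (a coder writing a line's codes one slot too early).  No
other realignment heuristic is applied.

## Code tokenization

The decoder's target vocabulary is built from the training corpus with a
frequency threshold (default 10):

* a code seen ≥ threshold times becomes one token, `I10-`;
* any other code is emitted as stem + closing suffix: `I659 → I65, 9-`,
  and three-character rare codes as stem + bare marker `-`;
* the trailing `-` marks "this token ends a code", making decoding a
  deterministic lossless inverse (property-tested over seeded random
  sequences at several thresholds).

The threshold scheme is the simplest mechanism that both exploits the
classification's stem hierarchy for rare codes and keeps frequent codes
atomic; raising the threshold can only shrink the set of full-code tokens.
Whether frequent multi-code n-grams should also merge was considered and
rejected: it complicates decoding for no measurable benefit at this scale.

## Model

A pre-layer-norm Transformer encoder–decoder implemented directly in NumPy
with explicit backward passes (gradient-checked against central finite
differences at float64).  Auxiliary variables enter as four learned special
tokens prepended to the encoder stream — the simplest conditioning
consistent with a "slightly adapted" standard architecture; a config hook
(`aux_fusion`) reserves the alternative of adding one embedding to every
encoder position.

Desk-scale defaults (the configuration all tests and the acceptance script
exercise): 2+2 layers, width 64, feed-forward 128, 4 heads, dropout 0.1,
label smoothing 0.1, Adam with the inverse-square-root schedule, warmup
400 steps, batch 64, 2,000 steps.  The warmup is shorter than the
conventional 4,000 of the full-size base setting because desk-scale runs
take only ~2,000 steps in total; `full_size_config()` ships the
conventional setting (6 layers, width 512, warmup 4,000) but is not
exercised by the test suite.  All stochastic components — initialization,
batch shuffling, dropout — derive from the one config seed; training loss
trajectories and greedy decoding are bit-reproducible, and checkpoints
reload to identical greedy predictions.

**Decoding.**  Greedy decoding is batched; beam search (default beam 4,
length penalty 0.6 in the standard `((5+L)/6)^α` form) runs per
certificate.  Token streams that violate the tokenizer grammar (dangling
stem, suffix with no stem) are repaired by dropping the offending fragment
and flagging the prediction as malformed rather than failing a batch.  The
guarantee that a wider beam never lowers the model's own sequence
log-probability holds for ranking by raw log-probability, i.e. with the
length penalty at 0; the default penalty trades that invariant for better
length behaviour.

**Confidence.**  A prediction's score is the geometric mean of its emitted
token probabilities, `exp(mean log p)` — length-normalized so sequences of
any length map into [0, 1], as the 0.01-grid rejection analysis requires.
Raw sequence probability is available from the per-token log-probs.

**Ensembles.**  Members trained from different seeds share vocabularies;
at every decoding step the next-token distribution is the arithmetic mean
of member softmax outputs.  An ensemble of one is exactly its member;
identical members reproduce the single model.

## Evaluation

* **Counting.**  A predicted code is a true positive only on exact match
  up to the fourth character.  Order is never penalized.  Repeated codes
  use multiset semantics: `tp = Σ_c min(count_pred, count_truth)` — proven
  equivalent to optimal one-to-one assignment for exact matching, and
  tested against a brute-force assignment oracle.
* **Aggregation.**  Micro-averaging: counts pool over certificates before
  P/R/F.  Conventions made explicit because the definitions leave them
  open: empty prediction vs empty truth scores 1.0; zero TP with any error
  scores 0.
* **Uncertainty.**  Percentile bootstrap over certificates, B = 1000
  default, seeded.
* **Per-chapter rates.**  `fp_rate = FP_c/(TP_c+FP_c)` over chapter-c
  *predictions*, `fn_rate = FN_c/(TP_c+FN_c)` over chapter-c *truth*;
  prevalence is the chapter's share of truth codes.  These denominators are
  one defensible reading of per-chapter error reporting and are recorded as
  such; rows sort by descending prevalence and zero-denominator chapters
  are omitted.
* **Rejection curve.**  Thresholds on the 0.01 grid; a prediction with
  score ≤ t is rejected (strict acceptance above the threshold); each point
  records the accepted fraction and the micro-F on the accepted subset;
  thresholds rejecting everything produce no point.
* **Shared-code removal.**  For expert-disagreement studies on
  certificates sampled *because* model and database disagree, codes common
  to both (multiset intersection) are deleted from model, database and
  expert sequences before metrics, preventing the shared majority from
  inflating agreement.

## Synthetic benchmark

The generator emulates the structure of a national mortality corpus, not
its language.  Text is a pseudo-language: each lexicon phrase starts with a
unique head word mapping to 1–3 codes, so the rule-based oracle parses
deterministically and the grammar is exactly recoverable in principle.
Default study conditions: 90% paper origin; unreadable-word corruption in
10% of paper certificates (every word of one phrase becomes `!`, the
database keeps the hidden codes); misalignment probability 0.02 — the real
phenomenon is known only to be "rare", so this default is a configurable
guess; filled-line count distributed (0.15, 0.25, 0.25, 0.15, 0.12, 0.08)
over 1–6 lines; mortality-shaped age marginals; uniform year and gender.
A context-rule trigger appears on ~25% of certificates, half the time with
an external-cause phrase earlier in backward order, so both branches of
the chapter-9/19 rule are well represented.  Electronic-typo noise exists
as a knob but defaults to 0 — the rate is unquantified and enabling it
would only add UNK noise.

The corpus splitter excludes validation and test certificates per year
stratum, mirroring per-year exclusion at configurable scale, and the whole
generation is byte-reproducible under its seed.

**What passing tests show — and don't.**  Grammar recovery (micro-F ≥ 0.90
and ≥ 90% context-rule adherence for a 2-layer model trained ~5 minutes on
~20k certificates; observed ≈ 0.97 and ≈ 99%) demonstrates that the
pipeline — preprocessing, tokenization, conditioning, training, decoding,
metrics — is implemented correctly and that the architecture can learn
order-preserving code emission, context-dependent rules, year drift, and
calibrated confidence.  It does not demonstrate performance on real
clinical language: the synthetic lexicon has no synonymy, misspelling
variety, or long-tail code distribution, and a corpus of millions of real
certificates with a 5,000-code vocabulary is orders of magnitude harder.
Headline numbers from full-scale corpora are therefore not comparable to
the synthetic ones; what does transfer is directional behaviour — e.g.
rejecting low-confidence predictions raises F on the accepted subset, and
recall drops against database truth on `!`-containing certificates because
the database contains codes the text cannot support.

## Numerical and degenerate-input choices

* float32 training; attention masks are additive −1e9; softmax is
  max-subtracted; ensemble probabilities are floored at 1e-30 before log.
* Training aborts with a diagnostic if the loss becomes non-finite.
* Empty certificate lines contribute neither tokens nor separators; a
  certificate must have at least one non-empty line.
* Unknown words map to UNK; `!` has a dedicated reserved id.
* Targets longer than `max_target_len` raise at encoding time, naming the
  certificate.
* The per-stage pipeline derives every stage seed from the master seed by
  hashing, writes a manifest (config hash, seeds, input hashes, version)
  next to each output, and never mutates its inputs.

## Known limitations

* No line-level realignment of predictions (the flat backward target is
  the contract); no underlying-cause-of-death selection.
* The coder cannot predict codes hidden behind `!` — by design the
  benchmark measures the resulting bias rather than papering over it.
* The NumPy implementation targets clarity and determinism over speed; it
  is not suited to corpora beyond ~10⁵ certificates.
* Chapter validity is syntactic plus range membership; no dictionary of
  the ~14k real code labels ships with the package, so syntactically valid
  but unassigned codes within a chapter range are accepted.
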