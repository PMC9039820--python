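"""Seeded synthetic death-certificate corpora with a rule-based coding oracle.

Real mortality corpora are not redistributable, so end-to-end experiments
here run on generated certificates whose text is a pseudo-language with a
*known* phrase-to-code lexicon.  The generator reproduces the structural
pathologies that make the real coding task interesting:

* five part-1 lines plus one part-2 line, with later lines rarely used;
* a hard cap of 20 ICD-10 codes per certificate;
* line-level misalignment, where one line's codes are stored prepended to
  the immediately preceding filled line's sequence;
* unreadable words on paper-origin certificates, replaced by ``!`` in the
  text while the database still stores the codes a human coder inferred;
* a ~90/10 paper/electronic origin mix;
* coding rules that drift across years; and
* one context-dependent rule: a "hematoma-like" trigger phrase codes into
  the circulatory chapter (9) by default but into the injury chapter (19)
  whenever an external-cause code (chapter 20) was already emitted earlier
  in the backward-concatenated output.

Each phrase starts with a unique head word, so the oracle parses text
deterministically by greedy head-word lookup; filler words carry no codes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .certificates import (
    AGE_CLASSES,
    N_LINES,
    MAX_CODES,
    AuxiliaryVariables,
    CertificateCodes,
    CertificateText,
    DeathCertificate,
    UNREADABLE,
)
from .icd10 import ICDCode, chapter_of, chapter_table, parse_code

__all__ = [
    "LexiconEntry",
    "ContextRule",
    "YearDriftRule",
    "RuleGrammar",
    "NoiseConfig",
    "CertificatePair",
    "SplitCorpus",
    "build_grammar",
    "oracle_code",
    "generate_certificate",
    "generate_corpus",
]

DEFAULT_YEARS = (2011, 2012, 2013, 2014, 2015, 2016)


@dataclass(frozen=True)
class LexiconEntry:
    phrase: tuple[str, ...]
    codes: tuple[ICDCode, ...]


@dataclass(frozen=True)
class ContextRule:
    """Chapter-9-vs-19 choice conditioned on a prior external-cause code."""

    trigger_head: str
    default_code: ICDCode  # chapter 9
    alternate_code: ICDCode  # chapter 19


@dataclass(frozen=True)
class YearDriftRule:
    """In ``years``, ``phrase_head``'s first code is replaced by ``alt_code``."""

    phrase_head: str
    years: tuple[int, ...]
    alt_code: ICDCode


@dataclass
class RuleGrammar:
    lexicon: list[LexiconEntry]
    context_rules: list[ContextRule]
    year_drift: list[YearDriftRule]
    filler_words: list[str]
    code_universe: set[str]
    years: tuple[int, ...] = DEFAULT_YEARS

    def __post_init__(self) -> None:
        heads = [e.phrase[0] for e in self.lexicon]
        if len(heads) != len(set(heads)):
            raise ValueError("lexicon phrase heads must be unique")
        self._by_head = {e.phrase[0]: e for e in self.lexicon}
        self._context_by_head = {r.trigger_head: r for r in self.context_rules}
        self._drift = {(r.phrase_head, y): r.alt_code for r in self.year_drift for y in r.years}
        self.external_heads = [
            e.phrase[0]
            for e in self.lexicon
            if any(chapter_of(c).index == 20 for c in e.codes)
        ]

    def entry(self, head: str) -> LexiconEntry | None:
        return self._by_head.get(head)

    def codes_for(self, head: str, year: int, external_seen: bool) -> tuple[ICDCode, ...]:
        """Codes a coder writes for the phrase at ``head`` in context."""
        rule = self._context_by_head.get(head)
        if rule is not None:
            return (rule.alternate_code if external_seen else rule.default_code,)
        entry = self._by_head[head]
        alt = self._drift.get((head, year))
        if alt is not None:
            return (alt,) + entry.codes[1:]
        return entry.codes

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "lexicon": [
                    {"phrase": list(e.phrase), "codes": [c.text for c in e.codes]}
                    for e in self.lexicon
                ],
                "context_rules": [
                    {
                        "trigger_head": r.trigger_head,
                        "default_code": r.default_code.text,
                        "alternate_code": r.alternate_code.text,
                    }
                    for r in self.context_rules
                ],
                "year_drift": [
                    {
                        "phrase_head": r.phrase_head,
                        "years": list(r.years),
                        "alt_code": r.alt_code.text,
                    }
                    for r in self.year_drift
                ],
                "filler_words": self.filler_words,
                "code_universe": sorted(self.code_universe),
                "years": list(self.years),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "RuleGrammar":
        d = json.loads(text)
        return cls(
            lexicon=[
                LexiconEntry(tuple(e["phrase"]), tuple(parse_code(c) for c in e["codes"]))
                for e in d["lexicon"]
            ],
            context_rules=[
                ContextRule(
                    r["trigger_head"],
                    parse_code(r["default_code"]),
                    parse_code(r["alternate_code"]),
                )
                for r in d["context_rules"]
            ],
            year_drift=[
                YearDriftRule(r["phrase_head"], tuple(r["years"]), parse_code(r["alt_code"]))
                for r in d["year_drift"]
            ],
            filler_words=list(d["filler_words"]),
            code_universe=set(d["code_universe"]),
            years=tuple(d["years"]),
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Corruption probabilities mirroring the observed database pathologies."""

    p_misalign: float = 0.02
    p_unreadable_paper: float = 0.10
    p_paper_origin: float = 0.90
    p_typo_electronic: float = 0.0
    # distribution of total filled lines (1..6)
    max_lines_filled: tuple[float, ...] = (0.15, 0.25, 0.25, 0.15, 0.12, 0.08)

    def __post_init__(self) -> None:
        probs = (
            self.p_misalign,
            self.p_unreadable_paper,
            self.p_paper_origin,
            self.p_typo_electronic,
            *self.max_lines_filled,
        )
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if len(self.max_lines_filled) != N_LINES:
            raise ValueError(f"max_lines_filled needs {N_LINES} weights")
        if abs(sum(self.max_lines_filled) - 1.0) > 1e-9:
            raise ValueError("max_lines_filled must sum to 1")


# ---------------------------------------------------------------------------
# Grammar construction
# ---------------------------------------------------------------------------

_CONSONANTS = "bcdfglmnprstv"
_VOWELS = "aeiou"

# chapters cycled when drawing the code universe, most prevalent first
_CHAPTER_CYCLE = (9, 18, 2, 10, 4, 6, 5, 11, 21, 14, 20, 1, 19, 3, 13, 12, 16, 17, 7, 22, 8, 15)


def _all_stems_by_chapter() -> dict[int, list[str]]:
    stems: dict[int, list[str]] = {ch.index: [] for ch in chapter_table()}
    for letter in "ABCDEFGHIJKLMNOPQRSTUVWXYZ":
        for num in range(100):
            stem = f"{letter}{num:02d}"
            for ch in chapter_table():
                if ch.contains(stem):
                    stems[ch.index].append(stem)
                    break
    return stems


def _make_word(rng: np.random.Generator, used: set[str]) -> str:
    while True:
        n_syll = int(rng.integers(2, 4))
        w = "".join(
            _CONSONANTS[int(rng.integers(len(_CONSONANTS)))]
            + _VOWELS[int(rng.integers(len(_VOWELS)))]
            for _ in range(n_syll)
        )
        if w not in used:
            used.add(w)
            return w


def build_grammar(
    n_phrases: int,
    n_codes: int,
    seed: int,
    n_context_rules: int = 1,
    n_drift_rules: int = 1,
    years: Sequence[int] = DEFAULT_YEARS,
) -> RuleGrammar:
    """Build a deterministic phrase→code grammar spanning ≥10 chapters."""
    if n_codes < 50:
        raise ValueError("n_codes must be at least 50")
    if n_phrases < n_codes:
        raise ValueError("n_phrases must be at least n_codes")
    if n_context_rules < 1:
        raise ValueError("at least one context rule is required")
    if n_drift_rules < 1:
        raise ValueError("at least one year-drift rule is required")

    rng = np.random.default_rng(seed)
    stems_by_chapter = _all_stems_by_chapter()

    # draw the code universe, cycling chapters so ≥10 are covered
    universe: list[ICDCode] = []
    seen: set[str] = set()
    ci = 0
    while len(universe) < n_codes:
        chap = _CHAPTER_CYCLE[ci % len(_CHAPTER_CYCLE)]
        ci += 1
        stems = stems_by_chapter[chap]
        stem = stems[int(rng.integers(len(stems)))]
        text = stem + (str(int(rng.integers(10))) if rng.random() < 0.7 else "")
        if text not in seen:
            seen.add(text)
            universe.append(parse_code(text))

    by_chapter: dict[int, list[ICDCode]] = {}
    for c in universe:
        by_chapter.setdefault(chapter_of(c).index, []).append(c)
    for needed in (9, 19, 20):
        if needed not in by_chapter:  # cycle guarantees these for n_codes ≥ 50
            raise ValueError(f"code universe missing chapter {needed}")

    used_words: set[str] = set()
    fillers = [_make_word(rng, used_words) for _ in range(12)]
    tails = [_make_word(rng, used_words) for _ in range(40)]

    lexicon: list[LexiconEntry] = []

    def _phrase_words() -> tuple[str, ...]:
        head = _make_word(rng, used_words)
        n_tail = int(rng.choice([0, 1, 2], p=[0.45, 0.4, 0.15]))
        tail = tuple(tails[int(rng.integers(len(tails)))] for _ in range(n_tail))
        return (head,) + tail

    # context rules: trigger phrases whose coding depends on prior chapter-20
    context_rules: list[ContextRule] = []
    for _ in range(n_context_rules):
        ch9 = by_chapter[9][int(rng.integers(len(by_chapter[9])))]
        ch19 = by_chapter[19][int(rng.integers(len(by_chapter[19])))]
        phrase = _phrase_words()
        lexicon.append(LexiconEntry(phrase, (ch9,)))
        context_rules.append(ContextRule(phrase[0], ch9, ch19))

    # guarantee at least two external-cause phrases
    ext_codes = by_chapter[20]
    for k in range(2):
        phrase = _phrase_words()
        lexicon.append(LexiconEntry(phrase, (ext_codes[k % len(ext_codes)],)))

    # every universe code appears as some phrase's first code (coverage),
    # then extra phrases reuse random codes
    remaining = [c for c in universe]
    rng.shuffle(remaining)  # type: ignore[arg-type]
    while len(lexicon) < n_phrases:
        if remaining:
            first = remaining.pop()
        else:
            first = universe[int(rng.integers(len(universe)))]
        n_extra = int(rng.choice([0, 1, 2], p=[0.6, 0.3, 0.1]))
        extras = tuple(universe[int(rng.integers(len(universe)))] for _ in range(n_extra))
        lexicon.append(LexiconEntry(_phrase_words(), (first,) + extras))

    # year drift: in the later half of the year range a phrase codes differently
    drift_rules: list[YearDriftRule] = []
    drift_candidates = [
        e for e in lexicon
        if e.phrase[0] not in {r.trigger_head for r in context_rules}
        and not any(chapter_of(c).index == 20 for c in e.codes)
    ]
    years = tuple(int(y) for y in years)
    late_years = years[len(years) // 2:]
    for k in range(n_drift_rules):
        entry = drift_candidates[int(rng.integers(len(drift_candidates)))]
        drift_candidates = [e for e in drift_candidates if e.phrase[0] != entry.phrase[0]]
        old = entry.codes[0]
        pool = [c for c in by_chapter[chapter_of(old).index] if c.text != old.text]
        alt = pool[int(rng.integers(len(pool)))] if pool else universe[0]
        drift_rules.append(YearDriftRule(entry.phrase[0], late_years, alt))

    return RuleGrammar(
        lexicon=lexicon,
        context_rules=context_rules,
        year_drift=drift_rules,
        filler_words=fillers,
        code_universe={c.text for c in universe},
        years=years,
    )


# ---------------------------------------------------------------------------
# Coding oracle
# ---------------------------------------------------------------------------


def oracle_code(
    text_lines: Sequence[str],
    aux: AuxiliaryVariables,
    grammar: RuleGrammar,
    clean_lines: Sequence[str] | None = None,
    strict: bool = True,
) -> tuple[CertificateCodes, CertificateCodes]:
    """Code certificate text the way the human/expert process would.

    Lines are processed in backward order (part 2 first); phrases emit their
    lexicon codes, with year drift applied and context rules resolved
    against the codes already emitted in the backward stream.  ``!`` words
    contribute nothing — the first return value is this *visible* truth.
    The second value is the *database* truth: when ``clean_lines`` (the
    pre-corruption text) is supplied it is coded instead, so codes hidden
    behind ``!`` reappear, emulating coders who infer unreadable words from
    context; otherwise the two channels coincide.
    """
    visible = _code_lines(text_lines, aux, grammar, strict=strict)
    if clean_lines is None:
        database = visible
    else:
        database = _code_lines(clean_lines, aux, grammar, strict=strict)
    return visible, database


def _code_lines(
    text_lines: Sequence[str],
    aux: AuxiliaryVariables,
    grammar: RuleGrammar,
    strict: bool = True,
) -> CertificateCodes:
    per_line: list[tuple[ICDCode, ...]] = [()] * N_LINES
    external_seen = False
    fillers = set(grammar.filler_words)
    for idx in range(N_LINES - 1, -1, -1):
        words = text_lines[idx].split()
        line_codes: list[ICDCode] = []
        i = 0
        while i < len(words):
            w = words[i]
            if w == UNREADABLE or w in fillers:
                i += 1
                continue
            entry = grammar.entry(w)
            if entry is None:
                if strict:
                    raise ValueError(f"unknown phrase head {w!r} on line {idx + 1}")
                i += 1
                continue
            codes = grammar.codes_for(w, aux.year, external_seen)
            line_codes.extend(codes)
            if any(chapter_of(c).index == 20 for c in codes):
                external_seen = True
            i += len(entry.phrase)
        per_line[idx] = tuple(line_codes)
    return CertificateCodes(tuple(per_line))


# ---------------------------------------------------------------------------
# Certificate and corpus generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CertificatePair:
    """A pristine certificate and its database-style counterpart."""

    clean: DeathCertificate
    db_style: DeathCertificate


# age sampling weights rise toward old age (mortality-shaped)
_AGE_WEIGHTS = np.array([0.5, 0.3, 0.2] + [0.3 + 0.15 * k for k in range(19)])
_AGE_WEIGHTS = _AGE_WEIGHTS / _AGE_WEIGHTS.sum()

P_CONTEXT_TRIGGER = 0.25  # a context-rule trigger phrase appears on the cert
P_EXTERNAL_GIVEN_TRIGGER = 0.5  # … with an external cause earlier in backward order


def _sample_aux(grammar: RuleGrammar, noise: NoiseConfig, rng: np.random.Generator) -> AuxiliaryVariables:
    return AuxiliaryVariables(
        gender=int(rng.integers(1, 3)),
        year=int(grammar.years[int(rng.integers(len(grammar.years)))]),
        age_class=AGE_CLASSES[int(rng.choice(len(AGE_CLASSES), p=_AGE_WEIGHTS))],
        origin="paper" if rng.random() < noise.p_paper_origin else "electronic",
    )


def generate_certificate(
    grammar: RuleGrammar,
    noise: NoiseConfig,
    seed: int | np.random.Generator,
    cert_id: str = "c0",
) -> CertificatePair:
    """Generate one clean/database-style certificate pair.

    The database version differs from the clean one only by (i) one-hop
    code misalignment with probability ``p_misalign`` and (ii), for paper
    origin with probability ``p_unreadable_paper``, one phrase's words
    replaced by ``!`` in the text while the database codes keep the hidden
    phrase's codes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    aux = _sample_aux(grammar, noise, rng)

    ordinary = [
        e.phrase[0]
        for e in grammar.lexicon
        if e.phrase[0] not in {r.trigger_head for r in grammar.context_rules}
        and e.phrase[0] not in grammar.external_heads
    ]

    total_lines = int(rng.choice(np.arange(1, N_LINES + 1), p=np.asarray(noise.max_lines_filled)))
    part2 = total_lines >= 2 and rng.random() < 0.5
    n_part1 = min(total_lines - (1 if part2 else 0), N_LINES - 1)
    filled = list(range(n_part1)) + ([N_LINES - 1] if part2 else [])

    # each filled line: 1-2 phrases drawn from the ordinary lexicon
    line_heads: dict[int, list[str]] = {
        idx: [ordinary[int(rng.integers(len(ordinary)))] for _ in range(int(rng.choice([1, 2], p=[0.65, 0.35])))]
        for idx in filled
    }

    # context-rule event: place a trigger, optionally with an external cause
    # earlier in backward order (a later line, or before it on the same line)
    if grammar.context_rules and rng.random() < P_CONTEXT_TRIGGER:
        rule = grammar.context_rules[int(rng.integers(len(grammar.context_rules)))]
        tline = filled[int(rng.integers(len(filled)))]
        line_heads[tline].append(rule.trigger_head)
        if rng.random() < P_EXTERNAL_GIVEN_TRIGGER:
            ext = grammar.external_heads[int(rng.integers(len(grammar.external_heads)))]
            later = [i for i in filled if i > tline]
            if later and rng.random() < 0.7:
                line_heads[later[int(rng.integers(len(later)))]].insert(0, ext)
            else:
                line_heads[tline].insert(0, ext)

    # assemble text, respecting the 20-code cap
    lines = [""] * N_LINES
    budget = MAX_CODES
    fillers = grammar.filler_words
    for idx in sorted(line_heads):
        words: list[str] = []
        for head in line_heads[idx]:
            entry = grammar.entry(head)
            cost = len(entry.codes)
            if budget - cost < 0:
                continue
            budget -= cost
            words.extend(entry.phrase)
            if rng.random() < 0.25:
                words.append(fillers[int(rng.integers(len(fillers)))])
        if not words:  # keep the line non-empty without spending code budget
            words = [fillers[int(rng.integers(len(fillers)))]]
        lines[idx] = " ".join(words)
    if not any(lines):
        head = ordinary[int(rng.integers(len(ordinary)))]
        lines[0] = " ".join(grammar.entry(head).phrase)

    visible, _ = oracle_code(lines, aux, grammar)
    clean = DeathCertificate(
        id=cert_id, text=CertificateText(tuple(lines)), aux=aux, codes=visible
    )

    # database-style corruption
    db_lines = list(lines)
    db_per_line = list(visible.per_line)

    if aux.origin == "paper" and rng.random() < noise.p_unreadable_paper:
        # hide one coded phrase: every word of it becomes "!"
        candidates = []
        for idx in sorted(line_heads):
            pos = 0
            words = db_lines[idx].split()
            while pos < len(words):
                entry = grammar.entry(words[pos])
                # hiding a trigger or external-cause phrase could *change*
                # other visible codes via the context rule, not just drop
                # codes; keep those readable
                protected = {r.trigger_head for r in grammar.context_rules} | set(
                    grammar.external_heads
                )
                if entry is not None and entry.phrase[0] not in protected:
                    candidates.append((idx, pos, len(entry.phrase)))
                    pos += len(entry.phrase)
                else:
                    pos += 1
        if candidates:
            idx, pos, plen = candidates[int(rng.integers(len(candidates)))]
            words = db_lines[idx].split()
            words[pos:pos + plen] = [UNREADABLE] * plen
            db_lines[idx] = " ".join(words)

    if rng.random() < noise.p_misalign:
        coded = [i for i in range(N_LINES) if db_per_line[i]]
        movable = [
            k for k in coded
            if any(j < k and lines[j] for j in range(N_LINES))
        ]
        if movable:
            k = movable[int(rng.integers(len(movable)))]
            j = max(jj for jj in range(k) if lines[jj])
            db_per_line[j] = tuple(db_per_line[k]) + tuple(db_per_line[j])
            db_per_line[k] = ()

    db_style = DeathCertificate(
        id=cert_id,
        text=CertificateText(tuple(db_lines)),
        aux=aux,
        codes=CertificateCodes(tuple(db_per_line)),
    )
    return CertificatePair(clean=clean, db_style=db_style)


@dataclass
class SplitCorpus:
    train: list[CertificatePair]
    validation: list[CertificatePair]
    test: list[CertificatePair]

    def split(self, name: str) -> list[CertificatePair]:
        return getattr(self, name)


def generate_corpus(
    n: int,
    grammar: RuleGrammar,
    noise: NoiseConfig,
    seed: int,
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> SplitCorpus:
    """Generate ``n`` certificate pairs split per-year into train/val/test.

    Validation and test certificates are excluded from each year stratum
    separately, so every split covers every year; splits have disjoint ids
    and the whole procedure is deterministic under ``seed``.
    """
    if abs(sum(split_fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    pairs = [
        generate_certificate(grammar, noise, rng, cert_id=f"c{i:06d}") for i in range(n)
    ]

    by_year: dict[int, list[CertificatePair]] = {}
    for p in pairs:
        by_year.setdefault(p.clean.aux.year, []).append(p)

    f_train, f_val, f_test = split_fractions
    train: list[CertificatePair] = []
    val: list[CertificatePair] = []
    test: list[CertificatePair] = []
    for year in sorted(by_year):
        group = by_year[year]
        order = rng.permutation(len(group))
        n_val = int(round(f_val * len(group)))
        n_test = int(round(f_test * len(group)))
        if (f_val > 0 and n_val < 1) or (f_test > 0 and n_test < 1):
            raise ValueError(
                f"n={n} too small to stratify year {year} into all splits"
            )
        val.extend(group[i] for i in order[:n_val])
        test.extend(group[i] for i in order[n_val:n_val + n_test])
        train.extend(group[i] for i in order[n_val + n_test:])
    return SplitCorpus(train=train, validation=val, test=test)
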