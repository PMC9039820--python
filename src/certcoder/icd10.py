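"""ICD-10 codes, WHO chapters, and the hierarchical code tokenizer.

ICD-10 codes are short alphanumeric strings — one uppercase letter followed
by two digits, with an optional fourth alphanumeric character (``I64``,
``G819``).  The 14k-entity classification is organised into 22 chapters,
each covering an inclusive range of three-character stems (circulatory
disease is chapter 9, ``I00``–``I99``; external causes are chapter 20,
``V01``–``Y98``).  Validity here is syntactic plus chapter-range membership;
no code-label dictionary is shipped.

The :class:`CodeTokenizer` exploits the hierarchy of the classification:
codes frequent in a training corpus are kept as single target tokens
(``"I10-"``), while rare four-character codes decompose into their stem plus
a terminal suffix token (``"I659"`` → ``["I65", "9-"]``), so the decoder can
generalise across codes sharing a stem.  The trailing ``-`` marks the end of
a code, which makes decoding a deterministic, lossless inverse of encoding.
"""

from __future__ import annotations

import csv
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

__all__ = [
    "ICDCode",
    "Chapter",
    "CodeTokenizer",
    "CodeValidationError",
    "CodeDecodeError",
    "parse_code",
    "chapter_of",
    "chapter_table",
    "fit_code_tokenizer",
    "encode_codes",
    "decode_codes",
]

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]?$")


class CodeValidationError(ValueError):
    """Raised when a string is not a well-formed, in-range ICD-10 code."""


class CodeDecodeError(ValueError):
    """Raised when a token stream cannot be regrouped into codes."""


@dataclass(frozen=True, order=True)
class ICDCode:
    """A validated ICD-10 code (uppercase, 3 or 4 characters)."""

    text: str

    def __post_init__(self) -> None:
        if not _CODE_RE.match(self.text):
            raise CodeValidationError(
                f"{self.text!r} is not a valid ICD-10 code "
                "(expected 1 uppercase letter, 2 digits, optional 4th alphanumeric)"
            )

    @property
    def stem(self) -> str:
        """First three characters; a well-formed code in its own right."""
        return self.text[:3]

    @property
    def suffix(self) -> str:
        """Fourth character, or '' for three-character codes."""
        return self.text[3:]

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.text


@dataclass(frozen=True)
class Chapter:
    """One of the 22 WHO chapters, defined by inclusive stem ranges."""

    index: int
    label: str
    stem_start: str
    stem_end: str

    def contains(self, stem: str) -> bool:
        return self.stem_start <= stem <= self.stem_end


def chapter_table() -> tuple[Chapter, ...]:
    """The packaged 22-chapter boundary table, ordered by chapter index."""
    return _CHAPTERS


def _load_chapters() -> tuple[Chapter, ...]:
    path = resources.files("certcoder.data").joinpath("icd10_chapters.csv")
    with path.open("r", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    chapters = tuple(
        Chapter(
            index=int(r["chapter_index"]),
            label=r["label"],
            stem_start=r["stem_start"],
            stem_end=r["stem_end"],
        )
        for r in rows
    )
    return tuple(sorted(chapters, key=lambda c: c.index))


_CHAPTERS = _load_chapters()


def parse_code(raw: str) -> ICDCode:
    """Parse and validate an ICD-10 code string.

    Input is whitespace-trimmed and uppercased; the result must match the
    syntactic pattern and fall inside one of the 22 chapter ranges.
    """
    if raw is None or not str(raw).strip():
        raise CodeValidationError("empty string is not an ICD-10 code")
    text = str(raw).strip().upper()
    code = ICDCode(text)
    if _find_chapter(code.stem) is None:
        raise CodeValidationError(
            f"{text!r} falls outside every ICD-10 chapter range"
        )
    return code


def _find_chapter(stem: str) -> Chapter | None:
    for ch in _CHAPTERS:
        if ch.contains(stem):
            return ch
    return None


def chapter_of(code: ICDCode | str) -> Chapter:
    """Map a valid code to its unique WHO chapter."""
    if isinstance(code, str):
        code = parse_code(code)
    ch = _find_chapter(code.stem)
    if ch is None:  # parse_code guarantees this cannot happen
        raise CodeValidationError(f"{code.text!r} has no chapter")
    return ch


def is_valid_code(raw: str) -> bool:
    """True if ``raw`` parses as an in-range ICD-10 code."""
    try:
        parse_code(raw)
        return True
    except CodeValidationError:
        return False


# ---------------------------------------------------------------------------
# Hierarchical code tokenizer
# ---------------------------------------------------------------------------

END_MARK = "-"


@dataclass
class CodeTokenizer:
    """Frequency-thresholded hierarchical tokenizer for code sequences.

    Codes whose corpus frequency reaches ``frequency_threshold`` become
    single full-code tokens (the code text followed by the terminal ``-``).
    Every other code is emitted as its three-character stem token followed
    by a closing token: ``"9-"`` for a fourth character, or the bare ``"-"``
    marker for three-character codes.  A token therefore ends a code iff it
    carries the terminal marker.
    """

    full_code_vocab: set[str] = field(default_factory=set)
    stem_vocab: set[str] = field(default_factory=set)
    suffix_vocab: set[str] = field(default_factory=set)
    frequency_threshold: int = 1

    def encode(self, codes: Sequence[ICDCode | str]) -> list[str]:
        tokens: list[str] = []
        for c in codes:
            code = c if isinstance(c, ICDCode) else parse_code(c)
            if code.text in self.full_code_vocab:
                tokens.append(code.text + END_MARK)
            else:
                tokens.append(code.stem)
                tokens.append(code.suffix + END_MARK)
        return tokens

    def decode(self, tokens: Sequence[str]) -> list[ICDCode]:
        codes: list[ICDCode] = []
        pending: str | None = None
        for tok in tokens:
            if tok.endswith(END_MARK):
                body = tok[: -len(END_MARK)]
                try:
                    if pending is None:
                        # full-code token (or bare marker, which is malformed)
                        if not body:
                            raise CodeDecodeError("terminal marker with no pending stem")
                        codes.append(parse_code(body))
                    else:
                        codes.append(parse_code(pending + body))
                        pending = None
                except CodeValidationError as exc:
                    raise CodeDecodeError(
                        f"token {tok!r} does not close a valid code: {exc}"
                    ) from exc
            else:
                if pending is not None:
                    raise CodeDecodeError(
                        f"stem {pending!r} left open before stem {tok!r}"
                    )
                pending = tok
        if pending is not None:
            raise CodeDecodeError(f"dangling stem {pending!r} at end of stream")
        return codes

    def token_vocabulary(self) -> list[str]:
        """All tokens this tokenizer can emit, sorted for reproducibility."""
        toks = {c + END_MARK for c in self.full_code_vocab}
        toks |= self.stem_vocab
        toks |= self.suffix_vocab
        return sorted(toks)

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "full_code_vocab": sorted(self.full_code_vocab),
                "stem_vocab": sorted(self.stem_vocab),
                "suffix_vocab": sorted(self.suffix_vocab),
                "frequency_threshold": self.frequency_threshold,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CodeTokenizer":
        d = json.loads(text)
        return cls(
            full_code_vocab=set(d["full_code_vocab"]),
            stem_vocab=set(d["stem_vocab"]),
            suffix_vocab=set(d["suffix_vocab"]),
            frequency_threshold=int(d["frequency_threshold"]),
        )


def fit_code_tokenizer(
    code_corpus: Iterable[Sequence[ICDCode | str]],
    frequency_threshold: int = 10,
) -> CodeTokenizer:
    """Fit the tokenizer's vocabularies on a corpus of code sequences.

    Stems and suffixes of *all* corpus codes always enter the vocabulary so
    that any code built from seen stems remains encodable; only codes seen
    at least ``frequency_threshold`` times are additionally kept whole.
    """
    if frequency_threshold < 0:
        raise ValueError("frequency_threshold must be non-negative")
    counts: Counter[str] = Counter()
    stems: set[str] = set()
    suffixes: set[str] = set()
    for seq in code_corpus:
        for c in seq:
            code = c if isinstance(c, ICDCode) else parse_code(c)
            counts[code.text] += 1
            stems.add(code.stem)
            suffixes.add(code.suffix + END_MARK)
    full = {c for c, n in counts.items() if n >= frequency_threshold}
    # decoding generality: all ten digit suffixes plus the bare marker
    suffixes |= {str(d) + END_MARK for d in range(10)}
    suffixes.add(END_MARK)
    return CodeTokenizer(
        full_code_vocab=full,
        stem_vocab=stems,
        suffix_vocab=suffixes,
        frequency_threshold=frequency_threshold,
    )


def encode_codes(tok: CodeTokenizer, codes: Sequence[ICDCode | str]) -> list[str]:
    """Functional alias for :meth:`CodeTokenizer.encode`."""
    return tok.encode(codes)


def decode_codes(tok: CodeTokenizer, tokens: Sequence[str]) -> list[ICDCode]:
    """Functional alias for :meth:`CodeTokenizer.decode`."""
    return tok.decode(tokens)
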