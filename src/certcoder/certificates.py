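"""Death-certificate data model, I/O, normalization and backward concatenation.

A certificate carries six free-text lines — five for part 1 of the WHO
causal-chain form (immediate causes first, underlying causes last) and one
for part 2 (contributing conditions) — four auxiliary variables (gender,
year of death, age class, paper/electronic origin), and, when labelled, one
ICD-10 code sequence per line.

The database the model trains on stores codes per line, but human coders
occasionally move a line's codes to the *front* of the preceding line's
sequence (misalignment).  Concatenating lines in backward order — part 2
first, then part-1 lines from last to first — yields a flat code target
that is invariant under this corruption while preserving within-line code
order, which is why both model input and target use that order.
"""

from __future__ import annotations

import csv
import json
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .icd10 import CodeValidationError, ICDCode, parse_code

__all__ = [
    "AGE_CLASSES",
    "N_LINES",
    "AuxiliaryVariables",
    "CertificateText",
    "CertificateCodes",
    "DeathCertificate",
    "TextVocabulary",
    "SchemaError",
    "read_certificates",
    "write_certificates",
    "backward_concatenate",
    "normalize_text",
    "fit_text_vocab",
    "tokenize_text",
]

N_LINES = 6  # lines 1-5 = part 1, line 6 = part 2
MAX_CODES = 20
ORIGINS = ("paper", "electronic")
UNREADABLE = "!"

# 22 age classes: two infant bins, then 5-year intervals with an open top bin
AGE_CLASSES: tuple[str, ...] = (
    "<28d",
    "28d-<1y",
    "1-4",
    *(f"{a}-{a + 4}" for a in range(5, 95, 5)),
    "95+",
)


class SchemaError(ValueError):
    """A record violates the certificate schema; names record and field."""

    def __init__(self, message: str, record: object = None, field_name: str | None = None):
        parts = []
        if record is not None:
            parts.append(f"record {record}")
        if field_name:
            parts.append(f"field {field_name!r}")
        prefix = " / ".join(parts)
        super().__init__(f"{prefix}: {message}" if prefix else message)
        self.record = record
        self.field_name = field_name


@dataclass(frozen=True)
class AuxiliaryVariables:
    """The four exogenous variables conditioning the coder."""

    gender: int
    year: int
    age_class: str
    origin: str

    def __post_init__(self) -> None:
        if self.gender not in (1, 2):
            raise SchemaError(f"gender must be 1 or 2, got {self.gender!r}", field_name="gender")
        if self.age_class not in AGE_CLASSES:
            raise SchemaError(
                f"unknown age_class {self.age_class!r}", field_name="age_class"
            )
        if self.origin not in ORIGINS:
            raise SchemaError(
                f"origin must be one of {ORIGINS}, got {self.origin!r}", field_name="origin"
            )


@dataclass(frozen=True)
class CertificateText:
    """Six ordered free-text lines; empty strings mark unused lines."""

    lines: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lines) != N_LINES:
            raise SchemaError(
                f"expected {N_LINES} lines, got {len(self.lines)}", field_name="lines"
            )
        if not any(l.strip() for l in self.lines):
            raise SchemaError("all lines empty", field_name="lines")


@dataclass(frozen=True)
class CertificateCodes:
    """Per-line ground-truth ICD-10 code sequences."""

    per_line: tuple[tuple[ICDCode, ...], ...]

    def __post_init__(self) -> None:
        if len(self.per_line) != N_LINES:
            raise SchemaError(
                f"expected {N_LINES} code lines, got {len(self.per_line)}",
                field_name="codes",
            )
        total = sum(len(seq) for seq in self.per_line)
        if total > MAX_CODES:
            raise SchemaError(
                f"{total} codes exceed the {MAX_CODES}-code cap", field_name="codes"
            )

    def flat(self) -> tuple[ICDCode, ...]:
        """All codes in forward line order (line 1 … line 6)."""
        return tuple(c for seq in self.per_line for c in seq)


@dataclass(frozen=True)
class DeathCertificate:
    id: str
    text: CertificateText
    aux: AuxiliaryVariables
    codes: CertificateCodes | None = None
    extra: dict = field(default_factory=dict, compare=False)


# ---------------------------------------------------------------------------
# I/O — JSONL and CSV round-trippable schema
# ---------------------------------------------------------------------------


def _codes_from_lists(lists: Sequence[Sequence[str]], record: object) -> CertificateCodes:
    try:
        per_line = tuple(tuple(parse_code(c) for c in seq) for seq in lists)
        return CertificateCodes(per_line)
    except (CodeValidationError, SchemaError) as exc:
        raise SchemaError(str(exc), record=record, field_name="codes") from exc


def cert_to_dict(cert: DeathCertificate) -> dict:
    d = {
        "id": cert.id,
        "gender": cert.aux.gender,
        "year": cert.aux.year,
        "age_class": cert.aux.age_class,
        "origin": cert.aux.origin,
        "lines": list(cert.text.lines),
    }
    if cert.codes is not None:
        d["codes"] = [[c.text for c in seq] for seq in cert.codes.per_line]
    d.update(cert.extra)
    return d


_KNOWN_FIELDS = {"id", "gender", "year", "age_class", "origin", "lines", "codes"}


def cert_from_dict(d: dict, record: object = None) -> DeathCertificate:
    for name in ("id", "gender", "year", "age_class", "origin", "lines"):
        if name not in d:
            raise SchemaError("missing field", record=record, field_name=name)
    try:
        aux = AuxiliaryVariables(
            gender=int(d["gender"]),
            year=int(d["year"]),
            age_class=str(d["age_class"]),
            origin=str(d["origin"]),
        )
        text = CertificateText(tuple(str(l) for l in d["lines"]))
    except SchemaError as exc:
        raise SchemaError(str(exc), record=record, field_name=exc.field_name) from exc
    codes = None
    if d.get("codes") is not None:
        codes = _codes_from_lists(d["codes"], record)
    extra = {k: v for k, v in d.items() if k not in _KNOWN_FIELDS}
    return DeathCertificate(id=str(d["id"]), text=text, aux=aux, codes=codes, extra=extra)


def read_certificates(path: str | Path, format: str | None = None) -> list[DeathCertificate]:
    """Read a JSONL or CSV corpus; the format defaults to the file suffix."""
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    certs: list[DeathCertificate] = []
    seen_ids: set[str] = set()
    if fmt == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for i, line in enumerate(fh):
                if not line.strip():
                    continue
                certs.append(cert_from_dict(json.loads(line), record=i))
    elif fmt == "csv":
        with path.open("r", encoding="utf-8", newline="") as fh:
            for i, row in enumerate(csv.DictReader(fh)):
                d: dict = {
                    "id": row["id"],
                    "gender": row["gender"],
                    "year": row["year"],
                    "age_class": row["age_class"],
                    "origin": row["origin"],
                    "lines": [row.get(f"line{k}", "") or "" for k in range(1, N_LINES + 1)],
                }
                code_cols = [row.get(f"codes{k}") for k in range(1, N_LINES + 1)]
                if any(c is not None for c in code_cols):
                    d["codes"] = [(c or "").split() for c in code_cols]
                certs.append(cert_from_dict(d, record=i))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    for i, c in enumerate(certs):
        if c.id in seen_ids:
            raise SchemaError("duplicate id", record=i, field_name="id")
        seen_ids.add(c.id)
    return certs


def write_certificates(
    certs: Iterable[DeathCertificate], path: str | Path, format: str | None = None
) -> None:
    path = Path(path)
    fmt = format or ("csv" if path.suffix.lower() == ".csv" else "jsonl")
    certs = list(certs)
    if fmt == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for c in certs:
                fh.write(json.dumps(cert_to_dict(c), ensure_ascii=False, sort_keys=True))
                fh.write("\n")
    elif fmt == "csv":
        cols = ["id", "gender", "year", "age_class", "origin"]
        cols += [f"line{k}" for k in range(1, N_LINES + 1)]
        has_codes = any(c.codes is not None for c in certs)
        if has_codes:
            cols += [f"codes{k}" for k in range(1, N_LINES + 1)]
        with path.open("w", encoding="utf-8", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for c in certs:
                row = {
                    "id": c.id,
                    "gender": c.aux.gender,
                    "year": c.aux.year,
                    "age_class": c.aux.age_class,
                    "origin": c.aux.origin,
                }
                for k, line in enumerate(c.text.lines, start=1):
                    row[f"line{k}"] = line
                if has_codes:
                    per = c.codes.per_line if c.codes else ((),) * N_LINES
                    for k, seq in enumerate(per, start=1):
                        row[f"codes{k}"] = " ".join(code.text for code in seq)
                w.writerow(row)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Normalization and tokenization
# ---------------------------------------------------------------------------


def normalize_text(line: str, origin: str | None = None) -> str:
    """Lowercase, fold accents, strip punctuation (keeping ``!``), collapse spaces.

    The same policy applies to both origins; the origin itself reaches the
    model as an auxiliary feature rather than through divergent cleaning.
    """
    folded = unicodedata.normalize("NFD", line.lower())
    out_chars = []
    for ch in folded:
        if unicodedata.category(ch) == "Mn":  # combining accent
            continue
        if ch == UNREADABLE or ch.isalnum():
            out_chars.append(ch)
        else:
            out_chars.append(" ")
    return " ".join("".join(out_chars).split())


def backward_concatenate(
    cert: DeathCertificate,
) -> tuple[list[list[str]], list[ICDCode]]:
    """Backward-ordered word blocks and the flat code target.

    Blocks run from part 2 (line 6) down to line 1; empty lines contribute
    nothing.  The target flattens the per-line codes in the same backward
    order, preserving within-line order — the representation under which
    the line-misalignment database artifact is invisible.
    """
    blocks: list[list[str]] = []
    for idx in range(N_LINES - 1, -1, -1):
        words = normalize_text(cert.text.lines[idx], cert.aux.origin).split()
        if words:
            blocks.append(words)
    target: list[ICDCode] = []
    if cert.codes is not None:
        for idx in range(N_LINES - 1, -1, -1):
            target.extend(cert.codes.per_line[idx])
    return blocks, target


@dataclass
class TextVocabulary:
    """Word-level vocabulary with fixed reserved ids.

    Reserved: PAD=0, BOS=1, EOS=2, UNK=3, LINE_SEP=4, "!"=5; learned word
    ids start at 6.
    """

    PAD: int = 0
    BOS: int = 1
    EOS: int = 2
    UNK: int = 3
    SEP: int = 4
    BANG: int = 5

    token_to_id: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return 6 + len(self.token_to_id)

    def id_of(self, word: str) -> int:
        if word == UNREADABLE:
            return self.BANG
        return self.token_to_id.get(word, self.UNK)

    def to_json(self) -> str:
        words = sorted(self.token_to_id, key=self.token_to_id.get)
        return json.dumps({"words": words}, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "TextVocabulary":
        words = json.loads(text)["words"]
        return cls(token_to_id={w: 6 + i for i, w in enumerate(words)})


def fit_text_vocab(
    corpus: Iterable[DeathCertificate], max_size: int | None = None
) -> TextVocabulary:
    """Frequency-ranked word vocabulary over normalized certificate text."""
    from collections import Counter

    counts: Counter[str] = Counter()
    for cert in corpus:
        for line in cert.text.lines:
            for w in normalize_text(line, cert.aux.origin).split():
                if w != UNREADABLE:
                    counts[w] += 1
    limit = None if max_size is None else max(0, max_size - 6)
    ranked = [w for w, _ in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))]
    if limit is not None:
        ranked = ranked[:limit]
    return TextVocabulary(token_to_id={w: 6 + i for i, w in enumerate(ranked)})


def tokenize_text(vocab: TextVocabulary, blocks: Sequence[Sequence[str]]) -> list[int]:
    """Map word blocks to ids with BOS/EOS framing and LINE_SEP between blocks."""
    ids = [vocab.BOS]
    for bi, block in enumerate(blocks):
        if bi > 0:
            ids.append(vocab.SEP)
        ids.extend(vocab.id_of(w) for w in block)
    ids.append(vocab.EOS)
    return ids
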