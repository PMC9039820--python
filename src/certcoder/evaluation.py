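"""Exact-match code-level metrics, bootstrap CIs, per-chapter error rates,
rejection-curve calibration analysis, and the shared-code-removal protocol.

A predicted code counts as a true positive only on an exact match, up to
the fourth character; code order is never penalized, and repeated codes are
matched with multiset semantics (``tp = Σ_c min(count_pred(c),
count_truth(c))``).  Corpus metrics are micro-averaged: TP/FP/FN counts are
pooled over certificates before precision, recall and F are computed, and
95% CIs come from a percentile bootstrap over certificates.

Conventions the definitions leave open, made explicit here: an empty
prediction against an empty truth scores P = R = F = 1; zero TP with any
FP or FN scores 0; chapters with a zero denominator are omitted from the
per-chapter report.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .icd10 import ICDCode, chapter_of, parse_code

__all__ = [
    "MatchCounts",
    "MetricsReport",
    "ChapterReport",
    "RejectionCurve",
    "count_matches",
    "prf",
    "corpus_metrics",
    "per_chapter_rates",
    "rejection_curve",
    "remove_shared_codes",
]

CodeSeq = Sequence[ICDCode | str]


def _texts(codes: CodeSeq) -> list[str]:
    return [c.text if isinstance(c, ICDCode) else parse_code(c).text for c in codes]


@dataclass(frozen=True)
class MatchCounts:
    tp: int
    fp: int
    fn: int

    def __add__(self, other: "MatchCounts") -> "MatchCounts":
        return MatchCounts(self.tp + other.tp, self.fp + other.fp, self.fn + other.fn)


def count_matches(pred: CodeSeq, truth: CodeSeq) -> MatchCounts:
    """TP/FP/FN under exact, order-free, multiset matching."""
    p = Counter(_texts(pred))
    t = Counter(_texts(truth))
    tp = sum(min(p[c], t[c]) for c in p)
    return MatchCounts(tp=tp, fp=sum(p.values()) - tp, fn=sum(t.values()) - tp)


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean from pooled counts."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    if tp == 0 and fp == 0 and fn == 0:
        return 1.0, 1.0, 1.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f


@dataclass(frozen=True)
class MetricsReport:
    precision: float
    recall: float
    f_measure: float
    ci: dict  # metric -> (low, high)
    n_certificates: int
    bootstrap_replicates: int
    seed: int

    def summary(self) -> str:
        rows = []
        for name in ("precision", "recall", "f_measure"):
            lo, hi = self.ci[name]
            rows.append(f"{name:<10} {getattr(self, name):.3f} (95% CI {lo:.3f}-{hi:.3f})")
        rows.append(f"n = {self.n_certificates}, bootstrap B = {self.bootstrap_replicates}")
        return "\n".join(rows)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "n_certificates": self.n_certificates,
            "bootstrap_replicates": self.bootstrap_replicates,
            "seed": self.seed,
        }


def _align(preds: Mapping[str, CodeSeq], truths: Mapping[str, CodeSeq]) -> list[MatchCounts]:
    if set(preds) != set(truths):
        missing = set(truths) ^ set(preds)
        raise ValueError(f"prediction/truth id mismatch: {sorted(missing)[:5]}")
    return [count_matches(preds[k], truths[k]) for k in sorted(preds)]


def corpus_metrics(
    preds: Mapping[str, CodeSeq],
    truths: Mapping[str, CodeSeq],
    B: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Micro-averaged P/R/F with percentile-bootstrap 95% CIs.

    Resampling is at the certificate level, with replacement, ``B``
    replicates, deterministic under ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    per_cert = _align(preds, truths)
    pooled = MatchCounts(
        tp=sum(c.tp for c in per_cert),
        fp=sum(c.fp for c in per_cert),
        fn=sum(c.fn for c in per_cert),
    )
    precision, recall, f = prf(pooled)

    arr = np.array([[c.tp, c.fp, c.fn] for c in per_cert], dtype=np.int64)
    rng = np.random.default_rng(seed)
    n = len(per_cert)
    stats = np.empty((B, 3))
    for b in range(B):
        sample = arr[rng.integers(0, n, size=n)].sum(axis=0)
        stats[b] = prf(MatchCounts(*sample.tolist()))
    lo, hi = np.percentile(stats, [2.5, 97.5], axis=0)
    ci = {
        "precision": (float(lo[0]), float(hi[0])),
        "recall": (float(lo[1]), float(hi[1])),
        "f_measure": (float(lo[2]), float(hi[2])),
    }
    return MetricsReport(
        precision=precision,
        recall=recall,
        f_measure=f,
        ci=ci,
        n_certificates=n,
        bootstrap_replicates=B,
        seed=seed,
    )


@dataclass(frozen=True)
class ChapterRow:
    chapter: int
    label: str
    fp_rate: float  # percent
    fn_rate: float  # percent
    prevalence: float  # percent of all truth codes


@dataclass(frozen=True)
class ChapterReport:
    rows: tuple[ChapterRow, ...]

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["chapter", "label", "fp_rate_pct", "fn_rate_pct", "prevalence_pct"])
            for r in self.rows:
                w.writerow([r.chapter, r.label, f"{r.fp_rate:.2f}", f"{r.fn_rate:.2f}", f"{r.prevalence:.4f}"])


def per_chapter_rates(
    preds: Mapping[str, CodeSeq], truths: Mapping[str, CodeSeq]
) -> ChapterReport:
    """Per-chapter FP rate, FN rate and truth-code prevalence (percent).

    ``fp_rate = FP_c / (TP_c + FP_c)`` (share of chapter-c predictions that
    are wrong), ``fn_rate = FN_c / (TP_c + FN_c)``; rows sort by descending
    prevalence, and chapters with zero denominators on both sides are
    omitted.
    """
    if set(preds) != set(truths):
        raise ValueError("prediction/truth id mismatch")
    by_chapter: dict[int, list[int]] = {}  # chapter -> [tp, fp, fn]

    def bucket(ch: int) -> list[int]:
        return by_chapter.setdefault(ch, [0, 0, 0])

    total_truth = 0
    truth_per_chapter: Counter[int] = Counter()
    for k in preds:
        p = Counter(_texts(preds[k]))
        t = Counter(_texts(truths[k]))
        for code in set(p) | set(t):
            ch = chapter_of(parse_code(code)).index
            tp = min(p[code], t[code])
            bucket(ch)[0] += tp
            bucket(ch)[1] += p[code] - tp
            bucket(ch)[2] += t[code] - tp
            truth_per_chapter[ch] += t[code]
            total_truth += t[code]

    from .icd10 import chapter_table

    labels = {ch.index: ch.label for ch in chapter_table()}
    rows = []
    for ch, (tp, fp, fn) in by_chapter.items():
        if tp + fp == 0 and tp + fn == 0:
            continue
        fp_rate = 100.0 * fp / (tp + fp) if tp + fp else 0.0
        fn_rate = 100.0 * fn / (tp + fn) if tp + fn else 0.0
        prevalence = 100.0 * truth_per_chapter[ch] / total_truth if total_truth else 0.0
        rows.append(ChapterRow(ch, labels[ch], fp_rate, fn_rate, prevalence))
    rows.sort(key=lambda r: (-r.prevalence, r.chapter))
    return ChapterReport(tuple(rows))


@dataclass(frozen=True)
class RejectionPoint:
    threshold: float
    fraction_accepted: float
    f_on_accepted: float


@dataclass(frozen=True)
class RejectionCurve:
    points: tuple[RejectionPoint, ...]

    def to_csv(self, path: str | Path) -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh)
            w.writerow(["threshold", "pct_accepted", "f_measure"])
            for p in self.points:
                w.writerow([f"{p.threshold:.2f}", f"{100 * p.fraction_accepted:.2f}", f"{p.f_on_accepted:.4f}"])

    def at_acceptance(self, target_fraction: float) -> RejectionPoint:
        """The point whose acceptance fraction is closest to ``target_fraction``."""
        return min(self.points, key=lambda p: abs(p.fraction_accepted - target_fraction))


def rejection_curve(
    scores: Mapping[str, float], preds: Mapping[str, CodeSeq], truths: Mapping[str, CodeSeq]
) -> RejectionCurve:
    """Selective-prediction curve on the 0.01 threshold grid.

    At each threshold ``t`` predictions with score ≤ t are rejected; the
    point records the accepted fraction and the micro F on the accepted
    subset.  Thresholds rejecting everything yield no point.
    """
    ids = sorted(preds)
    if set(scores) != set(preds) or set(preds) != set(truths):
        raise ValueError("scores/preds/truths id mismatch")
    for k, s in scores.items():
        if not (0.0 <= s <= 1.0):
            raise ValueError(f"score for {k!r} outside [0, 1]: {s}")
    counts = {k: count_matches(preds[k], truths[k]) for k in ids}
    points = []
    for t in np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2):
        accepted = [k for k in ids if scores[k] > t]
        if not accepted:
            continue
        pooled = MatchCounts(
            tp=sum(counts[k].tp for k in accepted),
            fp=sum(counts[k].fp for k in accepted),
            fn=sum(counts[k].fn for k in accepted),
        )
        _, _, f = prf(pooled)
        points.append(RejectionPoint(float(t), len(accepted) / len(ids), f))
    return RejectionCurve(tuple(points))


def remove_shared_codes(
    pred: CodeSeq, database: CodeSeq, expert: CodeSeq
) -> tuple[list[str], list[str], list[str]]:
    """Delete codes common to prediction and database from all three sequences.

    The shared multiset (intersection of prediction and database counts) is
    removed by count from each sequence, preserving the order of what
    remains — the preprocessing used before comparing disagreeing sources
    against an expert recoding.
    """
    p, d, e = _texts(pred), _texts(database), _texts(expert)
    shared = Counter(p) & Counter(d)

    def strip(seq: list[str]) -> list[str]:
        budget = Counter(shared)
        out = []
        for c in seq:
            if budget[c] > 0:
                budget[c] -= 1
            else:
                out.append(c)
        return out

    return strip(p), strip(d), strip(e)
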