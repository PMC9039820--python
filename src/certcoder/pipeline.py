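"""Reproducible pipeline stages: generate → train → predict → evaluate → calibrate.

Every stage reads a :class:`PipelineConfig` (YAML-backed), derives its own
seed deterministically from the master seed, writes its outputs under the
configured output directory, and drops a ``manifest.json`` (config hash,
seeds, input file hashes, package version) next to them so every report is
traceable to a config + seed.  Stages never mutate their inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .certificates import backward_concatenate, read_certificates, write_certificates
from .evaluation import (
    corpus_metrics,
    count_matches,
    per_chapter_rates,
    prf,
    rejection_curve,
)
from .icd10 import parse_code
from .model import CoderResults, Seq2SeqCoder, TransformerConfig, ensemble_predict
from .synthetic import NoiseConfig, build_grammar, generate_corpus

__all__ = [
    "PipelineConfig",
    "stage_seed",
    "cmd_generate",
    "cmd_train",
    "cmd_predict",
    "cmd_evaluate",
    "cmd_calibrate",
    "run_all",
]

# canonical worked examples of the metric semantics: six predictions
# against the truth "I64 G819"
METRIC_EXAMPLES: tuple[tuple[tuple[str, ...], tuple[float, float, float]], ...] = (
    (("B189", "H155"), (0.0, 0.0, 0.0)),
    (("I64", "G81"), (0.5, 0.5, 0.5)),
    (("I64",), (1.0, 0.5, 0.66)),
    (("I64", "G819", "A338", "B87"), (0.5, 1.0, 0.66)),
    (("I64", "G819"), (1.0, 1.0, 1.0)),
    (("G819", "I64"), (1.0, 1.0, 1.0)),
)
METRIC_EXAMPLES_TRUTH = ("I64", "G819")


@dataclass
class GeneratorConfig:
    n_certificates: int = 22000
    n_phrases: int = 160
    n_codes: int = 120
    split_fractions: tuple[float, float, float] = (0.9, 0.05, 0.05)
    noise: NoiseConfig = field(default_factory=NoiseConfig)


@dataclass
class PipelineConfig:
    out_dir: str = "runs/default"
    seed: int = 7
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    model: TransformerConfig = field(default_factory=TransformerConfig)
    ensemble_size: int = 1
    code_frequency_threshold: int = 10
    eval_beam_size: int = 1
    bootstrap_replicates: int = 1000

    # -- YAML ---------------------------------------------------------------

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "generator" in kwargs:
            g = dict(kwargs["generator"])
            if "noise" in g:
                n = dict(g["noise"])
                if "max_lines_filled" in n:
                    n["max_lines_filled"] = tuple(n["max_lines_filled"])
                g["noise"] = NoiseConfig(**n)
            if "split_fractions" in g:
                g["split_fractions"] = tuple(g["split_fractions"])
            kwargs["generator"] = GeneratorConfig(**g)
        if "model" in kwargs:
            kwargs["model"] = TransformerConfig(**dict(kwargs["model"]))
        return cls(**kwargs)

    def apply_overrides(self, pairs: list[str]) -> None:
        """Flat dotted overrides, e.g. ``model.train_steps=500``."""
        for pair in pairs:
            key, _, value = pair.partition("=")
            obj: object = self
            parts = key.strip().split(".")
            for p in parts[:-1]:
                obj = getattr(obj, p)
            current = getattr(obj, parts[-1])
            setattr(obj, parts[-1], yaml.safe_load(value) if not isinstance(current, str) else value)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    h = hashlib.sha256(f"{master}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_manifest(out_dir: Path, stage: str, config: PipelineConfig, inputs: list[Path]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "config_hash": hashlib.sha256(config.to_yaml().encode()).hexdigest()[:16],
        "master_seed": config.seed,
        "stage_seed": stage_seed(config.seed, stage),
        "inputs": {p.name: _hash_file(p) for p in inputs if p.exists()},
        "elapsed_s": None,
    }
    (out_dir / f"manifest_{stage}.json").write_text(json.dumps(manifest, indent=1))


def _require(path: Path, producing_stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"missing {path}; run the '{producing_stage}' stage first"
        )
    return path


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def cmd_generate(config: PipelineConfig) -> dict[str, Path]:
    """Build the grammar, generate the corpus, write JSONL splits."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = config.generator
    seed = stage_seed(config.seed, "generate")
    grammar = build_grammar(g.n_phrases, g.n_codes, seed=seed)
    corpus = generate_corpus(
        g.n_certificates, grammar, g.noise, seed=seed + 1, split_fractions=g.split_fractions
    )
    paths: dict[str, Path] = {}
    for name in ("train", "validation", "test"):
        pairs = corpus.split(name)
        db_path = out / f"{name}.jsonl"
        write_certificates([p.db_style for p in pairs], db_path)
        paths[name] = db_path
        clean_path = out / f"{name}_clean.jsonl"
        write_certificates([p.clean for p in pairs], clean_path)
        paths[f"{name}_clean"] = clean_path
    (out / "grammar.json").write_text(grammar.to_json())
    _write_manifest(out, "generate", config, [])
    return paths


def cmd_train(config: PipelineConfig, verbose: bool = False) -> list[Path]:
    """Fit the ensemble members (one per derived seed); save checkpoints."""
    out = Path(config.out_dir)
    train_path = _require(out / "train.jsonl", "generate")
    val_path = _require(out / "validation.jsonl", "generate")
    train = read_certificates(train_path)
    val = read_certificates(val_path)
    ckpts = []
    for k in range(config.ensemble_size):
        cfg = dataclasses.replace(config.model, seed=stage_seed(config.seed, f"train-{k}"))
        coder = Seq2SeqCoder.from_corpus(
            train, val, cfg, code_frequency_threshold=config.code_frequency_threshold
        )
        t0 = time.time()
        results = coder.fit(verbose=verbose)
        if verbose:
            print(f"member {k}: trained in {time.time() - t0:.1f}s")
            print(results.summary())
        ckpt = out / f"checkpoint_{k}"
        results.save(ckpt)
        ckpts.append(ckpt)
    _write_manifest(out, "train", config, [train_path, val_path])
    return ckpts


def cmd_predict(config: PipelineConfig, input_corpus: str | Path | None = None) -> Path:
    """Decode the test corpus with the (possibly ensembled) trained coder."""
    out = Path(config.out_dir)
    members = []
    for k in range(config.ensemble_size):
        members.append(CoderResults.load(_require(out / f"checkpoint_{k}", "train")))
    in_path = Path(input_corpus) if input_corpus else _require(out / "test.jsonl", "generate")
    certs = read_certificates(in_path)
    preds = ensemble_predict(members, certs, beam_size=config.eval_beam_size)
    pred_path = out / "predictions.jsonl"
    with pred_path.open("w", encoding="utf-8") as fh:
        for p in preds:
            fh.write(
                json.dumps(
                    {"id": p.id, "pred_codes": [c.text for c in p.codes], "score": round(p.score, 6)}
                )
            )
            fh.write("\n")
    _write_manifest(out, "predict", config, [in_path])
    return pred_path


def _load_predictions(path: Path) -> tuple[dict[str, list], dict[str, float]]:
    preds: dict[str, list] = {}
    scores: dict[str, float] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            d = json.loads(line)
            preds[d["id"]] = [parse_code(c) for c in d["pred_codes"]]
            scores[d["id"]] = float(d["score"])
    return preds, scores


def _truths(path: Path) -> dict[str, list]:
    return {c.id: list(backward_concatenate(c)[1]) for c in read_certificates(path)}


def metric_examples_check() -> list[dict]:
    """Recompute the canonical six worked examples of the metric semantics.

    Values truncate (not round) to two decimals, the convention under which
    2/3 prints as 0.66.
    """

    def trunc2(x: float) -> float:
        return int(x * 100) / 100.0

    rows = []
    for pred, expected in METRIC_EXAMPLES:
        p, r, f = prf(count_matches(pred, METRIC_EXAMPLES_TRUTH))
        got = (trunc2(p), trunc2(r), trunc2(f))
        rows.append(
            {
                "prediction": " ".join(pred),
                "precision": got[0],
                "recall": got[1],
                "f_measure": got[2],
                "expected": list(expected),
                "ok": got == expected,
            }
        )
    return rows


def cmd_evaluate(
    config: PipelineConfig,
    predictions: str | Path | None = None,
    truths: str | Path | None = None,
) -> Path:
    """Micro metrics with bootstrap CIs, per-chapter rates, metric self-check."""
    out = Path(config.out_dir)
    pred_path = Path(predictions) if predictions else _require(out / "predictions.jsonl", "predict")
    truth_path = Path(truths) if truths else _require(out / "test.jsonl", "generate")
    preds, _ = _load_predictions(pred_path)
    truth_map = _truths(truth_path)
    report = corpus_metrics(
        preds, truth_map, B=config.bootstrap_replicates, seed=stage_seed(config.seed, "evaluate")
    )
    chapters = per_chapter_rates(preds, truth_map)
    chapters.to_csv(out / "per_chapter.csv")
    metrics_path = out / "metrics.json"
    metrics_path.write_text(
        json.dumps(
            {"corpus": report.to_dict(), "worked_examples": metric_examples_check()},
            indent=1,
        )
    )
    _write_manifest(out, "evaluate", config, [pred_path, truth_path])
    return metrics_path


def cmd_calibrate(
    config: PipelineConfig,
    predictions: str | Path | None = None,
    truths: str | Path | None = None,
) -> Path:
    """Write the rejection curve (threshold grid, acceptance, F) as CSV."""
    out = Path(config.out_dir)
    pred_path = Path(predictions) if predictions else _require(out / "predictions.jsonl", "predict")
    truth_path = Path(truths) if truths else _require(out / "test.jsonl", "generate")
    preds, scores = _load_predictions(pred_path)
    truth_map = _truths(truth_path)
    curve = rejection_curve(scores, preds, truth_map)
    curve_path = out / "rejection_curve.csv"
    curve.to_csv(curve_path)
    _write_manifest(out, "calibrate", config, [pred_path, truth_path])
    return curve_path


def run_all(config: PipelineConfig, verbose: bool = False) -> None:
    cmd_generate(config)
    cmd_train(config, verbose=verbose)
    cmd_predict(config)
    cmd_evaluate(config)
    cmd_calibrate(config)
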