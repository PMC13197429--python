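"""Orchestration: evaluate strategy/persona/language grids and write reports.

One evaluation *condition* is a prompt specification applied to every corpus
entry: prompts are built, the backend is queried (or a JSONL cache replayed),
responses are parsed, self-consistency chains are aggregated where the
strategy asks for it, and the scored predictions feed the metrics and
significance modules. ``run_grid`` sweeps the configured grid and writes
CSV/JSON tables plus a manifest (config hash, seeds, version) so any number in
a report can be regenerated bit-for-bit from the cache.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .corpus import SemiologyEntry, load_corpus
from .metrics import MetricsReport, Prediction, evaluate, make_prediction
from .parsing import RegionLexicon, parse_response
from .prompts import PromptSpec, build_prompt, select_exemplars, spec_for
from .selfconsistency import median_vote
from .significance import SignificanceReport, bh_adjust, permutation_test
from .synthetic import (
    Backend,
    ResponseCache,
    backend_query,
    get_backend,
)

log = logging.getLogger("semioloc")


@dataclass(frozen=True)
class RunConfig:
    """Settings for a full evaluation grid (one backend, several conditions)."""

    corpus_path: str | None = None
    backend: str = "mock"
    backend_params: Mapping[str, object] = field(default_factory=dict)
    temperature: float = 0.2
    strategies: tuple[str, ...] = ("ZS",)
    personas: tuple[str, ...] = ("AI assistant",)
    languages: tuple[str, ...] = ("en",)
    seed: int = 0
    n_chains: int = 5      # chains per query under SC
    n_perm: int = 999
    n_boot: int = 999
    n_bins: int = 10
    exemplar_k: int = 5
    output_dir: str | None = None
    cache_path: str | None = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def evaluate_condition(
    corpus: Sequence[SemiologyEntry],
    spec: PromptSpec,
    backend: Backend,
    lexicon: RegionLexicon | None = None,
    cache: ResponseCache | None = None,
    replay: bool = False,
    probability_mode: str = "predicted",
    exemplar_seed: int = 0,
) -> list[Prediction]:
    """Run one prompt condition over a corpus and return scored predictions.

    With ``replay=True`` responses are taken from the cache and the backend is
    never queried (a missing record is an error, never a fabricated response).
    """
    if lexicon is None:
        lexicon = RegionLexicon.default()
    predictions: list[Prediction] = []
    parse_language = spec.language
    for entry in corpus:
        entry_spec = spec
        if spec.exemplars and any(x.entry_id == entry.id for x in spec.exemplars):
            # leakage guard: re-draw exemplars excluding the query entry
            entry_spec = replace(
                spec,
                exemplars=select_exemplars(
                    corpus,
                    k=len(spec.exemplars),
                    seed=exemplar_seed,
                    exclude=entry.id,
                    with_reasoning=(spec.strategy == "FS-CoT"),
                    lexicon=lexicon,
                    language=spec.language,
                ),
            )
        prompt = build_prompt(entry, entry_spec, lexicon)
        chain_parses = []
        for chain_index in range(1, spec.n_chains + 1):
            if replay:
                if cache is None:
                    raise ValueError("replay requested without a cache")
                raw = cache.lookup(
                    entry.id, spec.strategy, spec.persona,
                    spec.language, spec.effective_query_language, chain_index,
                )
                if raw is None:
                    raise LookupError(
                        f"cache has no record for entry {entry.id!r}, "
                        f"strategy {spec.strategy}, chain {chain_index}"
                    )
            else:
                raw = backend_query(
                    backend,
                    prompt,
                    meta={"entry": entry, "spec": entry_spec, "chain_index": chain_index},
                    cache=cache,
                )
            parsed = parse_response(raw, lexicon, parse_language)
            if parsed.status != "ok":
                log.warning(
                    "entry=%s strategy=%s chain=%d parse=%s defects=%s",
                    entry.id, spec.strategy, chain_index, parsed.status,
                    "; ".join(parsed.defects),
                )
            chain_parses.append(parsed)
        if spec.n_chains > 1:
            vote = median_vote([p.likelihoods for p in chain_parses])
            parsed = chain_parses[vote.winner]
        else:
            parsed = chain_parses[0]
        predictions.append(make_prediction(entry, parsed, probability_mode))
    return predictions


@dataclass(frozen=True)
class ConditionResult:
    strategy: str
    persona: str
    language: str
    predictions: tuple[Prediction, ...]
    metrics: MetricsReport
    significance: SignificanceReport


@dataclass(frozen=True)
class GridResult:
    config: RunConfig
    conditions: tuple[ConditionResult, ...]

    def metrics_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.conditions:
            row = {
                "backend": self.config.backend,
                "strategy": c.strategy,
                "persona": c.persona,
                "language": c.language,
            }
            row.update(
                {k: v for k, v in c.metrics.as_dict().items() if k != "calibration_bins"}
            )
            rows.append(row)
        return pd.DataFrame(rows)

    def significance_frame(self) -> pd.DataFrame:
        tiny = float(np.finfo(float).tiny)
        pvals = [max(c.significance.p, tiny) for c in self.conditions]
        adjusted = bh_adjust(pvals) if pvals else []
        rows = []
        for c, p_adj in zip(self.conditions, adjusted):
            s = c.significance
            rows.append(
                {
                    "backend": self.config.backend,
                    "strategy": c.strategy,
                    "persona": c.persona,
                    "language": c.language,
                    "f1": s.score,
                    "null_mean": s.null_mean,
                    "null_sd": s.null_sd,
                    "z": s.z,
                    "p": s.p,
                    "p_empirical": s.p_empirical,
                    "p_adj": float(p_adj),
                }
            )
        return pd.DataFrame(rows)


def run_grid(
    config: RunConfig,
    corpus: Sequence[SemiologyEntry] | None = None,
    replay: bool = False,
) -> GridResult:
    """Evaluate every (strategy, persona, language) cell of the configured grid."""
    if corpus is None:
        if config.corpus_path is None:
            raise ValueError("config names no corpus and none was passed")
        corpus = load_corpus(config.corpus_path)
    lexicon = RegionLexicon.default()
    backend = get_backend(config.backend, **dict(config.backend_params))
    cache = None
    if config.cache_path is not None:
        cache = ResponseCache(config.cache_path)
        if replay and not cache.records:
            raise ValueError(f"replay requested but cache {config.cache_path} is empty")
    conditions: list[ConditionResult] = []
    for strategy in config.strategies:
        for persona in config.personas:
            for language in config.languages:
                spec = spec_for(
                    strategy,
                    corpus=corpus,
                    persona=persona,
                    language=language,
                    k=config.exemplar_k,
                    seed=config.seed,
                    lexicon=lexicon,
                )
                predictions = evaluate_condition(
                    corpus, spec, backend, lexicon, cache=cache, replay=replay,
                )
                metrics = evaluate(
                    predictions,
                    n_bins=config.n_bins,
                    n_boot=config.n_boot,
                    seed=config.seed,
                )
                significance = permutation_test(
                    predictions, n_perm=config.n_perm, seed=config.seed
                )
                conditions.append(
                    ConditionResult(
                        strategy=strategy,
                        persona=persona,
                        language=language,
                        predictions=tuple(predictions),
                        metrics=metrics,
                        significance=significance,
                    )
                )
    result = GridResult(config=config, conditions=tuple(conditions))
    if config.output_dir is not None:
        write_report(result, config.output_dir)
    return result


def write_report(result: GridResult, output_dir: str | Path) -> list[Path]:
    """Write CSV/JSON tables, the manifest and a plain-text summary.

    Output is a pure function of the results (no timestamps), so regenerating
    a report from the same results is byte-identical.
    """
    if not result.conditions:
        raise ValueError("cannot report an empty grid")
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    metrics_csv = out / "metrics.csv"
    result.metrics_frame().to_csv(metrics_csv, index=False, float_format="%.10g")
    written.append(metrics_csv)

    significance_csv = out / "significance.csv"
    result.significance_frame().to_csv(significance_csv, index=False, float_format="%.10g")
    written.append(significance_csv)

    full = {
        "manifest": {
            "config": {k: v for k, v in asdict(result.config).items()},
            "config_hash": result.config.config_hash(),
            "seed": result.config.seed,
            "version": __version__,
        },
        "conditions": [
            {
                "strategy": c.strategy,
                "persona": c.persona,
                "language": c.language,
                "metrics": c.metrics.as_dict(),
                "significance": {
                    "f1": c.significance.score,
                    "null_mean": c.significance.null_mean,
                    "null_sd": c.significance.null_sd,
                    "z": c.significance.z,
                    "p": c.significance.p,
                    "p_empirical": c.significance.p_empirical,
                    "n_perm": c.significance.n_perm,
                },
            }
            for c in result.conditions
        ],
    }
    report_json = out / "report.json"
    report_json.write_text(
        json.dumps(full, indent=2, sort_keys=True, default=str) + "\n", encoding="utf-8"
    )
    written.append(report_json)

    lines = [
        f"semioloc evaluation report (config {result.config.config_hash()})",
        f"backend: {result.config.backend}   entries: "
        f"{result.conditions[0].metrics.n_entries}",
        "",
    ]
    for c in result.conditions:
        lines.append(
            f"{c.strategy:7s} persona={c.persona!r:24s} lang={c.language}  "
            f"F1={100 * c.metrics.f1:6.2f}%  "
            f"CI=[{100 * c.metrics.f1_bootstrap.lower:.2f}, "
            f"{100 * c.metrics.f1_bootstrap.upper:.2f}]  "
            f"conf={c.metrics.mean_confidence:.3f}  "
            f"Brier={c.metrics.calibration.brier:.4f}  "
            f"z={c.significance.z:.2f}  p={c.significance.p:.3g}"
        )
    summary = out / "summary.txt"
    summary.write_text("\n".join(lines) + "\n", encoding="utf-8")
    written.append(summary)
    return written
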