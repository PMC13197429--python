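"""Prompt construction for the five likelihood-eliciting strategies.

A prompt is assembled, in order, from: the persona prefix ("you are a
{persona}", kept verbatim including the article), the instruction demanding a
JSON likelihood dictionary over the seven regions, optional few-shot exemplar
blocks, the chain-of-thought sentence with the required "Reasoning"/"Sources"
keys (CoT variants), and finally the query carrying the semiology text.

Strategies: ZS (zero-shot), FS (few-shot, K=5 exemplars), CoT (zero-shot
chain-of-thought), FS-CoT, SC (self-consistency: the ZS-CoT prompt sampled
over five independent chains and aggregated downstream).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources as _importlib_resources
from typing import Sequence

import numpy as np

from .corpus import REGIONS, SemiologyEntry
from .parsing import RegionLexicon

STRATEGIES = ("ZS", "FS", "CoT", "FS-CoT", "SC")
PERSONAS = ("AI assistant", "medical assistant", "neurologist", "expert epileptologist")

#: persona prefix template, applied verbatim
PERSONA_TEMPLATE = "you are a {persona}"

DEFAULT_K = 5
SC_CHAINS = 5


class PromptError(ValueError):
    """Raised for invalid prompt specifications or exemplar leakage."""


def _prompt_resource(name: str) -> str:
    return (
        _importlib_resources.files("semioloc") / "resources" / "prompts" / name
    ).read_text(encoding="utf-8").strip()


def _load_template(kind: str, language: str) -> str:
    try:
        return _prompt_resource(f"{kind}_{language}.txt")
    except FileNotFoundError:
        raise PromptError(f"no {kind!r} prompt resource for language {language!r}") from None


@dataclass(frozen=True)
class Exemplar:
    """One worked (semiology, target output) pair for few-shot prompting."""

    entry_id: str
    text: str
    output: str  # JSON dictionary text; FS-CoT outputs include Reasoning/Sources


@dataclass(frozen=True)
class PromptSpec:
    persona: str = "AI assistant"
    strategy: str = "ZS"
    language: str = "en"           # language of persona/instruction/exemplars
    query_language: str | None = None  # language of the semiology text (defaults to `language`)
    exemplars: tuple[Exemplar, ...] = ()
    n_chains: int = 1

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise PromptError(f"unknown strategy {self.strategy!r}")
        if self.strategy in ("FS", "FS-CoT") and not self.exemplars:
            raise PromptError(f"{self.strategy} requires at least one exemplar")
        if self.strategy in ("ZS", "CoT") and self.exemplars:
            raise PromptError(f"{self.strategy} takes no exemplars")
        if self.strategy == "SC" and self.n_chains != SC_CHAINS:
            object.__setattr__(self, "n_chains", SC_CHAINS)

    @property
    def is_cot(self) -> bool:
        return self.strategy in ("CoT", "FS-CoT", "SC")

    @property
    def effective_query_language(self) -> str:
        return self.query_language or self.language


def build_prompt(
    entry: SemiologyEntry,
    spec: PromptSpec,
    lexicon: RegionLexicon | None = None,
) -> str:
    """Assemble the full prompt text for one entry (pure function of inputs)."""
    if lexicon is None:
        lexicon = RegionLexicon.default()
    for exemplar in spec.exemplars:
        if exemplar.entry_id == entry.id or exemplar.text == entry.text:
            raise PromptError(
                f"exemplar {exemplar.entry_id!r} overlaps the query entry (leakage)"
            )
    parts: list[str] = [PERSONA_TEMPLATE.format(persona=spec.persona) + "."]
    instruction = _load_template("instruction", spec.language).format(
        region_list=", ".join(lexicon.region_names(spec.language))
    )
    parts.append(instruction)
    if spec.is_cot:
        parts.append(_load_template("cot", spec.language))
    for i, exemplar in enumerate(spec.exemplars, start=1):
        parts.append(f"Example {i}:\n{exemplar.text}\n{exemplar.output}")
    query_language = spec.effective_query_language
    query_template = _load_template("query", query_language)
    parts.append(query_template.format(text=entry.text_in(query_language)))
    return "\n\n".join(parts)


def exemplar_output(
    entry: SemiologyEntry,
    with_reasoning: bool = False,
    lexicon: RegionLexicon | None = None,
    language: str = "en",
    reasoning_template: str | None = None,
) -> str:
    """Target JSON for an exemplar: truth regions share 90% of the mass."""
    if lexicon is None:
        lexicon = RegionLexicon.default()
    truth = set(entry.truth)
    n_truth, n_other = len(truth), len(REGIONS) - len(truth)
    values = {
        region: round(90.0 / n_truth, 1) if region in truth
        else (round(10.0 / n_other, 1) if n_other else 0.0)
        for region in REGIONS
    }
    payload: dict[str, object] = {
        lexicon.surface(r, language): values[r] for r in REGIONS
    }
    if with_reasoning:
        template = reasoning_template or _default_reasoning_templates()[0]
        payload["Reasoning"] = template.format(region=entry.truth[0])
        payload["Sources"] = ["expert-curated exemplar"]
    return json.dumps(payload, ensure_ascii=False)


def _default_reasoning_templates() -> list[str]:
    text = _prompt_resource("fscot_reasoning_en.txt")
    return [l for l in text.splitlines() if l.strip() and not l.startswith("#")]


def select_exemplars(
    corpus: Sequence[SemiologyEntry],
    k: int = DEFAULT_K,
    seed: int = 0,
    exclude: str | None = None,
    with_reasoning: bool = False,
    lexicon: RegionLexicon | None = None,
    language: str = "en",
) -> tuple[Exemplar, ...]:
    """Sample k exemplars without replacement, never including ``exclude``.

    Sampling is stratified by the first-listed truth region when at least k
    distinct regions are represented; otherwise it is a plain uniform draw.
    Deterministic for a fixed seed.
    """
    pool = [e for e in corpus if e.id != exclude]
    if k >= len(corpus) or k > len(pool):
        raise PromptError(f"cannot draw {k} exemplars from a pool of {len(pool)}")
    rng = np.random.default_rng(seed)
    by_region: dict[str, list[SemiologyEntry]] = {}
    for e in pool:
        by_region.setdefault(e.truth[0], []).append(e)
    chosen: list[SemiologyEntry] = []
    if len(by_region) >= k:
        regions = rng.choice(sorted(by_region), size=k, replace=False)
        for region in regions:
            bucket = by_region[region]
            chosen.append(bucket[int(rng.integers(len(bucket)))])
    else:
        idx = rng.choice(len(pool), size=k, replace=False)
        chosen = [pool[int(i)] for i in idx]
    templates = _default_reasoning_templates() if with_reasoning else None
    exemplars = []
    for j, e in enumerate(chosen):
        template = templates[j % len(templates)] if templates else None
        exemplars.append(
            Exemplar(
                entry_id=e.id,
                text=e.text,
                output=exemplar_output(
                    e,
                    with_reasoning=with_reasoning,
                    lexicon=lexicon,
                    language=language,
                    reasoning_template=template,
                ),
            )
        )
    return tuple(exemplars)


def spec_for(
    strategy: str,
    corpus: Sequence[SemiologyEntry] = (),
    persona: str = "AI assistant",
    language: str = "en",
    query_language: str | None = None,
    k: int = DEFAULT_K,
    seed: int = 0,
    exclude: str | None = None,
    lexicon: RegionLexicon | None = None,
) -> PromptSpec:
    """Convenience constructor wiring exemplar selection per strategy."""
    exemplars: tuple[Exemplar, ...] = ()
    if strategy in ("FS", "FS-CoT"):
        exemplars = select_exemplars(
            corpus,
            k=k,
            seed=seed,
            exclude=exclude,
            with_reasoning=(strategy == "FS-CoT"),
            lexicon=lexicon,
            language=language,
        )
    return PromptSpec(
        persona=persona,
        strategy=strategy,
        language=language,
        query_language=query_language,
        exemplars=exemplars,
        n_chains=SC_CHAINS if strategy == "SC" else 1,
    )
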