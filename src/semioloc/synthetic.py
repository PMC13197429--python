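"""Synthetic corpora and a fully offline simulated responder.

The generator emulates the statistical shape of a curated semiology corpus —
class-imbalanced multi-label ground truth (majority region ~38% of entries),
short free-text descriptions with a right-skewed word-count distribution, and
optional pseudo-translations — without any clinical content: texts are random
draws from a small symptom vocabulary.

The mock responder stands in for a language-model backend. Its behaviour is
controllable along exactly the axes the evaluation measures:

* accuracy — fixed hit probability, or "calibrated" mode where a confidence
  c ~ Uniform(c_lo, c_hi) is drawn per query, the top region is sampled from
  the truth set with probability c, and the top region receives 100·c % of the
  likelihood mass. A calibrated responder therefore has measured accuracy
  E[c], Brier score E[c(1-c)], and a reliability diagram on the diagonal —
  closed forms the metrics tests recover.
* concentration — optional Dirichlet jitter of the non-winning mass
  (0 = spread evenly, keeping the analytic oracles exact).
* malformation — with probability ``malform_rate`` a defect (missing key,
  "None" value, non-numeric token, truncated JSON) is injected into the
  serialized response, exercising the real parser paths.
* planted effects — additive accuracy deltas per persona, per prompt/query
  language, and per description-length bin, used by the ablation drivers for
  parameter-recovery tests.

Every response is deterministic given (seed, entry id, chain index); prompt
conditions share the same underlying draws (paired design, see
``simulate_response``).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Protocol, Sequence

import numpy as np

from .corpus import N_REGIONS, REGIONS, SemiologyEntry, assign_length_bin
from .parsing import RegionLexicon
from .prompts import PromptSpec

# ---------------------------------------------------------------------------
# Deterministic per-query seeding
# ---------------------------------------------------------------------------

def _derive_rng(seed: int, *key_parts: object) -> np.random.Generator:
    """Generator keyed by a stable hash of (seed, *key_parts)."""
    digest = hashlib.sha256("\x1f".join(str(p) for p in key_parts).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence([int(seed) % 2**31, *words]))


# ---------------------------------------------------------------------------
# Synthetic corpus
# ---------------------------------------------------------------------------

#: default primary-region weights: Temporal Lobe majority at the prevalence the
#: study corpus reports; the remainder follows the usual clinical gradient
#: (frontal > parietal/occipital/insula > cingulate > hypothalamus).
DEFAULT_CLASS_WEIGHTS: tuple[float, ...] = (
    0.3821,  # Temporal Lobe
    0.2400,  # Frontal Lobe
    0.0500,  # Cingulate Gyrus
    0.1100,  # Parietal Lobe
    0.0900,  # Occipital Lobe
    0.0800,  # Insula
    0.0479,  # Hypothalamus
)

_VOCABULARY = (
    "aura", "automatisms", "chewing", "lip-smacking", "swallowing", "staring",
    "unresponsive", "head", "version", "tonic", "clonic", "posturing",
    "hypermotor", "pelvic", "thrusting", "bicycling", "vocalization",
    "laughter", "fear", "epigastric", "rising", "sensation", "deja", "vu",
    "visual", "flashing", "lights", "hemianopia", "tingling", "numbness",
    "left", "right", "arm", "leg", "face", "dystonic", "eye", "deviation",
    "salivation", "flushing", "tachycardia", "amnesia", "aphasia", "speech",
    "arrest", "nocturnal", "brief", "frequent", "gelastic", "autonomic",
    "sweating",
)


@dataclass(frozen=True)
class SyntheticCorpusParams:
    """Study-scale defaults: 1,269 entries, ~38% majority class, short texts."""

    n: int = 1269
    class_weights: tuple[float, ...] = DEFAULT_CLASS_WEIGHTS
    multilabel_prob: float = 0.2
    #: lognormal word-count parameters (median exp(mu) ~ 8 words)
    wordcount_mu: float = 2.1
    wordcount_sigma: float = 0.7
    wordcount_max: int = 80
    languages: tuple[str, ...] = ("en",)
    language_weights: tuple[float, ...] | None = None
    #: languages for which pseudo-translated text variants are attached
    translation_languages: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        weights = np.asarray(self.class_weights, dtype=float)
        if len(weights) != N_REGIONS or (weights < 0).any() or weights.sum() <= 0:
            raise ValueError("class_weights must be 7 nonnegative values with positive sum")
        if not abs(weights.sum() - 1.0) < 1e-9:
            raise ValueError("class_weights must sum to 1")
        if not 0.0 <= self.multilabel_prob <= 1.0:
            raise ValueError("multilabel_prob must be in [0, 1]")


def generate_corpus(params: SyntheticCorpusParams) -> list[SemiologyEntry]:
    """Deterministic synthetic corpus matching the configured distributions."""
    rng = np.random.default_rng(np.random.SeedSequence([params.seed % 2**31, 0xC0]))
    weights = np.asarray(params.class_weights, dtype=float)
    lang_weights = params.language_weights
    if lang_weights is None:
        lang_weights = tuple(1.0 / len(params.languages) for _ in params.languages)
    primaries = rng.choice(N_REGIONS, size=params.n, p=weights)
    entries: list[SemiologyEntry] = []
    for i in range(params.n):
        primary = int(primaries[i])
        truth = [REGIONS[primary]]
        if rng.random() < params.multilabel_prob:
            extra = int(rng.choice([j for j in range(N_REGIONS) if j != primary]))
            truth.append(REGIONS[extra])
        wc = int(np.clip(
            round(rng.lognormal(params.wordcount_mu, params.wordcount_sigma)),
            1, params.wordcount_max,
        ))
        tokens = rng.choice(len(_VOCABULARY), size=wc)
        text = " ".join(_VOCABULARY[t] for t in tokens)
        language = str(rng.choice(params.languages, p=lang_weights))
        translations = {
            lang: " ".join(f"{lang}:{_VOCABULARY[t]}" for t in tokens)
            for lang in params.translation_languages
        }
        entries.append(
            SemiologyEntry(
                id=f"syn-{i:05d}",
                text=text,
                language=language,
                truth=tuple(truth),
                translations=translations,
            )
        )
    return entries


# ---------------------------------------------------------------------------
# Mock responder
# ---------------------------------------------------------------------------

DEFECT_KINDS = ("missing_key", "none_value", "non_numeric", "broken_json")


@dataclass(frozen=True)
class ResponderParams:
    """Tunable behaviour of the simulated responder (see module docstring)."""

    mode: str = "calibrated"                 # "fixed" or "calibrated"
    accuracy: float = 0.6                    # hit probability in fixed mode
    conf_bounds: tuple[float, float] = (0.2, 1.0)  # Uniform(c_lo, c_hi), calibrated mode
    top_percent: float = 60.0                # top-region mass in fixed mode
    concentration: float = 0.0               # Dirichlet jitter of non-winning mass
    malform_rate: float = 0.0
    defect_mix: Mapping[str, float] = field(
        default_factory=lambda: {k: 0.25 for k in DEFECT_KINDS}
    )
    seed: int = 0
    # planted effects (additive accuracy deltas), used by ablation recovery tests
    strategy_effects: Mapping[str, float] = field(default_factory=dict)
    persona_effects: Mapping[str, float] = field(default_factory=dict)
    prompt_language_effects: Mapping[str, float] = field(default_factory=dict)
    query_language_effects: Mapping[str, float] = field(default_factory=dict)
    #: (edges, per-bin base accuracy) overriding `accuracy` by description length
    length_effects: tuple[tuple[int, ...], tuple[float, ...]] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "calibrated"):
            raise ValueError("mode must be 'fixed' or 'calibrated'")
        if not 0.0 <= self.malform_rate <= 1.0:
            raise ValueError("malform_rate must be in [0, 1]")
        if self.mode == "fixed" and not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy must be in [0, 1]")
        lo, hi = self.conf_bounds
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("conf_bounds must satisfy 0 <= lo <= hi <= 1")
        mix = np.array([self.defect_mix.get(k, 0.0) for k in DEFECT_KINDS])
        if (mix < 0).any() or not np.isclose(mix.sum(), 1.0):
            raise ValueError("defect_mix must be nonnegative weights summing to 1")


def _effective_accuracy(
    base: float, entry: SemiologyEntry, spec: PromptSpec, params: ResponderParams
) -> float:
    a = base
    if params.length_effects is not None:
        edges, per_bin = params.length_effects
        a = per_bin[assign_length_bin(entry.word_count, edges)]
    a += params.strategy_effects.get(spec.strategy, 0.0)
    a += params.persona_effects.get(spec.persona, 0.0)
    a += params.prompt_language_effects.get(spec.language, 0.0)
    a += params.query_language_effects.get(spec.effective_query_language, 0.0)
    return float(np.clip(a, 0.0, 1.0))


def _inject_defect(serialized: str, rng: np.random.Generator,
                   params: ResponderParams, surfaces: Sequence[str]) -> str:
    mix = np.array([params.defect_mix.get(k, 0.0) for k in DEFECT_KINDS])
    kind = DEFECT_KINDS[int(rng.choice(len(DEFECT_KINDS), p=mix / mix.sum()))]
    payload = json.loads(serialized)
    target = surfaces[int(rng.integers(len(surfaces)))]
    if kind == "missing_key":
        payload.pop(target, None)
        return json.dumps(payload, ensure_ascii=False)
    if kind == "none_value":
        payload[target] = "None"
        return json.dumps(payload, ensure_ascii=False)
    if kind == "non_numeric":
        payload[target] = "high"
        return json.dumps(payload, ensure_ascii=False)
    # broken_json: truncate, losing the closing brace and trailing keys
    cut = max(1, int(len(serialized) * 0.6))
    return serialized[:cut]


def simulate_response(
    entry: SemiologyEntry,
    prompt: PromptSpec,
    params: ResponderParams,
    chain_index: int = 1,
    lexicon: RegionLexicon | None = None,
) -> str:
    """One raw response text; deterministic given (seed, entry id, chain index).

    The random draws are keyed by (seed, entry, chain) only — *not* by the
    prompt condition — so evaluations across personas, strategies or languages
    are paired (common random numbers): a condition-blind responder returns
    byte-identical likelihoods under every condition, and a planted accuracy
    delta is recovered with paired rather than independent-sample precision.
    """
    if chain_index < 1:
        raise ValueError("chain_index must be >= 1")
    if lexicon is None:
        lexicon = RegionLexicon.default()
    rng = _derive_rng(params.seed, entry.id, chain_index)
    if params.mode == "calibrated":
        lo, hi = params.conf_bounds
        c = float(rng.uniform(lo, hi))
        hit_prob = _effective_accuracy(c, entry, prompt, params) if (
            params.strategy_effects or params.persona_effects
            or params.prompt_language_effects or params.query_language_effects
            or params.length_effects
        ) else c
        top_share = c
    else:
        hit_prob = _effective_accuracy(params.accuracy, entry, prompt, params)
        top_share = params.top_percent / 100.0
    truth_idx = [i for i, r in enumerate(REGIONS) if r in entry.truth]
    other_idx = [i for i in range(N_REGIONS) if i not in truth_idx]
    if rng.random() < hit_prob or not other_idx:
        top = truth_idx[int(rng.integers(len(truth_idx)))]
    else:
        top = other_idx[int(rng.integers(len(other_idx)))]
    vector = np.empty(N_REGIONS)
    remaining = 100.0 * (1.0 - top_share)
    rest = [i for i in range(N_REGIONS) if i != top]
    if params.concentration > 0:
        shares = rng.dirichlet([params.concentration] * len(rest))
    else:
        shares = np.full(len(rest), 1.0 / len(rest))
    vector[top] = 100.0 * top_share
    vector[rest] = remaining * shares
    language = prompt.language
    surfaces = lexicon.region_names(language)
    # 4-decimal precision: coarser rounding creates an atom at exactly 100*c_lo,
    # which would land in the wrong (open-left) reliability bin
    payload: dict[str, object] = {
        s: round(float(v), 4) for s, v in zip(surfaces, vector)
    }
    if prompt.is_cot:
        payload["Reasoning"] = (
            f"Step-by-step assessment places the onset in the {REGIONS[top]}."
        )
        payload["Sources"] = ["synthetic responder"]
    serialized = json.dumps(payload, ensure_ascii=False)
    if params.malform_rate > 0 and rng.random() < params.malform_rate:
        serialized = _inject_defect(serialized, rng, params, surfaces)
    return serialized


# ---------------------------------------------------------------------------
# Backend contract, registry and response cache
# ---------------------------------------------------------------------------

class BackendError(RuntimeError):
    """Transport/configuration failure; a backend never fabricates a response."""


class Backend(Protocol):
    name: str

    def query(self, prompt: str, meta: Mapping[str, object]) -> str: ...


class MockBackend:
    """Offline backend wrapping the simulated responder.

    ``meta`` must carry the structured context ("entry", "spec", "chain_index")
    that a real transport would not need; real adapters ignore it.
    """

    name = "mock"

    def __init__(self, params: ResponderParams | None = None,
                 lexicon: RegionLexicon | None = None,
                 temperature: float = 0.2):
        self.params = params or ResponderParams()
        self.lexicon = lexicon or RegionLexicon.default()
        self.temperature = temperature  # carried for parity with real adapters

    def query(self, prompt: str, meta: Mapping[str, object]) -> str:
        entry = meta["entry"]
        spec = meta["spec"]
        chain_index = int(meta.get("chain_index", 1))
        return simulate_response(entry, spec, self.params, chain_index, self.lexicon)


_BACKEND_REGISTRY: dict[str, Callable[..., Backend]] = {}


def register_backend(name: str, factory: Callable[..., Backend]) -> None:
    _BACKEND_REGISTRY[name] = factory


def get_backend(name: str, **config: object) -> Backend:
    try:
        factory = _BACKEND_REGISTRY[name]
    except KeyError:
        raise BackendError(
            f"no backend registered under {name!r}; known: {sorted(_BACKEND_REGISTRY)}"
        ) from None
    return factory(**config)


register_backend("mock", MockBackend)


class ResponseCache:
    """Append-only JSON-lines cache of every query/response pair."""

    def __init__(self, path: str | Path | None = None):
        self.path = Path(path) if path is not None else None
        self.records: list[dict] = []
        if self.path is not None and self.path.exists():
            with open(self.path, encoding="utf-8") as fh:
                self.records = [json.loads(line) for line in fh if line.strip()]

    def append(self, record: Mapping[str, object]) -> None:
        record = dict(record)
        record.setdefault("timestamp", time.strftime("%Y-%m-%dT%H:%M:%S%z"))
        self.records.append(record)
        if self.path is not None:
            with open(self.path, "a", encoding="utf-8") as fh:
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")

    def lookup(self, entry_id: str, strategy: str, persona: str,
               language: str, query_language: str, chain_index: int) -> str | None:
        for record in self.records:
            if (
                record.get("entry_id") == entry_id
                and record.get("strategy") == strategy
                and record.get("persona") == persona
                and record.get("language") == language
                and record.get("query_language") == query_language
                and record.get("chain_index") == chain_index
            ):
                return str(record["raw_text"])
        return None


def backend_query(
    backend: Backend,
    prompt: str,
    meta: Mapping[str, object],
    cache: ResponseCache | None = None,
) -> str:
    """Query a backend and append the exchange to the response cache."""
    raw = backend.query(prompt, meta)
    if cache is not None:
        entry = meta.get("entry")
        spec = meta.get("spec")
        cache.append(
            {
                "entry_id": getattr(entry, "id", None),
                "strategy": getattr(spec, "strategy", None),
                "persona": getattr(spec, "persona", None),
                "language": getattr(spec, "language", None),
                "query_language": getattr(spec, "effective_query_language", None),
                "chain_index": int(meta.get("chain_index", 1)),
                "raw_text": raw,
                "backend": getattr(backend, "name", "unknown"),
            }
        )
    return raw
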