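"""Structured extraction of region-likelihood dictionaries from raw responses.

The responder is instructed to answer with a JSON dictionary mapping the seven
canonical regions to percentage likelihoods (plus "Reasoning"/"Sources" for
chain-of-thought strategies). Real model output deviates from that contract in
predictable ways — prose around the dictionary, missing keys, "None" or
non-numeric values, truncated JSON, translated region names — so parsing never
raises: every deviation is recorded as a defect and a likelihood of 0 is
assigned to unrecoverable regions. A response with no recoverable region value
at all gets status ``failed`` and an all-zero vector, which downstream scoring
treats as an incorrect prediction with confidence 0.
"""

from __future__ import annotations

import json
import re
import unicodedata
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Mapping, Sequence

import numpy as np

from .corpus import N_REGIONS, REGIONS, REGION_INDEX

STATUS_OK = "ok"
STATUS_PARTIAL = "partial"
STATUS_FAILED = "failed"


def _fold(name: str) -> str:
    """Case- and diacritic-insensitive key for lexicon lookup."""
    stripped = "".join(
        ch
        for ch in unicodedata.normalize("NFKD", name)
        if not unicodedata.combining(ch)
    )
    return " ".join(stripped.casefold().split())


class RegionLexicon:
    """Per-language mapping from surface region names to canonical regions."""

    def __init__(self, table: Mapping[str, Mapping[str, str]]):
        # table: language -> {folded surface -> canonical}
        self._table = {lang: dict(mapping) for lang, mapping in table.items()}
        for lang, mapping in self._table.items():
            missing = set(REGIONS) - set(mapping.values())
            if missing:
                raise ValueError(f"lexicon for {lang!r} misses regions {sorted(missing)}")

    @classmethod
    def from_rows(cls, rows: Sequence[tuple[str, str, str]]) -> "RegionLexicon":
        table: dict[str, dict[str, str]] = {}
        for language, surface, canonical in rows:
            if canonical not in REGION_INDEX:
                raise ValueError(f"unknown canonical region {canonical!r}")
            table.setdefault(language, {})[_fold(surface)] = canonical
        return cls(table)

    @classmethod
    def default(cls) -> "RegionLexicon":
        """Lexicon shipped as a delimited resource (en, fr, es, zh)."""
        text = (
            _importlib_resources.files("semioloc") / "resources" / "lexicon.tsv"
        ).read_text(encoding="utf-8")
        rows = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            language, surface, canonical = line.split("\t")
            rows.append((language, surface, canonical))
        return cls.from_rows(rows)

    @property
    def languages(self) -> tuple[str, ...]:
        return tuple(sorted(self._table))

    def lookup(self, name: str, language: str) -> str | None:
        if language not in self._table:
            raise KeyError(f"lexicon does not cover language {language!r}")
        return self._table[language].get(_fold(name))

    def surface(self, region: str, language: str) -> str:
        """A representative surface form of ``region`` in ``language``."""
        if language not in self._table:
            raise KeyError(f"lexicon does not cover language {language!r}")
        if language == "en":
            return region
        for folded, canonical in self._table[language].items():
            if canonical == region:
                return folded
        raise KeyError(f"no surface form for {region!r} in {language!r}")

    def region_names(self, language: str) -> list[str]:
        return [self.surface(r, language) for r in REGIONS]


def canonicalize_region(name: str, language: str, lexicon: RegionLexicon) -> str | None:
    """Canonical region for a surface name, or None when unmapped."""
    match = lexicon.lookup(name, language)
    if match is None and language != "en":
        # translated responses frequently keep English keys
        match = lexicon.lookup(name, "en")
    return match


@dataclass(frozen=True)
class RegionLikelihood:
    """Nonnegative percentage likelihoods over the seven canonical regions.

    Values need not sum to 100: responders are not forced to normalize.
    """

    values: Mapping[str, float]

    def __post_init__(self) -> None:
        if set(self.values) != set(REGIONS):
            raise ValueError("likelihood dictionary must have exactly the 7 canonical keys")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("likelihoods must be nonnegative")

    @classmethod
    def from_array(cls, vector: Sequence[float]) -> "RegionLikelihood":
        vector = list(vector)
        if len(vector) != N_REGIONS:
            raise ValueError(f"expected {N_REGIONS} values, got {len(vector)}")
        return cls({r: float(v) for r, v in zip(REGIONS, vector)})

    @classmethod
    def zeros(cls) -> "RegionLikelihood":
        return cls.from_array([0.0] * N_REGIONS)

    def as_array(self) -> np.ndarray:
        return np.array([self.values[r] for r in REGIONS], dtype=float)

    def __getitem__(self, region: str) -> float:
        return float(self.values[region])


@dataclass(frozen=True)
class ParsedResponse:
    likelihoods: RegionLikelihood
    reasoning: str | None = None
    sources: tuple[str, ...] | None = None
    status: str = STATUS_OK
    defects: tuple[str, ...] = field(default_factory=tuple)

    @property
    def failed(self) -> bool:
        return self.status == STATUS_FAILED


_NUMBER_RE = re.compile(r"^\s*([-+]?\d+(?:\.\d+)?)\s*%?\s*$")
# salvage pattern for broken JSON: "key": value-ish
_PAIR_RE = re.compile(r'"([^"\n]+)"\s*:\s*("(?:[^"\\]|\\.)*"|[-+]?\d+(?:\.\d+)?\s*%?|None|null)')


def _first_balanced_block(raw: str) -> str | None:
    start = raw.find("{")
    if start < 0:
        return None
    depth = 0
    in_string = False
    escaped = False
    for i in range(start, len(raw)):
        ch = raw[i]
        if in_string:
            if escaped:
                escaped = False
            elif ch == "\\":
                escaped = True
            elif ch == '"':
                in_string = False
            continue
        if ch == '"':
            in_string = True
        elif ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth == 0:
                return raw[start : i + 1]
    return None  # unbalanced (truncated response)


def _coerce_value(value: object) -> tuple[float | None, str | None]:
    """(number, defect) from a raw dictionary value; number None when missing."""
    if isinstance(value, bool):
        return None, f"non-numeric value {value!r}"
    if isinstance(value, (int, float)):
        return float(value), None
    if value is None:
        return None, 'value "None"'
    if isinstance(value, str):
        match = _NUMBER_RE.match(value)
        if match:
            return float(match.group(1)), None
        if value.strip().lower() in {"none", "null", "nan", "n/a"}:
            return None, f"value {value!r}"
        return None, f"non-numeric value {value!r}"
    return None, f"non-numeric value of type {type(value).__name__}"


def _raw_pairs(raw: str) -> tuple[dict, list[str]]:
    """Dictionary of key/value pairs from the response, with format defects."""
    defects: list[str] = []
    block = _first_balanced_block(raw)
    if block is not None:
        try:
            obj = json.loads(block)
            if isinstance(obj, dict):
                return obj, defects
            defects.append("top-level JSON is not a dictionary")
        except json.JSONDecodeError:
            defects.append("malformed JSON block")
    else:
        defects.append("no balanced JSON dictionary found")
    # regex salvage over the whole response
    pairs: dict[str, object] = {}
    for key, value in _PAIR_RE.findall(raw):
        if value.startswith('"'):
            try:
                pairs[key] = json.loads(value)
            except json.JSONDecodeError:
                pairs[key] = value.strip('"')
        elif value in {"None", "null"}:
            pairs[key] = None
        else:
            pairs[key] = value
    if pairs:
        defects.append("recovered key/value pairs by regex")
    return pairs, defects


def parse_response(
    raw: str,
    lexicon: RegionLexicon | None = None,
    language: str = "en",
) -> ParsedResponse:
    """Extract likelihoods (and optional reasoning/sources) from raw text.

    Never raises on malformed input; see module docstring for the defect
    conventions. ``language`` selects the lexicon used to canonicalize region
    keys (English keys are always accepted as a fallback).
    """
    if lexicon is None:
        lexicon = RegionLexicon.default()
    pairs, defects = _raw_pairs(raw or "")
    values: dict[str, float] = {r: 0.0 for r in REGIONS}
    seen: set[str] = set()
    recovered = 0  # regions whose value coerced to a number
    reasoning: str | None = None
    sources: tuple[str, ...] | None = None
    for key, value in pairs.items():
        folded_key = _fold(str(key))
        if folded_key == "reasoning":
            reasoning = str(value) if value is not None else None
            continue
        if folded_key == "sources":
            if isinstance(value, (list, tuple)):
                sources = tuple(str(v) for v in value)
            elif value is not None:
                sources = (str(value),)
            continue
        region = canonicalize_region(str(key), language, lexicon)
        if region is None:
            defects.append(f"unrecognized key {key!r}")
            continue
        number, defect = _coerce_value(value)
        if number is None:
            defects.append(f"{region}: {defect}; assigned 0%")
            number = 0.0
        else:
            recovered += 1
            if number < 0:
                defects.append(f"{region}: negative likelihood {number}; assigned 0%")
                number = 0.0
            elif number > 100:
                defects.append(f"{region}: likelihood {number} exceeds 100%")
        values[region] = number
        seen.add(region)
    for region in REGIONS:
        if region not in seen:
            defects.append(f"{region}: missing; assigned 0%")
    likelihoods = RegionLikelihood(values)
    if recovered == 0:
        status = STATUS_FAILED
    elif recovered == N_REGIONS and not defects:
        status = STATUS_OK
    else:
        status = STATUS_PARTIAL
    return ParsedResponse(
        likelihoods=likelihoods,
        reasoning=reasoning,
        sources=sources,
        status=status,
        defects=tuple(defects),
    )


def serialize_response(parsed: ParsedResponse, language: str = "en",
                       lexicon: RegionLexicon | None = None) -> str:
    """Serialize back to the canonical JSON dictionary (round-trip stable)."""
    if lexicon is None:
        lexicon = RegionLexicon.default()
    payload: dict[str, object] = {
        lexicon.surface(r, language): parsed.likelihoods[r] for r in REGIONS
    }
    if parsed.reasoning is not None:
        payload["Reasoning"] = parsed.reasoning
    if parsed.sources is not None:
        payload["Sources"] = list(parsed.sources)
    return json.dumps(payload, ensure_ascii=False)
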