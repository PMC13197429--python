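"""Semiology corpora: loading, preprocessing, length bins and the naive baseline.

A corpus is a list of :class:`SemiologyEntry`, each pairing one free-text
seizure description with a non-empty subset of the seven canonical brain
regions that can host the seizure onset zone (SOZ). The canonical region order
is global and fixed: it defines vector layout everywhere downstream and breaks
argmax ties deterministically.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources as _importlib_resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The seven canonical SOZ regions, in the fixed global order.
REGIONS: tuple[str, ...] = (
    "Temporal Lobe",
    "Frontal Lobe",
    "Cingulate Gyrus",
    "Parietal Lobe",
    "Occipital Lobe",
    "Insula",
    "Hypothalamus",
)

REGION_INDEX: dict[str, int] = {r: i for i, r in enumerate(REGIONS)}

N_REGIONS = len(REGIONS)


class CorpusError(ValueError):
    """Raised for malformed corpus files or invalid entries."""


def _resource_text(name: str) -> str:
    return (_importlib_resources.files("semioloc") / "resources" / name).read_text(
        encoding="utf-8"
    )


def _parse_two_column(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("\t")
        out[key.strip()] = value.strip()
    return out


def _parse_term_list(text: str) -> list[str]:
    return [
        line.strip()
        for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]


@dataclass(frozen=True)
class PreprocessRules:
    """Deterministic text-normalization rules.

    ``abbreviation_map`` is matched case-sensitively on whole tokens (clinical
    abbreviations are conventionally cased, e.g. "LOC"); ``spelling_map`` and
    ``stop_terms`` match case-insensitively. Rules must be idempotent: no
    output token of either map may itself be a map key or a stop term.
    """

    abbreviation_map: Mapping[str, str] = field(default_factory=dict)
    spelling_map: Mapping[str, str] = field(default_factory=dict)
    stop_terms: Sequence[str] = ()

    @classmethod
    def default(cls) -> "PreprocessRules":
        """Rules shipped as editable plain-text resources (minimal defaults)."""
        return cls(
            abbreviation_map=_parse_two_column(_resource_text("abbreviations.tsv")),
            spelling_map={
                k.lower(): v
                for k, v in _parse_two_column(_resource_text("spelling.tsv")).items()
            },
            stop_terms=[t.lower() for t in _parse_term_list(_resource_text("stop_terms.txt"))],
        )

    @classmethod
    def none(cls) -> "PreprocessRules":
        """No-op rules (identity preprocessing apart from whitespace collapse)."""
        return cls()


def preprocess_text(raw: str, rules: PreprocessRules) -> str:
    """Expand abbreviations, correct spelling, drop stop terms, collapse whitespace.

    Empty input returns "". The function is deterministic and, for valid rules
    (map outputs are fixed points), idempotent.
    """
    stop = {t.lower() for t in rules.stop_terms}
    spelling = {k.lower(): v for k, v in rules.spelling_map.items()}
    out_tokens: list[str] = []
    for token in raw.split():
        if token in rules.abbreviation_map:
            expanded = rules.abbreviation_map[token].split()
        else:
            expanded = [token]
        for tok in expanded:
            tok = spelling.get(tok.lower(), tok)
            if tok.lower() in stop:
                continue
            out_tokens.append(tok)
    return " ".join(out_tokens)


@dataclass(frozen=True)
class SemiologyEntry:
    """One seizure description with its multi-label ground-truth region set."""

    id: str
    text: str
    language: str
    truth: tuple[str, ...]
    #: optional per-language variants of ``text`` (used by the language sweep)
    translations: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.truth:
            raise CorpusError(f"entry {self.id!r}: empty ground-truth region set")
        for region in self.truth:
            if region not in REGION_INDEX:
                raise CorpusError(f"entry {self.id!r}: unknown region {region!r}")

    @property
    def word_count(self) -> int:
        """Whitespace-token count of the (preprocessed) text."""
        return len(self.text.split())

    def text_in(self, language: str) -> str:
        """Description text in ``language`` (errors if no variant exists)."""
        if language == self.language:
            return self.text
        try:
            return self.translations[language]
        except KeyError:
            raise CorpusError(
                f"entry {self.id!r}: no translation for language {language!r}"
            ) from None


TRUTH_SEPARATOR = ";"


def load_corpus(
    path: str | Path,
    rules: PreprocessRules | None = None,
) -> list[SemiologyEntry]:
    """Load a tab-separated corpus (columns: id, text, language, regions).

    ``regions`` holds one or more canonical region names joined by ";".
    Optional ``text_<lang>`` columns are read as per-language translations.
    Texts are preprocessed with ``rules`` (defaults to the shipped rules).
    """
    if rules is None:
        rules = PreprocessRules.default()
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise CorpusError(f"{path}: empty corpus file") from None
    required = {"id", "text", "language", "regions"}
    missing = required - set(frame.columns)
    if missing:
        raise CorpusError(f"{path}: missing columns {sorted(missing)}")
    if len(frame) == 0:
        raise CorpusError(f"{path}: corpus has no entries")
    translation_cols = [c for c in frame.columns if c.startswith("text_")]
    entries: list[SemiologyEntry] = []
    for row_number, row in enumerate(frame.itertuples(index=False), start=2):
        raw_regions = [
            r.strip() for r in getattr(row, "regions").split(TRUTH_SEPARATOR) if r.strip()
        ]
        if not raw_regions:
            raise CorpusError(f"{path}, row {row_number}: empty ground-truth region set")
        for region in raw_regions:
            if region not in REGION_INDEX:
                raise CorpusError(
                    f"{path}, row {row_number}: unknown region {region!r}"
                )
        truth = tuple(dict.fromkeys(raw_regions))  # dedupe, keep order
        translations = {
            col[len("text_"):]: preprocess_text(getattr(row, col), rules)
            for col in translation_cols
            if getattr(row, col)
        }
        entries.append(
            SemiologyEntry(
                id=getattr(row, "id"),
                text=preprocess_text(getattr(row, "text"), rules),
                language=getattr(row, "language") or "en",
                truth=truth,
                translations=translations,
            )
        )
    return entries


def write_corpus(entries: Sequence[SemiologyEntry], path: str | Path) -> None:
    """Write entries back to the normalized TSV dialect read by load_corpus."""
    languages = sorted({lang for e in entries for lang in e.translations})
    rows = []
    for e in entries:
        row = {
            "id": e.id,
            "text": e.text,
            "language": e.language,
            "regions": TRUTH_SEPARATOR.join(e.truth),
        }
        for lang in languages:
            row[f"text_{lang}"] = e.translations.get(lang, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def corpus_summary(entries: Sequence[SemiologyEntry]) -> dict:
    """JSON-ready summary: size, per-region truth counts, word-count histogram."""
    counts = Counter(region for e in entries for region in e.truth)
    word_counts = [e.word_count for e in entries]
    hist, edges = np.histogram(word_counts, bins=10)
    return {
        "n_entries": len(entries),
        "class_counts": {r: int(counts.get(r, 0)) for r in REGIONS},
        "multi_label_fraction": float(np.mean([len(e.truth) > 1 for e in entries])),
        "word_count_histogram": {
            "edges": [float(x) for x in edges],
            "counts": [int(c) for c in hist],
        },
    }


# ---------------------------------------------------------------------------
# Length bins
# ---------------------------------------------------------------------------

def assign_length_bin(word_count: int | SemiologyEntry, edges: Sequence[int]) -> int:
    """Index of the half-open interval [edges[m], edges[m+1]) holding word_count.

    The half-open convention includes each interval's left edge and excludes
    its right edge. Counts outside [edges[0], edges[-1]) raise ValueError.
    """
    if isinstance(word_count, SemiologyEntry):
        word_count = word_count.word_count
    edges = list(edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly ascending with at least 2 values")
    if not (edges[0] <= word_count < edges[-1]):
        raise ValueError(
            f"word count {word_count} outside covered range [{edges[0]}, {edges[-1]})"
        )
    return int(np.searchsorted(edges, word_count, side="right") - 1)


def quantile_length_edges(
    entries: Sequence[SemiologyEntry], n_bins: int = 6
) -> list[int]:
    """Integer bin edges at word-count quantiles, covering all observed counts."""
    counts = np.array([e.word_count for e in entries])
    qs = np.quantile(counts, np.linspace(0, 1, n_bins + 1))
    edges = sorted(set(int(np.floor(q)) for q in qs[:-1]))
    edges.append(int(counts.max()) + 1)
    if len(edges) < 2:
        raise ValueError("degenerate word-count distribution: cannot form bins")
    return edges


# ---------------------------------------------------------------------------
# Naive baseline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NaiveBaseline:
    """Constant predictor that always emits the most frequent truth region."""

    region: str
    accuracy: float      # fraction of entries whose truth set contains the region
    weighted_f1: float   # weighted F1 of the constant predictor (secondary reading)


def naive_baseline(entries: Sequence[SemiologyEntry]) -> NaiveBaseline:
    """Score of a classifier that always predicts the majority truth region.

    A prediction counts as correct when the majority region is contained in
    the entry's (possibly multi-label) truth set. Ties on region frequency go
    to the earlier canonical region.
    """
    if not entries:
        raise CorpusError("cannot compute a baseline on an empty corpus")
    counts = Counter(region for e in entries for region in e.truth)
    majority = max(REGIONS, key=lambda r: (counts.get(r, 0), -REGION_INDEX[r]))
    correct = np.array([majority in e.truth for e in entries])
    accuracy = float(correct.mean())
    # weighted F1 of the constant predictor, via the shared scoring path
    from .metrics import Prediction, weighted_prf1

    predictions = [
        Prediction(
            entry_id=e.id,
            predicted=majority,
            truth=e.truth,
            correct=majority in e.truth,
            confidence=1.0,
            probability=1.0,
        )
        for e in entries
    ]
    _, _, f1 = weighted_prf1(predictions)
    return NaiveBaseline(region=majority, accuracy=accuracy, weighted_f1=f1)


def shuffled(entries: Sequence[SemiologyEntry], seed: int) -> list[SemiologyEntry]:
    """Corpus in a deterministic random order (utility for invariance tests)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(entries))
    return [entries[i] for i in order]


def summary_json(entries: Sequence[SemiologyEntry]) -> str:
    return json.dumps(corpus_summary(entries), indent=2, sort_keys=True)
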