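import numpy as np
import pytest

import semioloc as sl
from semioloc.parsing import RegionLikelihood


@pytest.fixture(scope="session")
def lexicon():
    return sl.RegionLexicon.default()


@pytest.fixture()
def toy_corpus_path(tmp_path):
    """Three-row TSV in the corpus dialect (tab-separated, ';' truth joins)."""
    rows = [
        "id\ttext\tlanguage\tregions",
        "e1\tLOC with automatisms\ten\tTemporal Lobe",
        "e2\tpelvic thrusting hypermotor\ten\tFrontal Lobe;Insula",
        "e3\tvisual aura flashing lights\ten\tOccipital Lobe",
    ]
    path = tmp_path / "toy.tsv"
    path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    return path


@pytest.fixture(scope="session")
def small_corpus():
    """200 singleton-truth synthetic entries (shared; treat as read-only)."""
    return sl.generate_corpus(
        sl.SyntheticCorpusParams(n=200, multilabel_prob=0.0, seed=42)
    )


@pytest.fixture(scope="session")
def default_corpus():
    """Study-scale defaults (n=1269, imbalanced multi-label)."""
    return sl.generate_corpus(sl.SyntheticCorpusParams(seed=7))


def likelihood(*values):
    return RegionLikelihood.from_array(values)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
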