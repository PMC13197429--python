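"""Synthetic corpus generator and mock responder behaviour."""

import numpy as np
import pytest

import semioloc as sl
from semioloc.synthetic import (
    BackendError,
    MockBackend,
    _derive_rng,
    backend_query,
    get_backend,
)


class TestGenerateCorpus:
    def test_deterministic_given_seed(self):
        params = sl.SyntheticCorpusParams(n=50, seed=9)
        a, b = sl.generate_corpus(params), sl.generate_corpus(params)
        assert [(e.id, e.text, e.truth) for e in a] == [
            (e.id, e.text, e.truth) for e in b
        ]

    def test_majority_fraction_matches_weights(self):
        params = sl.SyntheticCorpusParams(n=5000, multilabel_prob=0.0, seed=1)
        corpus = sl.generate_corpus(params)
        majority = np.mean([e.truth[0] == "Temporal Lobe" for e in corpus])
        # binomial standard error around the configured 0.38 weight
        assert majority == pytest.approx(0.3821, abs=0.02)

    def test_class_frequencies_within_three_se(self):
        params = sl.SyntheticCorpusParams(n=4000, multilabel_prob=0.0, seed=2)
        corpus = sl.generate_corpus(params)
        for region, weight in zip(sl.REGIONS, params.class_weights):
            freq = np.mean([e.truth[0] == region for e in corpus])
            se = np.sqrt(weight * (1 - weight) / params.n)
            assert abs(freq - weight) < 3 * se + 1e-9

    def test_zero_multilabel_prob_gives_singletons(self, small_corpus):
        assert all(len(e.truth) == 1 for e in small_corpus)

    def test_degenerate_weights_rejected(self):
        with pytest.raises(ValueError):
            sl.SyntheticCorpusParams(class_weights=(0.0,) * 7)

    def test_translations_attached(self):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=5, seed=3, translation_languages=("fr",))
        )
        assert all("fr" in e.translations for e in corpus)
        assert corpus[0].text_in("fr") != corpus[0].text


class TestSimulateResponse:
    def test_wellformed_without_malformation(self, small_corpus, lexicon):
        spec = sl.spec_for("ZS")
        params = sl.ResponderParams(malform_rate=0.0, seed=4)
        for entry in small_corpus[:50]:
            parsed = sl.parse_response(
                sl.simulate_response(entry, spec, params, lexicon=lexicon), lexicon
            )
            assert parsed.status == "ok"
            assert set(parsed.likelihoods.values) == set(sl.REGIONS)

    def test_deterministic_per_seed_entry_chain(self, small_corpus):
        spec = sl.spec_for("ZS")
        params = sl.ResponderParams(seed=5)
        entry = small_corpus[0]
        assert sl.simulate_response(entry, spec, params, 2) == sl.simulate_response(
            entry, spec, params, 2
        )
        assert sl.simulate_response(entry, spec, params, 1) != sl.simulate_response(
            entry, spec, params, 2
        )

    def test_cot_strategies_carry_reasoning_and_sources(self, small_corpus, lexicon):
        spec = sl.spec_for("CoT")
        params = sl.ResponderParams(seed=6)
        parsed = sl.parse_response(
            sl.simulate_response(small_corpus[0], spec, params, lexicon=lexicon), lexicon
        )
        assert parsed.reasoning and parsed.sources

    def test_chain_index_must_be_positive(self, small_corpus):
        with pytest.raises(ValueError):
            sl.simulate_response(
                small_corpus[0], sl.spec_for("ZS"), sl.ResponderParams(), chain_index=0
            )

    def test_fixed_accuracy_recovered(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=3000, multilabel_prob=0.0, seed=8)
        )
        spec = sl.spec_for("ZS")
        params = sl.ResponderParams(mode="fixed", accuracy=0.6, seed=9)
        hits = 0
        for entry in corpus:
            parsed = sl.parse_response(
                sl.simulate_response(entry, spec, params, lexicon=lexicon), lexicon
            )
            region, _ = sl.predict(parsed.likelihoods)
            hits += region in entry.truth
        se = np.sqrt(0.6 * 0.4 / len(corpus))
        assert hits / len(corpus) == pytest.approx(0.6, abs=3 * se)

    def test_malformation_fraction_matches_rate(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=5000, multilabel_prob=0.0, seed=10)
        )
        spec = sl.spec_for("ZS")
        params = sl.ResponderParams(malform_rate=0.1, seed=11)
        bad = sum(
            sl.parse_response(
                sl.simulate_response(e, spec, params, lexicon=lexicon), lexicon
            ).status
            != "ok"
            for e in corpus
        )
        assert bad / len(corpus) == pytest.approx(0.10, abs=0.013)


class TestBackend:
    def test_mock_backend_deterministic(self, small_corpus):
        backend = get_backend("mock", params=sl.ResponderParams(seed=12))
        meta = {"entry": small_corpus[0], "spec": sl.spec_for("ZS"), "chain_index": 1}
        assert backend.query("prompt", meta) == backend.query("prompt", meta)

    def test_unregistered_backend_is_configuration_error(self):
        with pytest.raises(BackendError, match="no backend registered"):
            get_backend("gpt-99")

    def test_five_chain_request_yields_five_cache_records(self, small_corpus, tmp_path):
        cache = sl.ResponseCache(tmp_path / "cache.jsonl")
        backend = MockBackend(sl.ResponderParams(seed=13))
        spec = sl.spec_for("SC")
        for chain in range(1, 6):
            backend_query(
                backend,
                "prompt",
                meta={"entry": small_corpus[0], "spec": spec, "chain_index": chain},
                cache=cache,
            )
        assert [r["chain_index"] for r in cache.records] == [1, 2, 3, 4, 5]
        reread = sl.ResponseCache(tmp_path / "cache.jsonl")
        assert len(reread.records) == 5


def test_derived_rng_stable_and_distinct():
    a = _derive_rng(1, "e1", 1).integers(0, 10**9)
    b = _derive_rng(1, "e1", 1).integers(0, 10**9)
    c = _derive_rng(1, "e1", 2).integers(0, 10**9)
    assert a == b and a != c
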