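"""Length, persona and language factor analyses (planted-effect recovery)."""

import numpy as np
import pytest

import semioloc as sl
from semioloc.ablations import language_sweep, length_analysis, persona_sweep
from semioloc.runner import evaluate_condition
from semioloc.synthetic import MockBackend

EDGES = (1, 4, 7, 11, 16, 24, 81)


def scored(corpus, params, lexicon, spec=None):
    spec = spec or sl.spec_for("ZS")
    backend = MockBackend(params, lexicon)
    return evaluate_condition(corpus, spec, backend, lexicon)


class TestLengthAnalysis:
    def test_planted_u_shape_recovered(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=1269, multilabel_prob=0.0, seed=21)
        )
        params = sl.ResponderParams(
            mode="fixed", accuracy=0.6, seed=22,
            length_effects=(EDGES, (0.8, 0.8, 0.4, 0.4, 0.8, 0.8)),
        )
        result = length_analysis(scored(corpus, params, lexicon), EDGES, seed=23)
        accs = [lv.accuracy for lv in result.levels]
        assert accs[0] > accs[2] and accs[5] > accs[3]  # U shape
        assert result.stats["kruskal_p"] < 0.001
        assert result.stats["ks_p"] < 0.05

    def test_length_blind_responder_not_flagged(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=800, multilabel_prob=0.0, seed=24)
        )
        params = sl.ResponderParams(mode="fixed", accuracy=0.6, seed=25)
        result = length_analysis(scored(corpus, params, lexicon), EDGES, seed=26)
        assert result.stats["ks_p"] > 0.05

    def test_surrogate_reproducible_and_bin_sizes_preserved(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=400, multilabel_prob=0.0, seed=27)
        )
        preds = scored(corpus, sl.ResponderParams(mode="fixed", seed=28), lexicon)
        a = length_analysis(preds, EDGES, n_shuffle=50, seed=29)
        b = length_analysis(preds, EDGES, n_shuffle=50, seed=29)
        assert a.stats["ks_p"] == b.stats["ks_p"]
        assert sum(lv.n for lv in a.levels) == len(preds)

    def test_bin_labels_use_half_open_notation(self, lexicon):
        corpus = sl.generate_corpus(sl.SyntheticCorpusParams(n=200, seed=30))
        preds = scored(corpus, sl.ResponderParams(seed=31), lexicon)
        result = length_analysis(preds, EDGES, n_shuffle=20, seed=32)
        assert result.levels[0].label == "[1, 4)"


class TestPersonaSweep:
    def test_persona_blind_responder_has_zero_deltas(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=500, multilabel_prob=0.0, seed=33)
        )
        backend = MockBackend(sl.ResponderParams(mode="fixed", accuracy=0.6, seed=34))
        result = persona_sweep(corpus, ["AI assistant", "neurologist"], backend)
        # conditions share the underlying draws, so blindness means exact zeros
        assert result.levels[1].delta_accuracy == 0.0
        assert result.levels[1].delta == 0.0

    def test_planted_expert_gain_recovered(self, lexicon):
        corpus = sl.generate_corpus(
            sl.SyntheticCorpusParams(n=1269, multilabel_prob=0.0, seed=35)
        )
        backend = MockBackend(
            sl.ResponderParams(
                mode="fixed", accuracy=0.5, seed=36,
                persona_effects={"expert epileptologist": 0.1},
            )
        )
        result = persona_sweep(corpus, list(sl.PERSONAS), backend)
        expert = next(l for l in result.levels if l.label == "expert epileptologist")
        # paired design: the delta estimate is binomial around the planted 0.1
        se = np.sqrt(0.1 * 0.9 / 1269)
        assert expert.delta_accuracy == pytest.approx(0.1, abs=3 * se)
        assert expert.delta_recall == pytest.approx(0.1, abs=3 * se)
        assert expert.delta > 0  # weighted F1 moves the same way

    def test_levels_ordered_as_configured(self, small_corpus):
        backend = MockBackend(sl.ResponderParams(seed=37))
        personas = ["neurologist", "AI assistant"]
        result = persona_sweep(small_corpus, personas, backend)
        assert [l.label for l in result.levels] == personas
        assert result.levels[0].delta == 0.0  # first persona is the baseline

    def test_empty_persona_list_rejected(self, small_corpus):
        with pytest.raises(ValueError):
            persona_sweep(small_corpus, [], MockBackend())


class TestLanguageSweep:
    def corpus(self, n=1269, seed=38):
        return sl.generate_corpus(
            sl.SyntheticCorpusParams(
                n=n, multilabel_prob=0.0, seed=seed, translation_languages=("fr",)
            )
        )

    def test_condition_labels(self, lexicon):
        corpus = self.corpus(n=120)
        result = language_sweep(corpus, ["fr"], MockBackend(sl.ResponderParams(seed=39)))
        assert [l.label for l in result.levels] == ["en:baseline", "fr:cross", "fr:same"]

    def test_language_blind_responder_has_null_deltas(self, lexicon):
        corpus = self.corpus(n=800, seed=40)
        backend = MockBackend(sl.ResponderParams(mode="fixed", accuracy=0.6, seed=41))
        result = language_sweep(corpus, ["fr"], backend)
        for level in result.levels[1:]:
            assert level.delta_accuracy == 0.0
            assert level.delta == 0.0

    def test_planted_same_language_penalty_recovered(self, lexicon):
        corpus = self.corpus(seed=42)
        backend = MockBackend(
            sl.ResponderParams(
                mode="fixed", accuracy=0.6, seed=43,
                prompt_language_effects={"fr": -0.05},
            )
        )
        result = language_sweep(corpus, ["fr"], backend)
        by_label = {l.label: l for l in result.levels}
        se = np.sqrt(0.05 * 0.95 / 1269)
        assert by_label["fr:same"].delta_accuracy == pytest.approx(-0.05, abs=3 * se)
        # the cross condition is untouched and paired: exactly zero
        assert by_label["fr:cross"].delta_accuracy == 0.0

    def test_missing_translation_is_an_error_naming_entries(self, small_corpus):
        with pytest.raises(ValueError, match="lack a 'fr' translation"):
            language_sweep(small_corpus, ["fr"], MockBackend())
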