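"""Baseline profiles, speaker distances, the asymmetric dialect matrix."""

import numpy as np
import pytest

from ndldist import (
    AsymmetricDistanceMatrix,
    Corpus,
    PronunciationRecord,
    WeightMatrix,
    accent_distance_resampled,
    baseline_profile,
    build_events,
    dialect_matrix,
    estimate_equilibrium,
    generate_lexicon,
    log_transform,
    parse_ipa,
    pearson,
    speaker_distance,
)

INVENTORY = list("ptkbdgmnslrieaou")


def unigram_weights() -> WeightMatrix:
    """Hand-built listener: three unigram cues with known weights for one word."""
    return WeightMatrix(cues=["x", "y", "z"], outcomes=["w"], V=np.array([[1.0], [0.8], [0.6]]))


def rec(speaker, meaning, ipa, freq=1.0):
    return PronunciationRecord(speaker, meaning, parse_ipa(ipa), freq)


class TestBaselineProfile:
    def test_single_speaker_single_tokens_is_own_activation(self):
        w = unigram_weights()
        c = Corpus([rec("a", "w", "x")])
        assert baseline_profile(w, c, n=1) == {"w": pytest.approx(1.0)}

    def test_mean_across_speakers(self):
        w = unigram_weights()
        c = Corpus([rec("a", "w", "x"), rec("b", "w", "z")])  # 1.0 and 0.6
        assert baseline_profile(w, c, n=1)["w"] == pytest.approx(0.8)

    def test_token_mean_within_speaker_before_speaker_mean(self):
        # speaker a: tokens 1.0 and 0.8 -> 0.9; speaker b: 0.6
        # correct order of averaging gives (0.9 + 0.6)/2 = 0.75, not the
        # pooled token mean (1.0 + 0.8 + 0.6)/3 = 0.8
        w = unigram_weights()
        c = Corpus([rec("a", "w", "x"), rec("a", "w", "y"), rec("b", "w", "z")])
        assert baseline_profile(w, c, n=1)["w"] == pytest.approx(0.75)

    def test_meaning_unknown_to_model_errors(self):
        w = unigram_weights()
        c = Corpus([rec("a", "other", "x")])
        with pytest.raises(ValueError, match="other"):
            baseline_profile(w, c, n=1)


class TestSpeakerDistance:
    def test_identical_speaker_has_zero_distance(self):
        corpus = generate_lexicon(12, INVENTORY, seed=5)
        w = estimate_equilibrium(build_events(corpus, 3))
        baseline = baseline_profile(w, corpus, 3)
        d = speaker_distance(w, baseline, corpus.records, "signed", 3)
        assert d.aggregate == pytest.approx(0.0, abs=1e-12)

    def test_uniform_shortfall(self):
        w = unigram_weights()
        baseline = {"w": 1.0}
        d = speaker_distance(w, baseline, [rec("s", "w", "z")], "signed", 1)
        assert d.aggregate == pytest.approx(0.4)
        assert d.per_outcome == {"w": pytest.approx(0.4)}

    def test_absolute_mode(self):
        w = unigram_weights()
        d = speaker_distance(w, {"w": 0.5}, [rec("s", "w", "x")], "absolute", 1)
        assert d.aggregate == pytest.approx(0.5)

    def test_uncovered_outcomes_skipped_not_scored(self, caplog):
        w = WeightMatrix(cues=["x", "y"], outcomes=["w", "v"], V=np.array([[1.0, 0.0], [0.0, 1.0]]))
        baseline = {"w": 1.0, "v": 1.0}
        d = speaker_distance(w, baseline, [rec("s", "w", "x")], "signed", 1)
        assert list(d.per_outcome) == ["w"]
        assert d.aggregate == pytest.approx(0.0)

    def test_no_covered_outcome_errors(self):
        w = unigram_weights()
        with pytest.raises(ValueError, match="covers no baseline meaning"):
            speaker_distance(w, {"other": 1.0}, [rec("s", "w", "x")], "signed", 1)


class TestAccentDistanceResampled:
    @pytest.fixture
    def multi_speaker_corpus(self):
        canonical = generate_lexicon(10, INVENTORY, seed=11)
        from ndldist import PerturbationModel, perturb_speaker

        records = []
        for i in range(6):
            m = PerturbationModel(substitution=0.05, inventory=INVENTORY, seed=11)
            records.extend(perturb_speaker(canonical, m, f"ref{i}").records)
        m = PerturbationModel(substitution=0.4, inventory=INVENTORY, seed=11)
        records.extend(perturb_speaker(canonical, m, "foreign").records)
        return Corpus(records)

    def test_split_sizes_and_reproducibility(self, multi_speaker_corpus):
        refs = [f"ref{i}" for i in range(6)]
        r1 = accent_distance_resampled(multi_speaker_corpus, refs, n_reps=2, seed=42)
        r2 = accent_distance_resampled(multi_speaker_corpus, refs, n_reps=2, seed=42)
        assert r1 == r2
        assert set(r1) == set(multi_speaker_corpus.speakers())

    def test_foreign_speaker_scores_higher_than_references(self, multi_speaker_corpus):
        refs = [f"ref{i}" for i in range(6)]
        res = accent_distance_resampled(multi_speaker_corpus, refs, n_reps=3, seed=0)
        ref_means = [res[r][0] for r in refs]
        assert res["foreign"][0] > max(ref_means)

    def test_single_reference_rejected(self, multi_speaker_corpus):
        with pytest.raises(ValueError, match="at least 2"):
            accent_distance_resampled(multi_speaker_corpus, ["ref0"], n_reps=1, seed=0)


class TestDialectMatrix:
    def test_identical_dialects_give_zero_matrix(self):
        c = generate_lexicon(8, INVENTORY, seed=3)
        m = dialect_matrix({"a": c, "b": c}, n=3)
        assert m.off_diagonal() == [pytest.approx(0.0, abs=1e-12)] * 2
        assert np.all(np.diag(m.values) == 0.0)

    def test_asymmetry_under_unequal_cue_overlap(self):
        # dialect b merges w1/w2 into homophones, so its listener splits the
        # cue's association (activations 0.5); dialect a keeps them apart.
        # Hand-derived: a hears b at (0 + 1)/2 = 0.5, b hears a at
        # (0 + 0.5)/2 = 0.25 -- asymmetric by construction.
        a = Corpus([rec("a", "w1", "a"), rec("a", "w2", "b")])
        b = Corpus([rec("b", "w1", "a"), rec("b", "w2", "a")])
        m = dialect_matrix({"a": a, "b": b}, n=3)
        assert m.cell("a", "b") == pytest.approx(0.5)
        assert m.cell("b", "a") == pytest.approx(0.25)
        assert m.cell("a", "b") != pytest.approx(m.cell("b", "a"))

    def test_empty_dialect_rejected(self):
        c = generate_lexicon(5, INVENTORY, seed=1)
        with pytest.raises(ValueError, match="at least 2"):
            dialect_matrix({"a": c})

    def test_diagonal_must_be_exact_zero(self):
        with pytest.raises(ValueError, match="diagonal"):
            AsymmetricDistanceMatrix(["a", "b"], np.array([[0.1, 0.2], [0.3, 0.0]]))

    def test_tsv_output_shape(self, tmp_path):
        c1 = generate_lexicon(6, INVENTORY, seed=1)
        from ndldist import PerturbationModel, perturb_speaker

        c2 = perturb_speaker(c1, PerturbationModel(substitution=0.3, inventory=INVENTORY, seed=1), "v2")
        m = dialect_matrix({"a": c1, "b": c2}, n=3)
        p = tmp_path / "matrix.tsv"
        m.write_tsv(p, header_comment="cfg")
        lines = [ln for ln in p.read_text(encoding="utf-8").splitlines() if not ln.startswith("# ")]
        assert lines[0].split("\t") == ["Listener", "a", "b"]
        assert len(lines) == 3


class TestLogTransform:
    def test_known_values(self):
        mask, out = log_transform([1.0, np.e, np.e**2])
        assert mask.all()
        np.testing.assert_allclose(out, [0.0, 1.0, 2.0])

    def test_zeros_excluded_by_default(self):
        mask, out = log_transform([0.0, 1.0, 0.0, np.e])
        assert mask.tolist() == [False, True, False, True]
        assert len(out) == 2

    def test_epsilon_policy_keeps_all(self):
        mask, out = log_transform([0.0, 1.0], epsilon_policy="epsilon", epsilon=1e-6)
        assert mask.all() and out[0] == pytest.approx(np.log(1e-6))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            log_transform([-0.1])

    def test_correlation_invariant_to_log_base(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0.1, 2.0, size=20)
        y = rng.normal(size=20)
        _, ln_d = log_transform(d)
        r_ln = pearson(ln_d, y)
        r_log10 = pearson(np.log10(d), y)
        assert r_ln == pytest.approx(r_log10)
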