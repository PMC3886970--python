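"""Equilibrium weights, incremental Rescorla-Wagner learning, activations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ndldist import (
    Event,
    RWParams,
    WeightMatrix,
    activation,
    activation_profile,
    build_events,
    estimate_equilibrium,
    simulate_rw,
)


def ev(cues, outcome, freq=1.0):
    return Event(frozenset(cues), outcome, freq)


class TestEstimateEquilibrium:
    def test_single_cue_single_outcome_saturates(self):
        w = estimate_equilibrium([ev("c", "O")])
        assert w.weight("c", "O") == pytest.approx(1.0)

    def test_ambiguous_cue_splits_evenly(self):
        w = estimate_equilibrium([ev("c", "O1"), ev("c", "O2")])
        assert w.weight("c", "O1") == pytest.approx(0.5)
        assert w.weight("c", "O2") == pytest.approx(0.5)

    def test_non_discriminative_cue_gets_zero(self):
        # hand-solved 2x2 system: c1 occurs with both outcomes, only c2
        # discriminates O, so V(c1,O)=0 and V(c2,O)=1
        w = estimate_equilibrium([ev(["c1", "c2"], "O"), ev(["c1"], "Oprime")])
        assert w.weight("c1", "O") == pytest.approx(0.0, abs=1e-10)
        assert w.weight("c2", "O") == pytest.approx(1.0)
        # and for O': full-rank solve gives V(c1)=1, V(c2)=-1
        assert w.weight("c1", "Oprime") == pytest.approx(1.0)
        assert w.weight("c2", "Oprime") == pytest.approx(-1.0)

    def test_empty_events_rejected(self):
        with pytest.raises(ValueError):
            estimate_equilibrium([])

    def test_residual_small_on_full_rank_system(self):
        events = [ev(["a"], "O1", 3), ev(["b"], "O2", 2), ev(["a", "b"], "O1", 1)]
        w = estimate_equilibrium(events)
        assert w.residual <= 1e-8

    @given(st.integers(0, 2**31 - 1), st.floats(1.5, 1000.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, seed, factor):
        rng = np.random.default_rng(seed)
        events = []
        for _ in range(6):
            cues = rng.choice(list("abcde"), size=rng.integers(1, 4), replace=False)
            events.append(ev(cues, f"O{rng.integers(0, 3)}", float(rng.integers(1, 20))))
        w1 = estimate_equilibrium(events)
        w2 = estimate_equilibrium([Event(e.cues, e.outcome, e.frequency * factor) for e in events])
        assert w1.cues == w2.cues and w1.outcomes == w2.outcomes
        np.testing.assert_allclose(w1.V, w2.V, atol=1e-10)


class TestSimulateRW:
    def test_single_association_approaches_asymptote_monotonically(self):
        # closed form: V_t = 1 - (1 - alpha*beta)^t
        p = RWParams(alpha=0.5, beta_present=0.2, beta_absent=0.2)
        trajectory = [
            simulate_rw([ev("c", "O")], p, n_trials=t).weight("c", "O") for t in (1, 3, 10, 50)
        ]
        for t, v in zip((1, 3, 10, 50), trajectory):
            assert v == pytest.approx(1 - (1 - 0.1) ** t)
        assert trajectory == sorted(trajectory)

    def test_blocking_of_a_redundant_cue(self):
        p = RWParams(alpha=0.5, beta_present=0.2, beta_absent=0.2)
        pretrained = simulate_rw([ev(["c1"], "O")], p, n_trials=500)
        blocked = simulate_rw([ev(["c1", "c2"], "O")], p, n_trials=200, initial=pretrained)
        # c1 already predicts O perfectly, so c2 accrues (almost) nothing
        assert abs(blocked.weight("c2", "O")) < 1e-6
        # control: without pretraining the compound cue learns freely
        control = simulate_rw([ev(["c1", "c2"], "O")], p, n_trials=200)
        assert control.weight("c2", "O") > 0.4

    @pytest.mark.filterwarnings("ignore:overflow")
    def test_divergence_detected(self):
        events = [ev(["a", "b", "c"], "O1"), ev(["a", "b", "c"], "O2")]
        p = RWParams(alpha=1.0, beta_present=1.0, beta_absent=1.0)
        with pytest.raises(FloatingPointError):
            simulate_rw(events, p, n_trials=5000)

    @pytest.mark.parametrize("seed", range(10))
    def test_long_run_matches_equilibrium(self, seed):
        # randomized small instances: <=6 cues, <=3 outcomes
        rng = np.random.default_rng(seed)
        cues = list("abcdef")
        events = []
        for _ in range(int(rng.integers(3, 7))):
            cs = rng.choice(cues, size=rng.integers(1, 4), replace=False)
            events.append(ev(cs, f"O{rng.integers(0, 3)}", float(rng.integers(1, 6))))
        eq = estimate_equilibrium(events)
        # learning rate trades residual limit-cycle amplitude against the
        # convergence time along small co-occurrence eigenvalues; 0.02 with
        # 1e5 trials lands well inside 0.02 of the equilibrium on all seeds
        rw = simulate_rw(
            events, RWParams(alpha=0.1, beta_present=0.2, beta_absent=0.2), n_trials=100_000
        )
        got = rw.to_frame().loc[eq.cues, eq.outcomes].to_numpy()
        np.testing.assert_allclose(got, eq.V, atol=0.02)

    def test_sampled_regime_reproducible(self):
        events = [ev("a", "O1", 2), ev("b", "O2", 1)]
        w1 = simulate_rw(events, n_trials=500, seed=7, regime="sample")
        w2 = simulate_rw(events, n_trials=500, seed=7, regime="sample")
        np.testing.assert_array_equal(w1.V, w2.V)


class TestActivation:
    def test_published_activations_from_published_weights(self, table4_weights):
        # the four worked activation values recomputed from the printed weights
        assert activation(table4_weights, {"#wɪ", "wɪθ", "ɪθ#"}, "with") == pytest.approx(0.9995)
        assert activation(table4_weights, {"#hɚ", "hɚɹ", "ɚɹ#"}, "her") == pytest.approx(1.0000)
        # foreign pronunciations: unknown cues contribute nothing
        assert activation(table4_weights, {"#wɪ", "wɪz", "ɪz#"}, "with") == pytest.approx(0.2519)
        assert activation(table4_weights, {"#xɚ", "xɚɹ", "ɚɹ#"}, "her") == pytest.approx(0.2594)

    def test_all_unknown_cues_give_exactly_zero(self, table4_weights):
        assert activation(table4_weights, {"qq", "zz"}, "with") == 0.0

    def test_unknown_outcome_lists_known(self, table4_weights):
        with pytest.raises(KeyError, match="her"):
            activation(table4_weights, {"#wɪ"}, "nope")

    def test_linear_and_monotone_in_known_positive_cues(self, table4_weights):
        base = activation(table4_weights, {"#wɪ"}, "with")
        more = activation(table4_weights, {"#wɪ", "wɪθ"}, "with")
        assert more == pytest.approx(base + 0.3738)
        assert more > base

    def test_profile_matches_per_outcome_activation(self, table4_weights):
        cues = {"#wɪ", "wɪθ", "ɪθ#"}
        prof = activation_profile(table4_weights, cues)
        assert prof["with"] == pytest.approx(activation(table4_weights, cues, "with"))
        assert prof["her"] == pytest.approx(0.0)


class TestBuildEvents:
    def test_one_event_per_record_with_frequencies(self, table3_corpus):
        events = build_events(table3_corpus, 3)
        assert len(events) == 4
        assert [e.frequency for e in events] == [28_169_384, 28_169_384, 852_131, 852_131]
        assert events[0].cues == {"#wɪ", "wɪθ", "ɪθ#"}
        assert events[3].cues == {"#ɚ#"}

    def test_table3_training_surface(self, table3_corpus):
        w = estimate_equilibrium(build_events(table3_corpus, 3))
        assert (len(w.cues), len(w.outcomes)) == (9, 2)


class TestWeightMatrixIO:
    def test_tsv_round_trip(self, table4_weights, tmp_path):
        p = tmp_path / "weights.tsv"
        table4_weights.write_tsv(p, decimals=6, header_comment="cfg")
        back = WeightMatrix.read_tsv(p)
        assert back.cues == table4_weights.cues
        assert back.outcomes == table4_weights.outcomes
        np.testing.assert_allclose(back.V, table4_weights.V, atol=1e-6)
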