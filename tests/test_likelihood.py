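"""Scored-events likelihood: hand oracles, log-space checks, enumeration."""

import numpy as np
import pytest

from ordsustain import (
    EventSequence,
    ScoredEventsLikelihood,
    StagePrior,
    build_event_index,
    enumerate_valid_sequences,
    stage_levels,
    validate_sequence,
)
from ordsustain.likelihood import (
    exact_sequence_posterior,
    mixture_loglik,
    subject_likelihood,
    subject_stage_likelihood,
)

from conftest import evidence_from_rows


class TestStageLevels:
    def test_counting_events_up_to_stage(self):
        from ordsustain import SymptomDef, SymptomDictionary

        d = SymptomDictionary(
            (SymptomDef("T", "c", ("0", "1", "2")), SymptomDef("A", "c", ("0", "1")))
        )
        idx = build_event_index(d)
        # seq: T->1, A->1, T->2
        seq = EventSequence((idx.event_id("T", 1), idx.event_id("A", 1), idx.event_id("T", 2)))
        assert stage_levels(seq, 2, idx) == {"T": 1, "A": 1}
        assert stage_levels(seq, 0, idx) == {"T": 0, "A": 0}
        assert stage_levels(seq, 3, idx) == {"T": 2, "A": 1}

    def test_stage_out_of_range_rejected(self, binary_pair_dict):
        idx = build_event_index(binary_pair_dict)
        with pytest.raises(ValueError, match="stage"):
            stage_levels(EventSequence((0, 1)), 3, idx)


class TestValidateSequence:
    def test_descending_levels_invalid(self):
        from ordsustain import SymptomDef, SymptomDictionary

        d = SymptomDictionary((SymptomDef("A", "c", ("0", "1", "2")),))
        idx = build_event_index(d)
        assert validate_sequence(EventSequence((1, 0)), idx) is False
        assert validate_sequence(EventSequence((0, 1)), idx) is True

    def test_interleaved_symptoms_valid(self):
        from ordsustain import SymptomDef, SymptomDictionary

        d = SymptomDictionary(
            (SymptomDef("A", "c", ("0", "1", "2")), SymptomDef("B", "c", ("0", "1")))
        )
        idx = build_event_index(d)
        # A:1, B:1, A:2
        assert validate_sequence(EventSequence((0, 2, 1)), idx) is True

    def test_all_binary_symptoms_always_valid(self):
        # binary symptoms impose no within-symptom constraint
        from ordsustain import SymptomDef, SymptomDictionary

        rng = np.random.default_rng(0)
        d = SymptomDictionary(tuple(SymptomDef(f"b{i}", "c", ("0", "1")) for i in range(4)))
        idxb = build_event_index(d)
        for _ in range(10):
            perm = rng.permutation(idxb.n_events)
            assert validate_sequence(EventSequence(tuple(perm)), idxb) is True

    def test_non_permutation_rejected(self, binary_pair_dict):
        idx = build_event_index(binary_pair_dict)
        with pytest.raises(ValueError, match="permutation"):
            validate_sequence(EventSequence((0, 0)), idx)


@pytest.fixture
def two_binary_evidence(binary_pair_dict):
    rows = [{"A": [0.1, 0.9], "B": [0.95, 0.05]}]
    return evidence_from_rows(binary_pair_dict, rows)


class TestHandOracles:
    """Frozen hand-multiplication values for the 2-binary-symptom instance."""

    def test_stage_conditional_likelihood(self, binary_pair_dict, two_binary_evidence):
        idx = build_event_index(binary_pair_dict)
        row = {"A": np.array([0.1, 0.9]), "B": np.array([0.95, 0.05])}
        seq = EventSequence((0, 1))  # A:1 then B:1
        assert subject_stage_likelihood(row, seq, 1, idx) == pytest.approx(0.9 * 0.95)
        assert subject_stage_likelihood(row, seq, 0, idx) == pytest.approx(0.1 * 0.95)
        assert subject_stage_likelihood(row, seq, 2, idx) == pytest.approx(0.9 * 0.05)

    def test_stage_marginalized_likelihood_uniform_prior(self, binary_pair_dict):
        idx = build_event_index(binary_pair_dict)
        row = {"A": np.array([0.1, 0.9]), "B": np.array([0.95, 0.05])}
        seq = EventSequence((0, 1))
        lik = subject_likelihood(row, seq, StagePrior.uniform(2), idx)
        assert lik == pytest.approx((0.095 + 0.855 + 0.045) / 3)
        assert lik == pytest.approx(0.33167, abs=5e-6)

    def test_degenerate_prior_collapses_to_stage(self, binary_pair_dict):
        idx = build_event_index(binary_pair_dict)
        row = {"A": np.array([0.1, 0.9]), "B": np.array([0.95, 0.05])}
        prior = StagePrior(np.array([0.0, 1.0, 0.0]))
        assert subject_likelihood(row, EventSequence((0, 1)), prior, idx) == pytest.approx(0.855)

    def test_flat_evidence_gives_unit_likelihood(self, binary_pair_dict):
        idx = build_event_index(binary_pair_dict)
        row = {"A": np.ones(2), "B": np.ones(2)}
        for k in range(3):
            assert subject_stage_likelihood(row, EventSequence((0, 1)), k, idx) == 1.0
        assert subject_likelihood(
            row, EventSequence((0, 1)), StagePrior.uniform(2), idx
        ) == pytest.approx(1.0)


class TestEngineAgainstReference:
    def test_log_space_engine_matches_naive_product(self, small_dict):
        rng = np.random.default_rng(7)
        idx = build_event_index(small_dict)
        rows = []
        for _ in range(9):
            row = {}
            for s in small_dict:
                v = rng.uniform(0.05, 1.0, s.n_levels)
                row[s.name] = list(v / v.sum())
            rows.append(row)
        tensor = evidence_from_rows(small_dict, rows)
        engine = ScoredEventsLikelihood(tensor, idx)
        for seq_arr in list(enumerate_valid_sequences(idx))[:20]:
            seq = EventSequence(tuple(seq_arr))
            naive = mixture_loglik(tensor, [seq], np.array([1.0]), idx)
            assert engine.total_loglik(seq_arr) == pytest.approx(naive, abs=1e-9)

    def test_mixture_reductions(self, small_dict):
        rng = np.random.default_rng(3)
        idx = build_event_index(small_dict)
        rows = []
        for _ in range(5):
            row = {}
            for s in small_dict:
                v = rng.uniform(0.05, 1.0, s.n_levels)
                row[s.name] = list(v / v.sum())
            rows.append(row)
        tensor = evidence_from_rows(small_dict, rows)
        engine = ScoredEventsLikelihood(tensor, idx)
        seqs = list(enumerate_valid_sequences(idx))
        s0, s1 = seqs[0], seqs[3]
        single = engine.mixture_loglik(s0[None, :], np.array([1.0]))
        # two identical components collapse to one
        dup = engine.mixture_loglik(np.vstack([s0, s0]), np.array([0.3, 0.7]))
        assert dup == pytest.approx(single, abs=1e-9)
        # 5-subject mixture matches the per-subject reference computation
        two = engine.mixture_loglik(np.vstack([s0, s1]), np.array([0.4, 0.6]))
        ref = mixture_loglik(
            tensor,
            [EventSequence(tuple(s0)), EventSequence(tuple(s1))],
            np.array([0.4, 0.6]),
            idx,
        )
        assert two == pytest.approx(ref, abs=1e-9)

    def test_empty_mixture_rejected(self, flat_engine):
        with pytest.raises(ValueError, match="empty"):
            flat_engine.mixture_loglik(np.empty((0, 5), dtype=np.int64), np.array([]))

    def test_exchangeability_of_indistinguishable_events(self, small_dict):
        # evidence flat on 'mood' and 'mri': swapping their events changes nothing
        idx = build_event_index(small_dict)
        rows = [
            {
                "tremor": [0.7, 0.2, 0.1],
                "ataxia": [0.3, 0.7],
                "mood": [1.0, 1.0],
                "mri": [1.0, 1.0],
            }
        ]
        tensor = evidence_from_rows(small_dict, rows)
        engine = ScoredEventsLikelihood(tensor, idx)
        e_mood = idx.event_id("mood", 1)
        e_mri = idx.event_id("mri", 1)
        seq_a = np.array([idx.event_id("tremor", 1), e_mood, idx.event_id("tremor", 2),
                          e_mri, idx.event_id("ataxia", 1)])
        seq_b = seq_a.copy()
        seq_b[[1, 3]] = seq_b[[3, 1]]
        assert engine.total_loglik(seq_a) == pytest.approx(
            engine.total_loglik(seq_b), abs=1e-12
        )


class TestExactPosterior:
    def test_posterior_normalizes_over_valid_sequences(self, small_dict):
        rng = np.random.default_rng(11)
        idx = build_event_index(small_dict)
        rows = []
        for _ in range(6):
            row = {}
            for s in small_dict:
                v = rng.uniform(0.05, 1.0, s.n_levels)
                row[s.name] = list(v)
            rows.append(row)
        tensor = evidence_from_rows(small_dict, rows)
        engine = ScoredEventsLikelihood(tensor, idx)
        seqs, post = exact_sequence_posterior(engine)
        # N=5 with one 3-level symptom: 5!/2 valid orderings
        assert len(seqs) == 60
        assert post.sum() == pytest.approx(1.0, abs=1e-12)
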