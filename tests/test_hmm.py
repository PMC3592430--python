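"""Tests for supervised HMM training, Viterbi decoding and segment extraction."""

import numpy as np
import pytest

from oracles import enumerate_best_path
from ssrscan import TwoStateHMM, extract_segments, train_supervised, viterbi
from ssrscan.hmm import path_log_probability
from ssrscan.scoring import ScoreSeries


def _series(scores):
    return ScoreSeries("s", np.asarray(scores, dtype=np.int16))


def _uniform_model(n=6):
    return TwoStateHMM(
        priors=[0.5, 0.5],
        transitions=[[0.5, 0.5], [0.5, 0.5]],
        emissions=np.full((2, n + 1), 1.0 / (n + 1)),
    )


def _random_model(rng, n=6):
    return TwoStateHMM(
        priors=rng.dirichlet([1, 1]),
        transitions=np.vstack([rng.dirichlet(np.ones(2)), rng.dirichlet(np.ones(2))]),
        emissions=np.vstack(
            [rng.dirichlet(np.ones(n + 1)), rng.dirichlet(np.ones(n + 1))]
        ),
    )


class TestTrainSupervised:
    def test_all_background_priors_closed_form(self):
        # Ten segments, all starting non-MS: with add-one smoothing the
        # non-MS prior is (K+1)/(K+2).
        data = [(_series([0] * 50), [0] * 50)]
        model = train_supervised(data, segment_length=5, require_both_states=False)
        assert model.priors[0] == pytest.approx(11 / 12)

    def test_no_ms_labels_rejected_by_default(self):
        with pytest.raises(ValueError, match="no MS-labeled positions"):
            train_supervised([(_series([0] * 50), [0] * 50)], segment_length=5)

    def test_transition_counts_match_hand_count(self):
        # One 10-symbol series, one labeled nonMS->MS switch, no segment cuts.
        labels = [0, 0, 0, 0, 1, 1, 1, 1, 1, 1]
        scores = [0, 1, 0, 2, 6, 6, 5, 6, 6, 6]
        model = train_supervised([(_series(scores), labels)], segment_length=100)
        # hand counts: nonMS->nonMS 3, nonMS->MS 1, MS->MS 5, MS->nonMS 0
        assert model.transitions[0, 0] == pytest.approx((3 + 1) / (4 + 2))
        assert model.transitions[0, 1] == pytest.approx((1 + 1) / (4 + 2))
        assert model.transitions[1, 0] == pytest.approx((0 + 1) / (5 + 2))
        assert model.transitions[1, 1] == pytest.approx((5 + 1) / (5 + 2))

    def test_segment_joins_not_counted_as_bigrams(self):
        labels = [0, 0, 1, 1]
        scores = [0, 0, 6, 6]
        joined = train_supervised([(_series(scores), labels)], segment_length=4,
                                  require_both_states=False)
        cut = train_supervised([(_series(scores), labels)], segment_length=2,
                               require_both_states=False)
        # cutting between positions 1 and 2 removes the only 0->1 bigram
        assert joined.transitions[0, 1] > cut.transitions[0, 1]
        # and the second segment's start now contributes an MS prior count
        assert cut.priors[1] > joined.priors[1]

    def test_rows_are_stochastic_and_positive(self, rng):
        scores = rng.integers(0, 7, size=1000)
        labels = (scores > 3).astype(int)
        model = train_supervised([(_series(scores), labels)])
        model.validate()
        assert model.emissions.min() > 0  # add-one smoothing

    def test_recovers_generating_model_at_moderate_size(self, rng):
        truth = TwoStateHMM(
            priors=[0.9, 0.1],
            transitions=[[0.99, 0.01], [0.05, 0.95]],
            emissions=[
                [0.3, 0.3, 0.2, 0.1, 0.05, 0.03, 0.02],
                [0.02, 0.03, 0.05, 0.1, 0.2, 0.3, 0.3],
            ],
        )
        scores, states = truth.sample(120_000, rng)
        model = train_supervised([(_series(scores), states)], segment_length=500)
        assert np.abs(model.transitions - truth.transitions).max() < 0.02
        assert np.abs(model.emissions - truth.emissions).max() < 0.02


class TestViterbi:
    def test_deterministic_emissions_force_path(self):
        eps = 1e-12
        model = TwoStateHMM(
            priors=[0.5, 0.5],
            transitions=[[0.5, 0.5], [0.5, 0.5]],
            emissions=[
                [1 - 6 * eps] + [eps] * 6,  # nonMS emits only 0
                [eps] * 6 + [1 - 6 * eps],  # MS emits only 6
            ],
        )
        path = viterbi(_series([0, 0, 6, 6, 0]), model)
        assert path.tolist() == [0, 0, 1, 1, 0]

    def test_zero_prior_excludes_start_state(self):
        model = TwoStateHMM(
            priors=[1.0, 0.0],
            transitions=[[0.5, 0.5], [0.5, 0.5]],
            emissions=[[0.01] * 6 + [0.94], [0.01] * 6 + [0.94]],
        )
        path = viterbi(_series([6, 6, 6]), model)
        assert path[0] == 0

    def test_ties_break_toward_background(self):
        path = viterbi(_series([0, 3, 6, 2]), _uniform_model())
        assert path.tolist() == [0, 0, 0, 0]

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(12):
            model = _random_model(rng)
            length = int(rng.integers(1, 11))
            scores = rng.integers(0, 7, size=length)
            best, _ = enumerate_best_path(
                scores.tolist(),
                model.priors.tolist(),
                model.transitions.tolist(),
                model.emissions.tolist(),
            )
            path = viterbi(_series(scores), model)
            assert path_log_probability(_series(scores), path, model) == pytest.approx(
                best, abs=1e-9
            )

    def test_beats_random_paths(self, rng):
        model = _random_model(rng)
        scores = rng.integers(0, 7, size=60)
        series = _series(scores)
        best = path_log_probability(series, viterbi(series, model), model)
        for _ in range(1000):
            random_path = rng.integers(0, 2, size=60)
            assert best >= path_log_probability(series, random_path, model)

    def test_score_outside_support_rejected(self):
        with pytest.raises(ValueError):
            viterbi(_series([0, 7]), _uniform_model(n=6))

    def test_decoding_is_deterministic(self, rng):
        model = _random_model(rng)
        scores = rng.integers(0, 7, size=500)
        first = viterbi(_series(scores), model)
        second = viterbi(_series(scores), model)
        assert np.array_equal(first, second)


class TestExtractSegments:
    @pytest.mark.parametrize(
        "path, expected",
        [
            ([0, 1, 1, 0, 1], [(1, 3), (4, 5)]),
            ([0, 0, 0], []),
            ([1, 1, 1, 1], [(0, 4)]),
            ([], []),
        ],
    )
    def test_examples(self, path, expected):
        segs = extract_segments(np.asarray(path, dtype=np.uint8), "chr")
        assert [(s.start, s.end) for s in segs] == expected
        assert all(s.seq_id == "chr" for s in segs)
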