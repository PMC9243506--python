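"""Evaluation harnesses: fold structure, subject partitioning, the online
sliding window, and character decoding."""

import numpy as np
import pytest
from sklearn.linear_model import LogisticRegression

import p300wide as pw
from p300wide.estimator import SklearnAdapter
from p300wide.experiments import ExperimentConfig


class _ProbeClassifier:
    """Records what it is fitted/tested on; predicts via a trivial rule.

    Epoch index is planted in sample (0, 0) so partitions can be audited.
    """

    log: list

    def __init__(self, log):
        self.log = log

    def fit(self, X, y, subject_ids=None, profiles=None):
        self.log.append(("fit", np.asarray(X)[:, 0, 0].copy(), list(subject_ids)))
        return self

    def predict_proba(self, X, subject_ids=None, profiles=None):
        self.log.append(("test", np.asarray(X)[:, 0, 0].copy(), list(subject_ids)))
        n = len(X)
        return np.column_stack([np.ones(n), np.zeros(n)])


def _tagged_dataset(n_subjects=3, n=60, targets=12):
    """Tiny labeled epoch sets whose epochs carry a global index tag."""
    counter = 0
    dataset = {}
    for s in range(n_subjects):
        epochs = np.zeros((n, 30, 90))
        epochs[:, 0, 0] = np.arange(counter, counter + n)
        counter += n
        labels = np.array([1] * targets + [0] * (n - targets))
        dataset[f"S{s}"] = pw.EpochSet(
            epochs=epochs,
            labels=labels,
            subject_ids=np.array([f"S{s}"] * n, dtype=object),
            fs=100.0,
        )
    return dataset


class TestAccuracy:
    def test_perfect_predictions(self):
        assert pw.accuracy(np.array([0.9, 0.1, 0.8]), np.array([1, 0, 1])) == 1.0

    def test_threshold_boundary_predicts_positive(self):
        # p exactly 0.5 counts as a predicted target
        assert pw.accuracy(np.array([0.5, 0.5]), np.array([1, 0])) == 0.5

    def test_matches_brute_force_count(self, rng):
        p = rng.random(200)
        y = rng.integers(0, 2, 200)
        agree = sum(1 for pi, yi in zip(p, y) if (pi >= 0.5) == bool(yi))
        assert pw.accuracy(p, y) == agree / 200

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pw.accuracy(np.array([]), np.array([]))


class TestWithinSubjectCV:
    def test_every_epoch_tested_exactly_once_and_folds_disjoint(self):
        dataset = _tagged_dataset(n_subjects=1)
        log = []
        table = pw.within_subject_cv(dataset, lambda: _ProbeClassifier(log), ExperimentConfig())
        tested = np.concatenate([tags for kind, tags, _ in log if kind == "test"])
        assert sorted(tested.astype(int).tolist()) == list(range(60))
        for (k1, fit_tags, _), (k2, test_tags, _) in zip(log[::2], log[1::2]):
            assert not set(fit_tags) & set(test_tags)
            assert len(test_tags) == pytest.approx(12, abs=1)  # ~20% folds
        assert len(table) == 5

    def test_subject_with_too_few_minority_epochs_errors(self):
        dataset = _tagged_dataset(n_subjects=1, targets=3)
        with pytest.raises(ValueError, match="fewer than"):
            pw.within_subject_cv(dataset, lambda: _ProbeClassifier([]), ExperimentConfig())

    def test_high_snr_subject_is_nearly_perfectly_classified(self):
        # generator configured for near-separability; oracle = any
        # consistent classifier (plain logistic regression here)
        cfg = pw.ParadigmConfig(runs_per_session=2)
        prof = pw.SubjectProfile(
            subject_id="HS", sex="M", age_group="young",
            p300_amplitude=10.0, p300_latency=350.0, latency_jitter_sd=2.0, noise_scale=2.0,
        )
        rec = pw.synthesize_session(prof, cfg, seed=4)
        epochs, _ = pw.preprocess_recording(rec)
        table = pw.within_subject_cv(
            {"HS": epochs}, lambda: SklearnAdapter(LogisticRegression(max_iter=1000))
        )
        assert table["accuracy"].mean() > 0.95


class TestLeaveOneSubjectOut:
    def test_one_row_per_subject_and_heldout_never_trained_on(self):
        dataset = _tagged_dataset(n_subjects=4)
        log = []
        table = pw.leave_one_subject_out(dataset, lambda: _ProbeClassifier(log))
        assert len(table) == 4
        assert set(table["participant"]) == set(dataset)
        fits = [entry for entry in log if entry[0] == "fit"]
        tests = [entry for entry in log if entry[0] == "test"]
        for (_, _, fit_ids), (_, _, test_ids) in zip(fits, tests):
            assert set(test_ids).isdisjoint(set(fit_ids))
            assert len(set(fit_ids)) == 3

    def test_single_subject_is_rejected(self):
        dataset = _tagged_dataset(n_subjects=1)
        with pytest.raises(ValueError, match="at least 2"):
            pw.leave_one_subject_out(dataset, lambda: _ProbeClassifier([]))


class TestSplitHalf:
    def test_disjoint_splits_and_row_count(self):
        dataset = _tagged_dataset(n_subjects=8)
        log = []
        cfg = ExperimentConfig(design="split_half", n_repeats=4, seed=1)
        table = pw.split_half(dataset, lambda: _ProbeClassifier(log), cfg)
        assert len(table) == 16  # 4 repeats x 4 test subjects
        fits = [set(ids) for kind, _, ids in log if kind == "fit"]
        for rep in range(4):
            test_subjects = set(
                table[table["repeat"] == rep]["participant"]
            )
            assert test_subjects.isdisjoint(fits[rep])
            assert len(fits[rep]) == 4

    def test_repeats_are_seeded(self):
        dataset = _tagged_dataset(n_subjects=8)
        cfg = ExperimentConfig(design="split_half", seed=9)
        a = pw.split_half(dataset, lambda: _ProbeClassifier([]), cfg)
        b = pw.split_half(dataset, lambda: _ProbeClassifier([]), cfg)
        assert a.equals(b)

    def test_too_few_subjects_rejected(self):
        dataset = _tagged_dataset(n_subjects=5)
        with pytest.raises(ValueError, match="subjects"):
            pw.split_half(dataset, lambda: _ProbeClassifier([]))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((80, 30, 90))
    y = rng.integers(0, 2, 80)
    clf = pw.WideDeepP300Classifier(n_passes=1, random_state=0)
    clf.fit(X, y)
    return clf


class TestOnlinePrediction:

    def _stream(self, seconds=10.0):
        prof = pw.sample_profiles(1, seed=2)[0]
        cfg = pw.ParadigmConfig()
        sched = pw.generate_flash_schedule(cfg, (0, 0), seed=3)
        rec = pw.synthesize_recording(sched, prof, cfg, seed=4)
        n = int(seconds * rec.fs)
        return (
            pw.ContinuousRecording(
                data=rec.data[:, :n], fs=rec.fs, channel_names=rec.channel_names,
                markers=[], subject_id=prof.subject_id,
            ),
            prof,
        )

    def test_ten_second_stream_gives_19_outputs(self, fitted):
        stream, prof = self._stream(10.0)
        times, probs = pw.online_sliding_predict(stream, fitted.model_, prof)
        assert len(probs) == 19  # floor((10 - 1)/0.5) + 1
        assert times[0] == 1.0 and times[-1] == 10.0
        assert ((probs > 0.0) & (probs < 1.0)).all()

    def test_short_stream_warns_and_returns_empty(self, fitted):
        stream, prof = self._stream(0.8)
        with pytest.warns(UserWarning, match="shorter"):
            times, probs = pw.online_sliding_predict(stream, fitted.model_, prof)
        assert len(times) == 0 and len(probs) == 0

    def test_identical_buffer_gives_identical_output(self, fitted):
        stream, prof = self._stream(2.0)
        _, p1 = pw.online_sliding_predict(stream, fitted.model_, prof)
        _, p2 = pw.online_sliding_predict(stream, fitted.model_, prof)
        np.testing.assert_array_equal(p1, p2)


class TestCharacterDecoding:
    def _run_probs(self, target=(2, 3), hit=1.0, miss=0.0, cfg=None):
        cfg = cfg or pw.ParadigmConfig()
        events = pw.generate_flash_schedule(cfg, target, seed=5)
        lines = np.array([e.line_index for e in events])
        probs = np.where([e.is_target for e in events], hit, miss)
        return probs, lines

    def test_confident_probabilities_decode_the_target(self):
        probs, lines = self._run_probs(target=(4, 6))
        assert pw.decode_character(probs, lines) == (4, 6)

    def test_uniform_probabilities_fall_back_to_lowest_index(self):
        probs, lines = self._run_probs(hit=0.5, miss=0.5)
        assert pw.decode_character(probs, lines) == (0, 0)

    def test_aggregation_requires_full_line_coverage(self):
        probs, lines = self._run_probs()
        with pytest.raises(ValueError, match="covered"):
            pw.decode_character(probs[:-1], lines[:-1])

    def test_noisy_but_biased_probabilities_still_decode(self, rng):
        probs, lines = self._run_probs(target=(1, 2), hit=0.8, miss=0.2)
        probs = np.clip(probs + rng.normal(0, 0.05, len(probs)), 0, 1)
        assert pw.decode_character(probs, lines) == (1, 2)
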