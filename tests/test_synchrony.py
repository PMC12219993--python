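"""Group synchrony statistics, rest null, FDR, and tripartite classification."""

import numpy as np
import pytest

from edgesync.boundaries import convolve_boundaries
from edgesync.events import EventSeries
from edgesync.synchrony import (
    ASYNCHRONOUS,
    BOUNDARY,
    MOVIE,
    NON_EVENT,
    GroupEventMatrix,
    classify_frames,
    label_subject_events,
    rest_null_fractions,
    shift_null_fractions,
    stack_events,
    synchrony_test,
)


def make_events(frames_binary, tr=1.0):
    frames_binary = np.asarray(frames_binary, dtype=int)
    return EventSeries(
        frames=frames_binary,
        peak_frames=np.flatnonzero(frames_binary),
        alpha=0.05, n_null=1, tr_seconds=tr,
    )


class TestStackEvents:
    def test_disjoint_events_column_sums(self):
        rows = [np.eye(1, 10, k).ravel().astype(int) for k in (1, 4, 7)]
        g = stack_events([make_events(r) for r in rows])
        assert set(g.data.sum(axis=0)) <= {0, 1}

    def test_shared_frame_sums_to_subject_count(self):
        row = np.zeros(10, dtype=int)
        row[3] = 1
        g = stack_events([make_events(row)] * 4)
        assert g.data[:, 3].sum() == 4

    def test_counting_oracle_random(self, rng):
        rows = [(rng.random(50) < 0.2).astype(int) for _ in range(6)]
        g = stack_events([make_events(r) for r in rows])
        np.testing.assert_array_equal(g.data.sum(axis=0), np.sum(rows, axis=0))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            stack_events([make_events(np.zeros(10)), make_events(np.zeros(12))])


class TestRestNull:
    def test_no_events_all_zero(self):
        g = GroupEventMatrix(np.zeros((4, 20), dtype=int), ["a", "b", "c", "d"])
        assert not rest_null_fractions([g]).any()

    def test_always_on_subject_floors_fractions(self):
        data = np.zeros((5, 10), dtype=int)
        data[0] = 1
        null = rest_null_fractions([GroupEventMatrix(data, [str(i) for i in range(5)])])
        assert np.all(null >= 1 / 5)

    def test_pooled_length_bookkeeping(self):
        gs = [
            GroupEventMatrix(np.zeros((3, t), dtype=int), ["a", "b", "c"])
            for t in (10, 25, 40)
        ]
        assert rest_null_fractions(gs).shape[0] == 75

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rest_null_fractions([])


class TestSynchronyTest:
    def test_dominated_fraction_gives_p_near_one(self):
        movie = GroupEventMatrix(np.zeros((4, 10), dtype=int), list("abcd"))
        null = np.full(100, 0.5)
        fc = synchrony_test(movie, null)
        assert np.all(fc.p_values == 1.0)

    def test_exceeding_all_nulls_gives_permutation_floor(self):
        data = np.ones((4, 3), dtype=int)
        movie = GroupEventMatrix(data, list("abcd"))
        null = np.zeros(1000)
        fc = synchrony_test(movie, null)
        np.testing.assert_allclose(fc.p_values, 1 / 1001)

    def test_bh_discovery_rate_bounded_under_null(self, rng):
        # with null-distributed fractions, expected discoveries/m <= q
        discoveries = []
        for _ in range(50):
            data = (rng.random((10, 100)) < 0.03).astype(int)
            null = (rng.random((10, 400)) < 0.03).astype(int).mean(axis=0)
            fc = synchrony_test(GroupEventMatrix(data, [str(i) for i in range(10)]), null)
            discoveries.append(fc.significant.mean())
        assert np.mean(discoveries) <= 0.05 + 0.02


class TestClassifyFrames:
    @pytest.fixture
    def classified(self):
        T = 120
        fractions = np.zeros(T)
        fractions[[45, 100, 8]] = 0.8  # events at ending+5, far frame, and a weak frame
        fractions[20] = 0.3
        sig = np.zeros(T, dtype=bool)
        sig[[45, 100]] = True
        from edgesync.synchrony import FrameClassification

        fc = FrameClassification(
            fraction_with_event=fractions,
            p_values=np.where(sig, 0.001, 0.8),
            significant=sig,
            q_threshold=0.05,
        )
        ann = convolve_boundaries([40], T, 1.0)
        return classify_frames(fc, ann, (0.0, 10.0))

    def test_significant_frame_in_window_is_boundary(self, classified):
        assert classified.labels[45] == BOUNDARY

    def test_significant_frame_far_from_endings_is_movie(self, classified):
        assert classified.labels[100] == MOVIE

    def test_eventful_non_significant_frame_is_asynchronous(self, classified):
        assert classified.labels[20] == ASYNCHRONOUS

    def test_zero_event_frame_is_non_event(self, classified):
        assert classified.labels[0] == NON_EVENT
        assert np.sum(classified.labels == NON_EVENT) == 116

    def test_subject_order_invariance(self, rng):
        data = (rng.random((6, 80)) < 0.1).astype(int)
        null = (rng.random((6, 200)) < 0.05).astype(int).mean(axis=0)
        ann = convolve_boundaries([30], 80, 1.0)
        a = classify_frames(synchrony_test(GroupEventMatrix(data, list("abcdef")), null), ann)
        perm = rng.permutation(6)
        b = classify_frames(
            synchrony_test(GroupEventMatrix(data[perm], [chr(97 + i) for i in perm]), null), ann
        )
        np.testing.assert_array_equal(a.labels, b.labels)


class TestLabelSubjectEvents:
    def test_events_inherit_frame_labels(self, rng):
        data = np.zeros((3, 60), dtype=int)
        data[:, 25] = 1
        # the null must be fine-grained enough that the permutation-p floor
        # survives BH over the 60 frames
        null = np.zeros(10_000)
        fc = synchrony_test(GroupEventMatrix(data, list("abc")), null)
        ann = convolve_boundaries([20], 60, 1.0)
        fc = classify_frames(fc, ann, (0.0, 10.0))
        ev = make_events(data[0])
        assert label_subject_events(ev, fc) == [(25, BOUNDARY)]

    def test_no_events_gives_empty_list(self):
        from edgesync.synchrony import FrameClassification

        fc = FrameClassification(
            fraction_with_event=np.zeros(10),
            p_values=np.ones(10),
            significant=np.zeros(10, dtype=bool),
            q_threshold=0.05,
            labels=np.full(10, NON_EVENT, dtype=object),
        )
        assert label_subject_events(make_events(np.zeros(10)), fc) == []

    def test_unclassified_frames_rejected(self):
        from edgesync.synchrony import FrameClassification

        fc = FrameClassification(
            fraction_with_event=np.zeros(10),
            p_values=np.ones(10),
            significant=np.zeros(10, dtype=bool),
            q_threshold=0.05,
        )
        with pytest.raises(ValueError, match="classif"):
            label_subject_events(make_events(np.zeros(10)), fc)


def test_shift_null_preserves_event_counts(rng):
    data = (rng.random((5, 100)) < 0.1).astype(int)
    g = GroupEventMatrix(data, [str(i) for i in range(5)])
    null = shift_null_fractions(g, n_shifts=20, seed=0)
    assert null.shape[0] == 20 * 100
    # total event mass is conserved by circular shifting
    assert np.sum(null) * 5 == pytest.approx(20 * data.sum())
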