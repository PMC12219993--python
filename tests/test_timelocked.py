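"""Repeated-viewing alignment, synchrony, and pattern-similarity analyses."""

import numpy as np
import pytest

from edgesync.edgets import EdgeSeries, ParcelTimeSeries, edge_time_series, zscore
from edgesync.events import EventSeries
from edgesync.timelocked import (
    ViewingStack,
    align_clip,
    frame_similarity,
    peak_pattern_discrimination,
    select_peaks,
    synchrony_similarity_relation,
    viewing_counts,
    viewing_synchrony,
)


def make_events(binary, tr=1.0):
    binary = np.asarray(binary, dtype=int)
    return EventSeries(
        frames=binary, peak_frames=np.flatnonzero(binary), alpha=0.05, n_null=1, tr_seconds=tr
    )


def make_edges(data):
    n = data.shape[1]
    return edge_time_series(zscore(ParcelTimeSeries(data, 1.0)), assume_zscored=True)


class TestAlignClip:
    def test_window_extraction(self, rng):
        T, V, S = 120, 4, 3
        windows = [(10, 110), (0, 100), (20, 120), (5, 105)]
        series = [
            [make_events((rng.random(T) < 0.05).astype(int)) for _ in range(V)]
            for _ in range(S)
        ]
        stack = align_clip(series, windows)
        assert stack.events.shape == (S, V, 100)
        np.testing.assert_array_equal(stack.events[1, 0], series[1][0].frames[10:110])

    def test_unequal_windows_rejected(self, rng):
        series = [[make_events(np.zeros(50)), make_events(np.zeros(50))]]
        with pytest.raises(ValueError, match="length"):
            align_clip(series, [(0, 40), (0, 30)])

    def test_out_of_range_window_rejected(self):
        series = [[make_events(np.zeros(50)), make_events(np.zeros(50))]]
        with pytest.raises(ValueError, match="outside"):
            align_clip(series, [(0, 40), (20, 60)])


class TestViewingCounts:
    def test_counts_bounded_by_viewings(self, rng):
        ev = (rng.random((5, 4, 60)) < 0.2).astype(int)
        counts = viewing_counts(ViewingStack(events=ev))
        assert counts.max() <= 4 and counts.min() >= 0

    def test_counting_oracle(self, rng):
        ev = (rng.random((3, 4, 30)) < 0.3).astype(int)
        counts = viewing_counts(ViewingStack(events=ev))
        np.testing.assert_array_equal(counts, ev.sum(axis=1))

    def test_eventless_subject_zero_row(self, rng):
        ev = (rng.random((2, 3, 20)) < 0.5).astype(int)
        ev[0] = 0
        counts = viewing_counts(ViewingStack(events=ev))
        assert not counts[0].any()


class TestViewingSynchrony:
    def test_full_synchrony_fraction_one(self):
        ev = np.zeros((3, 4, 25), dtype=int)
        ev[:, :, 7] = 1
        fc = viewing_synchrony(ViewingStack(events=ev), np.zeros(5000))
        assert fc.fraction_with_event[7] == 1.0
        assert fc.significant[7]

    def test_fraction_identity_with_counts(self, rng):
        ev = (rng.random((4, 3, 40)) < 0.15).astype(int)
        stack = ViewingStack(events=ev)
        fc = viewing_synchrony(stack, np.linspace(0, 1, 50))
        np.testing.assert_allclose(
            fc.fraction_with_event, viewing_counts(stack).sum(axis=0) / (4 * 3)
        )

    def test_null_input_discoveries_bounded(self, rng):
        rates = []
        for _ in range(20):
            ev = (rng.random((6, 4, 80)) < 0.05).astype(int)
            null = (rng.random((24, 300)) < 0.05).astype(int).mean(axis=0)
            fc = viewing_synchrony(ViewingStack(events=ev), null)
            rates.append(fc.significant.mean())
        assert np.mean(rates) <= 0.05 + 0.02


class TestFrameSimilarity:
    def test_identical_units_similarity_one(self, rng):
        data = rng.standard_normal((30, 6))
        edges = make_edges(data)
        stack = ViewingStack(
            events=np.zeros((2, 2, 30), dtype=int),
            edges=[[edges, edges], [edges, edges]],
        )
        np.testing.assert_allclose(frame_similarity(stack), 1.0, atol=1e-10)

    def test_scale_invariance_per_frame(self, rng):
        d1, d2 = rng.standard_normal((2, 40, 5))
        e1, e2 = make_edges(d1), make_edges(d2)
        stack = ViewingStack(events=np.zeros((1, 2, 40), dtype=int), edges=[[e1, e2]])
        base = frame_similarity(stack)
        e1s = EdgeSeries(e1.data * 4.0, e1.edge_index, 1.0)
        e2s = EdgeSeries(e2.data * 4.0, e2.edge_index, 1.0)
        scaled = frame_similarity(
            ViewingStack(events=np.zeros((1, 2, 40), dtype=int), edges=[[e1s, e2s]])
        )
        np.testing.assert_allclose(base, scaled, atol=1e-10)

    def test_requires_edges(self):
        stack = ViewingStack(events=np.zeros((1, 2, 10), dtype=int))
        with pytest.raises(ValueError, match="edge"):
            frame_similarity(stack)


class TestSynchronySimilarityRelation:
    def test_identity_pairing_r_one(self, rng):
        f = rng.random(50)
        out = synchrony_similarity_relation(f, f)
        assert out["fraction_vs_similarity"][0] == pytest.approx(1.0)

    def test_shuffled_pairing_near_zero(self, rng):
        f = rng.random(500)
        s = rng.permutation(f)
        r, _ = synchrony_similarity_relation(f, s)["fraction_vs_similarity"]
        assert abs(r) < 0.15

    def test_optional_rss_channel(self, rng):
        f, s, m = rng.random((3, 40))
        out = synchrony_similarity_relation(f, s, mean_rss=m)
        assert set(out) == {"fraction_vs_similarity", "rss_vs_similarity"}


class TestPeakDiscrimination:
    def test_distinct_templates_discriminate(self, rng):
        T, N = 60, 8
        peaks = [15, 40]
        templates = {f: 4 * rng.standard_normal(N) for f in peaks}
        rows = []
        for _ in range(3):  # subjects
            views = []
            for _ in range(3):  # viewings
                data = rng.standard_normal((T, N))
                for f, tmpl in templates.items():
                    data[f] += tmpl
                views.append(make_edges(data))
            rows.append(views)
        stack = ViewingStack(events=np.zeros((3, 3, T), dtype=int), edges=rows)
        t, p, within, between = peak_pattern_discrimination(stack, peaks)
        assert within > between and p < 1e-4

    def test_single_peak_rejected(self, rng):
        stack = ViewingStack(
            events=np.zeros((1, 2, 20), dtype=int),
            edges=[[make_edges(rng.standard_normal((20, 4)))] * 2],
        )
        with pytest.raises(ValueError, match="2 peaks"):
            peak_pattern_discrimination(stack, [5])


def test_select_peaks_finds_local_maxima():
    frac = np.zeros(50)
    frac[[10, 30]] = 0.8
    frac[20] = 0.3
    sig = frac > 0.5
    peaks = select_peaks(frac, significant=sig, prominence=0.2)
    assert list(peaks) == [10, 30]
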