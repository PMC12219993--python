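"""Event-type characterization: patterns, similarity, block tests, profiles."""

import numpy as np
import pytest
from scipy.spatial.distance import squareform

from edgesync.characterize import (
    CoFluctuationPattern,
    amplitude_by_type,
    event_patterns,
    global_similarity,
    mean_pattern,
    pattern_differences,
    peak_locked_profiles,
    within_vs_between,
)
from edgesync.edgets import ParcelTimeSeries, RSSSeries, edge_time_series, zscore


def pat(vec, subject="s0", label="boundary", frame=0):
    return CoFluctuationPattern(np.asarray(vec, dtype=float), subject, frame, label)


def random_patterns(rng, subjects, types, n_events, E, template=None, noise=1.0):
    out = []
    for s in subjects:
        for t in types:
            for k in range(n_events):
                base = template[t] if template else np.zeros(E)
                out.append(pat(base + noise * rng.standard_normal(E), s, t, frame=k))
    return out


class TestEventPatterns:
    def test_rank_one_structure(self, rng):
        ts = zscore(ParcelTimeSeries(rng.standard_normal((40, 6)), 1.0))
        edges = edge_time_series(ts, assume_zscored=True)
        [p] = event_patterns(edges, [(17, "movie")], subject="s1")
        z = ts.data[17]
        expected = np.outer(z, z)
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(p.matrix(), expected, atol=1e-12)

    def test_vectorize_matricize_round_trip(self, rng):
        vec = rng.standard_normal(15)
        p = pat(vec)
        np.testing.assert_allclose(squareform(p.matrix(), checks=False), vec)

    def test_no_events_empty(self, rng):
        ts = zscore(ParcelTimeSeries(rng.standard_normal((10, 4)), 1.0))
        edges = edge_time_series(ts, assume_zscored=True)
        assert event_patterns(edges, []) == []


class TestAmplitudeByType:
    def test_planted_difference_detected(self, rng):
        trace = np.concatenate([np.full(30, 10.0), np.full(30, 5.0)]) + 0.1 * rng.standard_normal(60)
        amp = RSSSeries(trace, 1.0)
        events = [(t, "boundary") for t in range(0, 30, 2)] + [(t, "movie") for t in range(30, 60, 2)]
        values, tests = amplitude_by_type(amp, events)
        t, p = tests[("boundary", "movie")]
        assert p < 1e-6 and t > 0
        assert values["boundary"].mean() > values["movie"].mean()

    def test_singleton_type_skipped_with_warning(self, rng):
        amp = RSSSeries(rng.random(20) + 1, 1.0)
        events = [(1, "boundary"), (3, "movie"), (5, "movie"), (7, "movie")]
        with pytest.warns(UserWarning, match="fewer than 2"):
            _, tests = amplitude_by_type(amp, events)
        assert ("boundary", "movie") not in tests


class TestGlobalSimilarity:
    def test_headline_dimension_129_subjects(self, rng):
        subjects = [f"s{i}" for i in range(129)]
        patterns = random_patterns(rng, subjects, ["boundary"], 1, E=10)
        sim = global_similarity(patterns, subjects=subjects)
        assert sim.matrix.shape == (387, 387)

    def test_identical_patterns_give_unit_similarity(self, rng):
        v = rng.standard_normal(20)
        patterns = [pat(v, s, t, k) for s in ("a", "b") for t in ("boundary", "movie") for k in range(2)]
        sim = global_similarity(patterns)
        finite = sim.matrix[np.isfinite(sim.matrix)]
        np.testing.assert_allclose(finite, 1.0, atol=1e-10)

    def test_planted_templates_make_within_type_blocks_larger(self, rng):
        template = {t: 3 * rng.standard_normal(60) for t in ("boundary", "movie", "asynchronous")}
        patterns = random_patterns(
            rng, [f"s{i}" for i in range(6)], list(template), 3, 60, template
        )
        sim = global_similarity(patterns)
        t_stat, p, within, between = within_vs_between(sim, "boundary")
        assert within > between and p < 1e-6

    def test_pearson_invariant_to_affine_rescaling(self, rng):
        patterns = random_patterns(rng, ["a", "b", "c"], ["boundary", "movie"], 2, 30)
        scaled = [
            CoFluctuationPattern(2.5 * p.vector + 7.0, p.subject, p.frame, p.label)
            for p in patterns
        ]
        a = global_similarity(patterns).matrix
        b = global_similarity(scaled).matrix
        np.testing.assert_allclose(a, b, atol=1e-10)

    @pytest.mark.parametrize("metric", ["spearman", "nmi"])
    def test_alternative_metrics_run_and_detect_structure(self, rng, metric):
        template = {t: 3 * rng.standard_normal(40) for t in ("boundary", "movie", "asynchronous")}
        patterns = random_patterns(rng, ["a", "b", "c", "d"], list(template), 2, 40, template)
        sim = global_similarity(patterns, metric=metric)
        _, p, within, between = within_vs_between(sim, "boundary")
        assert within > between

    def test_single_subject_rejected(self, rng):
        patterns = random_patterns(rng, ["only"], ["boundary", "movie", "asynchronous"], 2, 10)
        sim = global_similarity(patterns)
        with pytest.raises(ValueError):
            within_vs_between(sim, "boundary")


class TestMeanPattern:
    def test_mean_of_single_pattern_is_itself(self, rng):
        v = rng.standard_normal(15)
        res = mean_pattern([pat(v)], ["a"] * 3 + ["b"] * 3, n_perm=50, seed=0)
        np.testing.assert_allclose(res.mean_vector, v)

    def test_pattern_plus_negation_cancels(self, rng):
        v = rng.standard_normal(15)
        neg = CoFluctuationPattern(-v, "s0", 1, "boundary")
        res = mean_pattern([pat(v), neg], ["a"] * 3 + ["b"] * 3, n_perm=50, seed=0)
        np.testing.assert_allclose(res.mean_vector, 0.0, atol=1e-12)

    def test_planted_cross_block_is_top_significant(self, rng):
        # nodes 0-9 system A, 10-19 system B, 20-29 system C; plant A-B edges
        labels = ["A"] * 10 + ["B"] * 10 + ["C"] * 10
        M = 0.05 * rng.standard_normal((30, 30))
        M = (M + M.T) / 2
        M[:10, 10:20] += 2.0
        M[10:20, :10] += 2.0
        np.fill_diagonal(M, 0.0)
        vec = squareform(M, checks=False)
        res = mean_pattern([pat(vec)], labels, n_perm=500, seed=1)
        assert res.top_block(between_only=True) == ("A", "B")
        ia, ib = res.systems.index("A"), res.systems.index("B")
        assert res.block_q_sig[ia, ib]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_pattern([], ["a"], n_perm=10)


class TestPeakLockedProfiles:
    def test_single_event_profile_is_raw_slice(self, rng):
        trace = rng.random(100) + 1
        amp = {"scan": RSSSeries(trace, 1.0)}
        res = peak_locked_profiles(amp, [("scan", 50, "movie")], half_window=10)
        np.testing.assert_allclose(res.profiles["movie"], trace[40:61])
        assert len(res.offsets) == 21  # ten frames each side of the peak

    def test_edge_events_masked_not_dropped(self, rng):
        trace = rng.random(30) + 1
        amp = {"scan": RSSSeries(trace, 1.0)}
        res = peak_locked_profiles(amp, [("scan", 3, "boundary")], half_window=10)
        assert np.isnan(res.profiles["boundary"][:7]).all()
        np.testing.assert_allclose(res.profiles["boundary"][7:], trace[0:14])

    def test_alignment_invariant_to_global_event_shift(self, rng):
        trace = rng.random(200) + 1
        amp = {"s": RSSSeries(trace, 1.0)}
        rolled = {"s": RSSSeries(np.roll(trace, 5), 1.0)}
        ev = [("s", f, "movie") for f in (60, 90, 120)]
        ev_shift = [("s", f + 5, "movie") for f in (60, 90, 120)]
        a = peak_locked_profiles(amp, ev, 10).profiles["movie"]
        b = peak_locked_profiles(rolled, ev_shift, 10).profiles["movie"]
        np.testing.assert_allclose(a, b)

    def test_wider_planted_bursts_exceed_off_peak(self, rng):
        T = 300
        base = np.ones(T)
        wide, narrow = base.copy(), base.copy()
        for f in (50, 150, 250):
            wide[f - 3 : f + 4] += 4.0  # broad elevation
            narrow[f] += 4.0
        amp = {"w": RSSSeries(wide + 0.01 * rng.random(T), 1.0),
               "n": RSSSeries(narrow + 0.01 * rng.random(T), 1.0)}
        events = [("w", f, "boundary") for f in (50, 150, 250)] + [
            ("n", f, "movie") for f in (50, 150, 250)
        ]
        res = peak_locked_profiles(amp, events, half_window=10)
        off = np.abs(res.offsets) == 2
        assert np.all(res.profiles["boundary"][off] > res.profiles["movie"][off])


class TestPatternDifferences:
    def test_uniform_shift_found_on_every_subject(self, rng):
        E = 45
        patterns = []
        for s in range(6):
            base = rng.standard_normal(E)
            for k in range(3):
                a = base + 0.1 * rng.standard_normal(E)
                b = base + 0.1 * rng.standard_normal(E)
                a[7] += 1.0  # one edge systematically larger under type A
                patterns.append(pat(a, f"s{s}", "boundary", k))
                patterns.append(pat(b, f"s{s}", "movie", k))
        res = pattern_differences(patterns, ("boundary", "movie"))
        assert res.q_sig[7]
        assert np.all(res.signs[:, 7] == 1)
        assert res.sign_consensus[7] == 1.0

    def test_null_discovery_rate_bounded(self, rng):
        rates = []
        for _ in range(10):
            patterns = random_patterns(rng, [f"s{i}" for i in range(8)], ["boundary", "movie"], 3, 40)
            res = pattern_differences(patterns, ("boundary", "movie"))
            rates.append(res.q_sig.mean())
        assert np.mean(rates) <= 0.05 + 0.03

    def test_single_subject_rejected(self, rng):
        patterns = random_patterns(rng, ["s0"], ["boundary", "movie"], 2, 10)
        with pytest.raises(ValueError, match="2 subjects"):
            pattern_differences(patterns, ("boundary", "movie"))

    def test_incomplete_subject_excluded_with_warning(self, rng):
        patterns = random_patterns(rng, ["s0", "s1", "s2"], ["boundary", "movie"], 2, 10)
        patterns.append(pat(rng.standard_normal(10), "s3", "boundary"))
        with pytest.warns(UserWarning, match="s3"):
            res = pattern_differences(patterns, ("boundary", "movie"))
        assert res.subjects == ["s0", "s1", "s2"]
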