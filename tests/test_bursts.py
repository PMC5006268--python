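import math

import numpy as np
import pytest

from maturesim import (
    BurstConfig,
    FixtureSpec,
    analyze_unit,
    burst_threshold,
    cma_curve,
    detect_bursts,
    extract_features,
    generate_bursty_fixture,
    isi_histogram,
)


def oracle_threshold(isis, bin_width):
    """Plain-python recomputation of the threshold rule, independent of
    the implementation under test."""
    idx = [max(math.ceil(x / bin_width - 1e-9), 1) - 1 for x in isis]
    n_bins = max(idx) + 1
    counts = [0] * n_bins
    for k in idx:
        counts[k] += 1
    occupied = [k for k, c in enumerate(counts) if c]
    if len(occupied) == 1:
        return (occupied[0] + 1) * bin_width
    cma = []
    running = 0
    for k, c in enumerate(counts):
        running += c
        cma.append(running / (k + 1))
    n = len(isis)
    mu = sum(isis) / n
    m2 = sum((x - mu) ** 2 for x in isis) / n
    m3 = sum((x - mu) ** 3 for x in isis) / n
    alpha = m3 / m2**1.5 if m2 > 0 else 0.0
    target = alpha * sum(cma) / len(cma)
    best = min(range(n_bins), key=lambda k: (abs(cma[k] - target), k))
    return (best + 1) * bin_width


def times_from_isis(isis):
    return np.concatenate([[0.0], np.cumsum(isis)])


class TestISIHistogram:
    def test_two_equal_isis_occupy_one_bin(self):
        hist = isi_histogram([0.0, 0.01, 0.02], 0.005)
        assert hist.n_isis == 2
        occupied = np.nonzero(hist.counts)[0]
        assert len(occupied) == 1
        assert hist.counts[occupied[0]] == 2
        assert hist.right_edges[occupied[0]] == pytest.approx(0.01)

    def test_single_spike_yields_empty_sentinel(self):
        assert isi_histogram([1.0], 0.005).empty

    def test_counts_are_conserved(self, rng):
        isis = rng.exponential(0.1, size=1000)
        hist = isi_histogram(times_from_isis(isis), 0.005)
        assert hist.counts.sum() == 1000

    def test_invalid_bin_width_rejected(self):
        with pytest.raises(ValueError):
            isi_histogram([0.0, 1.0], 0.0)


class TestCMACurve:
    def test_arithmetic_example(self):
        hist = isi_histogram([0.0], 0.005)
        hist.counts = np.array([4, 2, 2])
        hist.right_edges = 0.005 * np.arange(1, 4)
        hist.n_isis = 8
        assert np.allclose(cma_curve(hist), [4.0, 3.0, 8.0 / 3.0])

    def test_constant_counts_give_constant_cma(self):
        hist = isi_histogram([0.0], 0.005)
        hist.counts = np.full(10, 3)
        hist.n_isis = 30
        assert np.allclose(cma_curve(hist), 3.0)

    def test_cma_bounded_by_counts_seen_so_far(self, rng):
        isis = rng.exponential(0.05, size=500)
        hist = isi_histogram(times_from_isis(isis), 0.005)
        cma = cma_curve(hist)
        run_min = np.minimum.accumulate(hist.counts)
        run_max = np.maximum.accumulate(hist.counts)
        assert np.all(cma >= run_min - 1e-12)
        assert np.all(cma <= run_max + 1e-12)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            cma_curve(isi_histogram([0.0], 0.005))


class TestBurstThreshold:
    def test_single_occupied_bin_returns_that_isi(self):
        hist = isi_histogram([0.0, 0.01, 0.02, 0.03], 0.005)
        assert burst_threshold(hist) == pytest.approx(0.01)

    def test_bimodal_matches_independent_oracle(self):
        isis = [0.01] * 300 + [1.0] * 100
        t = times_from_isis(isis)
        hist = isi_histogram(t, 0.005)
        thr = burst_threshold(hist, isis=np.diff(t))
        assert thr == pytest.approx(oracle_threshold(isis, 0.005))
        assert 0.01 < thr < 1.0

    def test_matches_oracle_on_random_samples(self, rng):
        for _ in range(100):
            n = rng.integers(5, 200)
            isis = rng.exponential(rng.uniform(0.01, 1.0), size=n) + 1e-4
            t = times_from_isis(isis)
            hist = isi_histogram(t, 0.005)
            thr = burst_threshold(hist, isis=np.diff(t))
            assert thr == pytest.approx(
                oracle_threshold(list(np.diff(t)), 0.005), rel=1e-9
            )

    def test_scale_equivariance(self, rng):
        isis = rng.exponential(0.1, size=300) + 1e-3
        t = times_from_isis(isis)
        thr = burst_threshold(
            isi_histogram(t, 0.005), isis=np.diff(t),
            config=BurstConfig(bin_width_s=0.005),
        )
        thr2 = burst_threshold(
            isi_histogram(2.0 * t, 0.01), isis=np.diff(2.0 * t),
            config=BurstConfig(bin_width_s=0.01),
        )
        assert thr2 == pytest.approx(2.0 * thr)

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            burst_threshold(isi_histogram([0.5], 0.005))


class TestDetectBursts:
    def test_single_run_of_four(self):
        bursts = detect_bursts([0.0, 0.01, 0.02, 0.03], 0.05)
        assert len(bursts) == 1
        assert bursts[0].n_spikes == 4
        assert bursts[0].duration_s == pytest.approx(0.03)

    def test_runs_of_two_are_not_bursts(self):
        assert detect_bursts([0.0, 0.01, 1.0, 1.01], 0.05) == []

    def test_two_bursts_split_by_long_gap(self):
        t = [0.0, 0.01, 0.02, 1.0, 1.01, 1.02, 1.03]
        bursts = detect_bursts(t, 0.05)
        assert [b.n_spikes for b in bursts] == [3, 4]

    def test_boundary_isi_is_inclusive(self):
        assert len(detect_bursts([0.0, 0.05, 0.1], 0.05)) == 1

    def test_reported_bursts_satisfy_definition(self, rng):
        for _ in range(50):
            t = np.sort(rng.uniform(0, 10, size=rng.integers(3, 100)))
            t = np.unique(t)
            thr = rng.uniform(0.01, 1.0)
            isis = np.diff(t)
            for b in detect_bursts(t, thr):
                first = int(np.searchsorted(t, b.start_s))
                last = int(np.searchsorted(t, b.end_s))
                assert b.n_spikes == last - first + 1 >= 3
                assert np.all(isis[first:last] <= thr)
                if first > 0:
                    assert isis[first - 1] > thr
                if last < len(t) - 1:
                    assert isis[last] > thr


class TestExtractFeatures:
    def test_spike_rate_per_minute(self):
        fv = extract_features(np.arange(30), [], 300.0)
        assert fv.spike_rate == pytest.approx(6.0)

    def test_burst_rate_per_minute(self):
        t = [0.0, 0.01, 0.02]
        bursts = detect_bursts(t, 0.05)
        fv = extract_features(t, bursts * 3, 300.0)
        assert fv.burst_rate == pytest.approx(0.6)

    def test_mean_spikes_per_burst(self):
        t = np.array(
            [0.0, 0.01, 0.02, 1.0, 1.01, 1.02, 1.03, 2.0, 2.01, 2.02, 2.03,
             2.04]
        )
        fv = extract_features(t, detect_bursts(t, 0.05), 10.0)
        assert fv.spikes_per_burst == pytest.approx(4.0)

    def test_no_bursts_flags_absent_features(self):
        fv = extract_features([0.0, 5.0], [], 10.0)
        assert fv.burst_rate == 0.0
        assert math.isnan(fv.burst_duration_s)
        assert math.isnan(fv.spikes_per_burst)


class TestPipeline:
    def test_sparse_unit_skips_burst_analysis(self):
        fv, bursts = analyze_unit([0.0, 0.1, 0.2], 300.0)
        assert bursts == []
        assert fv.spike_rate == pytest.approx(0.6)

    def test_planted_burst_recovery(self):
        spec = FixtureSpec(
            n_units=5, n_bursts=25, spikes_per_burst=6,
            intra_burst_isi_s=0.01, min_gap_s=1.0, duration_s=60.0, seed=4,
        )
        trains, truth = generate_bursty_fixture(spec)
        recovered_total = 0
        planted_total = 0
        for u in range(spec.n_units):
            _, bursts = analyze_unit(trains.trains[u], trains.duration_s)
            planted = truth[u]
            planted_total += len(planted)
            for p in planted:
                hit = any(
                    b.start_s <= p.start_s and b.end_s >= p.end_s
                    and b.end_s - b.start_s < p.duration_s + 1.0
                    for b in bursts
                )
                recovered_total += hit
            # no detected burst may span an inter-burst gap
            for b in bursts:
                inside = [
                    p for p in planted
                    if b.start_s >= p.start_s - 0.5
                    and b.end_s <= p.end_s + 0.5
                ]
                assert inside, f"burst {b} spans a planted gap"
        assert recovered_total / planted_total >= 0.9
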