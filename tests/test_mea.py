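"""MEA pipeline: filters, spike detection, bursts, synchrony, complexity,
lag times, firing-rate metrics and spike sorting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from optoneuro import mea, synthetic
from optoneuro.types import SpikeTrainSet

from oracles import brute_bursts, brute_lz76, brute_network_bursts, brute_sttc

FS = 20_000.0


def _tone(freq, fs=FS, dur=1.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestFilters:
    def test_bandpass_removes_dc(self):
        x = np.full(int(FS), 50.0)
        y = mea.bandpass_filter(x, FS)
        assert np.abs(y).max() < 1e-6 * 50

    def test_inband_gain_via_fft(self):
        x = _tone(1000.0)
        y = mea.bandpass_filter(x, FS)
        gain = np.abs(np.fft.rfft(y))[1000] / np.abs(np.fft.rfft(x))[1000]
        assert abs(gain - 1) < 0.05

    def test_mains_attenuated(self):
        x = _tone(50.0)
        y = mea.bandpass_filter(x, FS)
        att = 20 * np.log10(np.abs(np.fft.rfft(x))[50] / np.abs(np.fft.rfft(y))[50])
        assert att >= 20

    def test_nyquist_error(self):
        with pytest.raises(ValueError):
            mea.bandpass_filter(np.zeros(100), 1000.0, lo=200, hi=600)

    def test_lfp_passband_and_stopband(self):
        lo = mea.extract_lfp(_tone(10.0), FS)
        hi = mea.extract_lfp(_tone(5000.0), FS)
        assert abs(lo.std() * np.sqrt(2) - 1) < 0.02  # 10 Hz preserved
        assert hi.std() * np.sqrt(2) < 0.05  # 5 kHz rejected

    def test_lfp_output_rate(self):
        out = mea.extract_lfp(np.zeros(int(2.5 * FS)), FS)
        assert out.shape[-1] == 2500
        with pytest.raises(ValueError):
            mea.extract_lfp(np.zeros(100), 1500.0)


class TestSpikeDetection:
    def test_false_positive_rate_on_noise(self):
        """5.5-SD threshold on pure Gaussian noise: <= 0.2 Hz false events."""
        rng = np.random.default_rng(1)
        rates = []
        for _ in range(8):
            noise = mea.bandpass_filter(rng.normal(0, 5, int(30 * FS)), FS)
            rates.append(mea.detect_spikes_adaptive(noise, FS).size / 30)
        assert np.mean(rates) <= 0.2

    def test_recall_precision_on_ground_truth(self):
        """Amplitude 10x noise SD: recall and precision >= 0.98 at 0.5 ms."""
        stim = synthetic.make_stim_schedule(1.0, 0.01, 10.0, 25.0)
        rec, gt = synthetic.simulate_mea_recording(
            n_electrodes=4, fs=FS, duration=30.0, baseline_rate=3.0,
            evoked_multiplier=2.0, stim=stim, waveform=(50.0, 1.0),
            noise_sd=5.0, seed=2,
        )
        trains = mea.detect_spike_trains(rec)
        tp = fp = fn = 0
        for eid in trains.trains:
            det = list(trains.trains[eid])
            for t in gt.trains.trains[eid]:
                cand = [d for d in det if abs(d - t) <= 5e-4]
                if cand:
                    tp += 1
                    det.remove(min(cand, key=lambda d: abs(d - t)))
                else:
                    fn += 1
            fp += len(det)
        assert tp / (tp + fn) >= 0.98
        assert tp / (tp + fp) >= 0.98

    def test_refractory_one_detection_for_close_pair(self):
        fs = FS
        trace = np.zeros(int(0.1 * fs))
        tpl = synthetic.biphasic_template(fs, 50.0, 1.0)
        for t0 in (0.030, 0.031):  # 1 ms apart
            i = int(t0 * fs)
            trace[i : i + tpl.size] += tpl
        times = mea.detect_spikes_adaptive(
            trace + 1e-3 * np.sin(np.arange(trace.size)), fs, noise_window=0.1
        )
        assert times.size == 1

    def test_refractory_never_violated(self):
        rng = np.random.default_rng(3)
        stim = synthetic.make_stim_schedule(2.0, 0.01, 1.0, 9.0)
        rec, _ = synthetic.simulate_mea_recording(
            n_electrodes=2, fs=FS, duration=10.0, baseline_rate=20.0,
            evoked_multiplier=3.0, stim=stim, seed=4,
        )
        trains = mea.detect_spike_trains(rec)
        for t in trains.trains.values():
            if t.size > 1:
                assert np.diff(t).min() >= mea.DEFAULT_REFRACTORY - 1e-9


class TestActiveElectrodes:
    @pytest.mark.parametrize(
        "n_spikes,duration,active",
        [(4, 60.0, False), (5, 60.0, True), (9, 120.0, False)],
    )
    def test_rate_boundaries(self, n_spikes, duration, active):
        trains = SpikeTrainSet(
            {"E0": np.linspace(0.1, duration - 0.1, n_spikes)}, duration
        )
        assert ("E0" in mea.active_electrodes(trains)) is active


class TestBursts:
    def test_five_spike_burst(self):
        bursts = mea.detect_bursts(np.array([0, 0.01, 0.02, 0.03, 0.04]))
        assert len(bursts) == 1
        b = bursts[0]
        assert (b.start, b.end, b.n_spikes) == (0.0, 0.04, 5)

    def test_four_spikes_no_burst(self):
        assert mea.detect_bursts(np.array([0, 0.01, 0.02, 0.03])) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n = rng.integers(0, 50)
            t = np.sort(rng.uniform(0, 2.0, n))
            ours = mea.detect_bursts(t)
            brute = brute_bursts(t, 0.100, 5)
            assert [(b.start, b.end, b.n_spikes) for b in ours] == pytest.approx(brute)


class TestNetworkBursts:
    def _set(self, trains, duration=10.0):
        return SpikeTrainSet(trains, duration)

    def test_quarter_participation(self):
        trains = {f"E{i:02d}": np.array([]) for i in range(16)}
        for i in range(4):
            trains[f"E{i:02d}"] = np.array([1.0 + 0.004 * (3 * i + j) for j in range(3)])
        nb = mea.detect_network_bursts(self._set(trains))
        assert len(nb) == 1
        assert nb[0].n_spikes == 12
        assert len(nb[0].electrodes) == 4

    def test_insufficient_participation(self):
        trains = {f"E{i:02d}": np.array([]) for i in range(16)}
        for i in range(2):
            trains[f"E{i:02d}"] = np.array([1.0 + 0.004 * (6 * i + j) for j in range(6)])
        assert mea.detect_network_bursts(self._set(trains)) == []

    def test_matches_brute_force(self):
        rng = np.random.default_rng(6)
        for _ in range(500):
            n_e = int(rng.integers(2, 6))
            trains = {
                f"E{i}": np.sort(rng.uniform(0, 1.0, rng.integers(0, 15)))
                for i in range(n_e)
            }
            ours = mea.detect_network_bursts(SpikeTrainSet(trains, 1.0))
            brute = brute_network_bursts(
                {e: list(t) for e, t in trains.items()}, 0.100, 10, 0.25
            )
            assert len(ours) == len(brute)
            for o, b in zip(ours, brute):
                assert (o.start, o.end, o.n_spikes) == pytest.approx(b[:3])
                assert o.electrodes == b[3]


class TestSTTC:
    def test_identical_trains(self):
        t = np.array([0.5, 1.2, 3.3, 7.0])
        assert mea.sttc(t, t, 0.02, 10.0) == pytest.approx(1.0)

    def test_hand_evaluated_case(self):
        # a={1,5}, b={1.01,9}, T=10, dt=0.05:
        # P_A=P_B=0.5, T_A=T_B=0.02 -> 0.5*2*(0.48/0.99) = 0.48484848...
        val = mea.sttc([1.0, 5.0], [1.01, 9.0], dt=0.05, T=10.0)
        assert val == pytest.approx(0.48 / 0.99)

    def test_empty_train_nan(self):
        assert np.isnan(mea.sttc([], [1.0], 0.02, 10.0))

    def test_poisson_null_near_zero(self):
        rng = np.random.default_rng(7)
        vals = []
        for _ in range(60):
            a = np.sort(rng.uniform(0, 600, rng.poisson(600)))
            b = np.sort(rng.uniform(0, 600, rng.poisson(600)))
            vals.append(mea.sttc(a, b, 0.02, 600.0))
        assert abs(np.mean(vals)) <= 0.02

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.lists(st.floats(0.1, 9.9), min_size=1, max_size=12),
        b=st.lists(st.floats(0.1, 9.9), min_size=1, max_size=12),
        dt=st.floats(0.01, 0.5),
        shift=st.floats(0, 3.0),
    )
    def test_matches_brute_force_and_symmetry(self, a, b, dt, shift):
        ours = mea.sttc(a, b, dt, T=14.0)
        brute = brute_sttc(a, b, dt, T=14.0)
        if np.isnan(ours):
            assert np.isnan(brute)
        else:
            assert ours == pytest.approx(brute, abs=1e-12)
            assert mea.sttc(b, a, dt, T=14.0) == pytest.approx(ours)

    def test_shift_invariance_interior(self):
        rng = np.random.default_rng(8)
        a = np.sort(rng.uniform(1, 5, 20))
        b = np.sort(rng.uniform(1, 5, 25))
        base = mea.sttc(a, b, 0.05, 10.0)
        shifted = mea.sttc(a + 2.0, b + 2.0, 0.05, 10.0)
        assert shifted == pytest.approx(base, abs=1e-12)


class TestSynchronyIndex:
    def test_identical_trains_maximal(self):
        t = np.sort(np.random.default_rng(9).uniform(0, 60, 60))
        trains = SpikeTrainSet({"a": t, "b": t.copy()}, 60.0)
        df, agg = mea.synchrony_index(trains)
        # all coincident pairs land at lag 0: raw mass far above the 0.02 null
        assert df["raw"].iloc[0] > 10 * 0.02
        assert df["normalized"].iloc[0] > 10
        assert agg == pytest.approx(df["raw"].mean())

    def test_poisson_null_matches_window_fraction(self):
        """Independent trains: raw index ~ window/support = 0.02."""
        rng = np.random.default_rng(10)
        vals = []
        for _ in range(40):
            a = np.sort(rng.uniform(0, 300, rng.poisson(300)))
            b = np.sort(rng.uniform(0, 300, rng.poisson(300)))
            df, _ = mea.synchrony_index(SpikeTrainSet({"a": a, "b": b}, 300.0))
            vals.append(df["raw"].iloc[0])
        assert np.mean(vals) == pytest.approx(0.02, abs=0.005)

    def test_jitter_monotonicity(self):
        rng = np.random.default_rng(11)
        wins = 0
        n = 30
        for _ in range(n):
            t = np.sort(rng.uniform(0, 120, 150))
            tight = np.sort(t + rng.normal(0, 0.005, t.size))
            loose = np.sort(t + rng.normal(0, 0.050, t.size))
            d1, _ = mea.synchrony_index(SpikeTrainSet({"a": t, "b": tight}, 121.0))
            d2, _ = mea.synchrony_index(SpikeTrainSet({"a": t, "b": loose}, 121.0))
            wins += d1["raw"].iloc[0] > d2["raw"].iloc[0]
        assert wins / n >= 0.95


class TestBinarize:
    def test_empty_and_full(self):
        assert not mea.binarize_train([], 0.1, 0.05).any()
        assert mea.binarize_train([0.001, 0.0501], 0.1, 0.05).tolist() == [1, 1]

    def test_length(self):
        assert mea.binarize_train([], 1.0, 0.001).size == 1000


class TestLZC:
    def test_constant_string(self):
        res = mea.lempel_ziv_complexity(np.zeros(10, dtype=int))
        assert res.c_n == brute_lz76("0" * 10) == 2
        assert res.lzc == pytest.approx(2 / 10 * np.log2(10))

    def test_canonical_string(self):
        s = "0001101001000101"
        res = mea.lempel_ziv_complexity(np.array([int(c) for c in s]))
        assert res.c_n == brute_lz76(s)

    @settings(deadline=None, max_examples=300, derandomize=True)
    @given(bits=st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_matches_brute_force(self, bits):
        res = mea.lempel_ziv_complexity(np.array(bits))
        assert res.c_n == brute_lz76("".join(map(str, bits)))
        n = len(bits)
        assert res.lzc == pytest.approx(res.c_n / n * np.log2(n) if n > 1 else res.c_n)

    def test_random_exceeds_periodic(self):
        rng = np.random.default_rng(12)
        periodic = np.tile([0, 1], 100)
        c_per = mea.lempel_ziv_complexity(periodic).c_n
        c_rand = [
            mea.lempel_ziv_complexity(rng.integers(0, 2, 200)).c_n
            for _ in range(50)
        ]
        assert np.mean(c_rand) > c_per

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            mea.lempel_ziv_complexity(np.array([0, 1, 2]))


class TestLagTimes:
    def test_basic_formula(self):
        lags = mea.lag_times([10.135], [10.0])
        assert lags[0] == pytest.approx(0.135)

    def test_missing_and_window(self):
        lags = mea.lag_times([2.5], [0.0, 1.0])
        assert np.isnan(lags[0]) and lags[1] == pytest.approx(1.5)

    def test_peaks_before_first_stim_ignored(self):
        lags = mea.lag_times([0.5, 1.2], [1.0])
        assert lags[0] == pytest.approx(0.2)


class TestMFR:
    def test_fold_change_arithmetic(self):
        trains = SpikeTrainSet(
            {"a": np.concatenate([np.linspace(0.1, 9.9, 10), np.linspace(10.1, 19.9, 80)])},
            20.0,
        )
        df = mea.mfr_metrics(trains, {"before": (0, 10), "during": (10, 20)})
        assert df.loc["a", "fold_change"] == pytest.approx(8.0)

    def test_equal_rates_fold_one(self):
        trains = SpikeTrainSet({"a": np.arange(0.5, 20.0, 1.0)}, 20.0)
        df = mea.mfr_metrics(trains, {"before": (0, 10), "during": (10, 20)})
        assert df.loc["a", "fold_change"] == pytest.approx(1.0)

    def test_zero_before_rate_nan(self):
        trains = SpikeTrainSet({"a": np.array([15.0, 16.0])}, 20.0)
        df = mea.mfr_metrics(trains, {"before": (0, 10), "during": (10, 20)})
        assert np.isnan(df.loc["a", "fold_change"])

    def test_multiplier_recovery_at_600s(self):
        """Median during/before fold ~ evoked_multiplier (+-20%)."""
        stim = synthetic.make_stim_schedule(1.0, 0.010, 200.0, 400.0)
        gt = synthetic.simulate_mea_spike_trains(
            n_electrodes=16, duration=600.0, baseline_rate=1.0,
            evoked_multiplier=3.0, stim=stim, seed=13,
        )
        df = mea.mfr_metrics(
            gt.trains, {"before": (0, 200), "during": (200, 400), "after": (400, 600)}
        )
        med = df["fold_change"].median()
        assert 3.0 * 0.8 <= med / 0.88 <= 3.0 * 1.2  # 0.88 = elevated duty fraction

    def test_zero_width_window(self):
        trains = SpikeTrainSet({"a": np.array([1.0])}, 10.0)
        with pytest.raises(ValueError):
            mea.mfr_metrics(trains, {"before": (0, 0), "during": (0, 5)})


class TestSortSpikes:
    def _families(self, seed=0, n=200, sep=10.0):
        rng = np.random.default_rng(seed)
        base = synthetic.biphasic_template(FS, 50.0, 1.0)
        w1 = np.tile(base, (n, 1))
        w2 = np.tile(np.roll(base, 3) * 0.6, (n, 1))
        noise = rng.normal(0, np.abs(base).max() / sep, (2 * n, base.size))
        X = np.vstack([w1, w2]) + noise
        y = np.repeat([0, 1], n)
        return X, y

    def test_identical_waveforms_one_unit(self):
        X = np.tile(synthetic.biphasic_template(FS, 50.0, 1.0), (40, 1))
        res = mea.sort_spikes(X)
        assert res.n_units == 1

    def test_two_families_recovered(self):
        X, y = self._families()
        res = mea.sort_spikes(X, seed=1)
        assert res.n_units == 2
        # label agreement up to permutation
        agree = max(
            np.mean(res.labels == y), np.mean(res.labels == 1 - y)
        )
        assert agree >= 0.98

    def test_determinism(self):
        X, _ = self._families(seed=3)
        r1 = mea.sort_spikes(X, seed=5)
        r2 = mea.sort_spikes(X, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_few_spikes_warns(self):
        X = np.random.default_rng(4).normal(size=(12, 20))
        with pytest.warns(UserWarning, match="max_k"):
            mea.sort_spikes(X, max_k=10)
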