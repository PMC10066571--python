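"""Filtering, EOG regression, referencing, spline, epoching, rejection."""

import numpy as np
import pytest

from auderp import (autoreject_like, bandpass, epoch_and_baseline, make_eog,
                    notch, remove_blinks, rereference_average,
                    spline_interpolate, spline_interpolate_array)
from auderp.containers import EpochSet, EventSchedule, Recording
from auderp.preprocess import EOG_NAME
from auderp.simulate import blink_template, blink_topography


def _recording(layout, data, srate=500.0, events=None, non_scalp=()):
    events = events or EventSchedule(np.empty(0), [], np.empty(0, int))
    return Recording(data, srate, layout, events, list(non_scalp))


def _sine(freq, srate, n, amp=1.0):
    return amp * np.sin(2 * np.pi * freq * np.arange(n) / srate)


class TestFilters:
    def test_bandpass_passband_and_stopband(self, layout8):
        n = 10 * 500
        data = np.tile(_sine(10.0, 500, n), (8, 1))
        rec = bandpass(_recording(layout8, data))
        mid = slice(n // 4, 3 * n // 4)
        assert np.ptp(rec.data[0, mid]) == pytest.approx(2.0, rel=0.01)

        data40 = np.tile(_sine(40.0, 500, n), (8, 1))
        rec40 = bandpass(_recording(layout8, data40))
        atten = np.ptp(rec40.data[0, mid]) / 2.0
        assert atten < 10 ** (-20 / 20)  # >= 20 dB down

    def test_zero_phase_impulse_symmetric(self, layout8):
        n = 30001  # the 0.5 Hz edge has seconds-long tails
        data = np.zeros((8, n))
        data[:, n // 2] = 1.0
        rec = bandpass(_recording(layout8, data))
        h = rec.data[0]
        assert np.allclose(h, h[::-1], atol=1e-9)  # symmetric about the impulse
        # cross-correlation peak lag of filtered vs input template = 0
        lag = np.argmax(np.correlate(h, data[0], mode="full")) - (n - 1)
        assert lag == 0

    def test_filter_linearity(self, layout8, rng):
        x = rng.standard_normal((8, 2000))
        y = rng.standard_normal((8, 2000))
        fx = bandpass(_recording(layout8, x)).data
        fy = bandpass(_recording(layout8, y)).data
        fxy = bandpass(_recording(layout8, 2.0 * x - 3.0 * y)).data
        assert np.allclose(fxy, 2.0 * fx - 3.0 * fy, atol=1e-9)

    def test_notch_kills_50hz_only(self, layout8):
        n = 10 * 500
        mid = slice(n // 4, 3 * n // 4)
        r50 = notch(_recording(layout8, np.tile(_sine(50.0, 500, n, 10.0), (8, 1))))
        assert np.max(np.abs(r50.data[0, mid])) <= 0.32
        r10 = notch(_recording(layout8, np.tile(_sine(10.0, 500, n), (8, 1))))
        assert np.ptp(r10.data[0, mid]) == pytest.approx(2.0, rel=0.01)
        rdc = notch(_recording(layout8, np.full((8, n), 7.0)))
        assert np.allclose(rdc.data, 7.0, atol=1e-6)

    def test_invalid_edges_rejected(self, layout8):
        rec = _recording(layout8, np.zeros((8, 100)))
        with pytest.raises(ValueError):
            bandpass(rec, low=30.0, high=25.0)
        with pytest.raises(ValueError):
            notch(rec, freq=300.0)


class TestEog:
    def test_identical_channels_give_zero_eog(self, layout8):
        data = np.tile(np.sin(np.arange(100.0)), (8, 1))
        rec = make_eog(_recording(layout8, data), "E1", "E2")
        assert rec.layout.channel_names[-1] == EOG_NAME
        assert np.allclose(rec.data[-1], 0)
        assert EOG_NAME in rec.non_scalp

    def test_blink_arithmetic(self, layout8):
        data = np.zeros((8, 1000))
        tmpl = blink_template(500.0)
        i1, i2 = layout8.index("E1"), layout8.index("E2")
        data[i1, 100:100 + tmpl.size] = 60.0 * tmpl
        data[i2, 100:100 + tmpl.size] = -40.0 * tmpl
        rec = make_eog(_recording(layout8, data), "E1", "E2")
        assert np.max(rec.data[-1]) == pytest.approx(100.0, rel=1e-9)

    def test_independent_noise_variances_add(self, layout8, rng):
        data = rng.standard_normal((8, 200_000)) * 3.0
        rec = make_eog(_recording(layout8, data), "E1", "E2")
        assert np.var(rec.data[-1]) == pytest.approx(2 * 9.0, rel=0.05)

    def test_missing_channel(self, layout8):
        with pytest.raises(KeyError):
            make_eog(_recording(layout8, np.zeros((8, 10))), "E1", "nope")


class TestBlinkRemoval:
    def _blinky(self, layout, rng, amp=80.0, srate=500.0, n=30_000):
        clean = rng.standard_normal((layout.n_channels, n)) * 5.0
        tmpl = blink_template(srate)
        w = blink_topography(layout) * amp
        blink = np.zeros(n)
        onsets = np.arange(2000, n - tmpl.size, 3000)
        for i in onsets:
            blink[i:i + tmpl.size] += tmpl
        mixed = clean + w[:, None] * blink[None, :]
        eog = 1.3 * blink * amp + rng.standard_normal(n) * 1.0
        data = np.vstack([mixed, eog])
        from auderp.layout import SensorLayout
        lay = SensorLayout(layout.channel_names + [EOG_NAME],
                           np.vstack([layout.positions, layout.positions[-1]]),
                           layout.reference_name)
        rec = Recording(data, srate, lay,
                        EventSchedule(np.empty(0), [], np.empty(0, int)),
                        [EOG_NAME])
        blink_mask = np.abs(blink) > 0.02
        quiet_mask = blink == 0.0
        return rec, clean, blink_mask, quiet_mask

    def test_known_mixing_mostly_removed(self, layout32, rng):
        rec, clean, blink_mask, quiet = self._blinky(layout32, rng)
        out = remove_blinks(rec)
        frontal = np.argsort(-np.abs(blink_topography(layout32)))[:5]
        before = rec.data[frontal][:, blink_mask] - clean[frontal][:, blink_mask]
        after = out.data[frontal][:, blink_mask] - clean[frontal][:, blink_mask]
        reduction = 1 - np.var(after) / np.var(before)
        assert reduction >= 0.80
        # blink-free segments barely touched
        rms_change = np.sqrt(np.mean((out.data[frontal][:, quiet]
                                      - rec.data[frontal][:, quiet]) ** 2))
        rms_signal = np.sqrt(np.mean(rec.data[frontal][:, quiet] ** 2))
        assert rms_change / rms_signal < 0.05

    def test_no_blinks_is_noop(self, layout8, rng):
        data = np.vstack([rng.standard_normal((8, 5000)),
                          np.zeros((1, 5000))])
        from auderp.layout import SensorLayout
        lay = SensorLayout(layout8.channel_names + [EOG_NAME],
                           np.vstack([layout8.positions, layout8.positions[-1]]),
                           "Cz")
        rec = Recording(data, 500.0, lay,
                        EventSchedule(np.empty(0), [], np.empty(0, int)),
                        [EOG_NAME])
        with pytest.raises(ValueError):
            remove_blinks(rec)  # zero-variance EOG is degenerate

    def test_blink_confined_to_eog_leaves_scalp(self, layout8, rng):
        scalp = rng.standard_normal((8, 20_000))
        tmpl = blink_template(500.0)
        eog = np.zeros(20_000)
        for i in range(1000, 19_000, 2500):
            eog[i:i + tmpl.size] += 100 * tmpl
        from auderp.layout import SensorLayout
        lay = SensorLayout(layout8.channel_names + [EOG_NAME],
                           np.vstack([layout8.positions, layout8.positions[-1]]),
                           "Cz")
        rec = Recording(np.vstack([scalp, eog]), 500.0, lay,
                        EventSchedule(np.empty(0), [], np.empty(0, int)),
                        [EOG_NAME])
        out = remove_blinks(rec)
        rms = np.sqrt(np.mean((out.data[:8] - scalp) ** 2))
        assert rms < 0.05 * np.sqrt(np.mean(scalp ** 2))


class TestReference:
    def test_constant_offset_zeroed(self, layout32):
        rec = _recording(layout32, np.full((32, 100), 5.0))
        out = rereference_average(rec)
        assert np.allclose(out.data, 0, atol=1e-9)

    def test_scalp_mean_is_zero(self, layout32, rng):
        rec = _recording(layout32, rng.standard_normal((32, 500)))
        out = rereference_average(rec)
        scalp = [i for i in range(32) if i != layout32.index("Cz")]
        assert np.max(np.abs(out.data[scalp].mean(axis=0))) < 1e-9

    def test_idempotent(self, layout32, rng):
        rec = _recording(layout32, rng.standard_normal((32, 200)))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data, atol=1e-9)

    def test_reference_reconstruction_of_smooth_field(self, layout128):
        # dipolar (first-order spherical-harmonic) field, avg-referenced
        d = np.array([0.3, -0.5, 0.81])
        field = layout128.positions @ d
        rec = _recording(layout128, np.tile(field[:, None], (1, 3)))
        out = rereference_average(rec)
        icz = layout128.index("Cz")
        scalp = [i for i in range(128) if i != icz]
        truth = field[icz] - field[scalp].mean()
        assert out.data[icz, 0] == pytest.approx(truth, rel=0.05)


class TestSpline:
    def test_constant_field_reproduced(self, layout32, rng):
        vals = np.full(28, 3.7)
        est = spline_interpolate_array(layout32.positions[:28], vals,
                                       layout32.positions[28:])
        assert np.allclose(est, 3.7, atol=1e-6)

    def test_leave_one_out_smooth_field(self, layout128):
        # low-order harmonic: Y_2-like field on the sphere
        p = layout128.positions
        field = 3 * p[:, 2] ** 2 - 1 + 0.5 * p[:, 0]
        errs = []
        for i in range(0, 128, 16):
            good = np.delete(np.arange(128), i)
            est = spline_interpolate_array(p[good], field[good], p[[i]])
            errs.append(abs(est[0] - field[i]))
        rel = np.max(errs) / np.ptp(field)
        assert rel <= 0.05

    def test_exact_at_duplicated_knot(self, layout32, rng):
        field = np.cos(layout32.positions @ np.array([0.2, 0.1, 0.97]))
        good = np.arange(31)
        # without the ridge term the spline passes through its knots exactly
        est = spline_interpolate_array(layout32.positions[good], field[good],
                                       layout32.positions[[5]], ridge=0.0)
        assert est[0] == pytest.approx(field[5], abs=1e-9)

    def test_too_few_channels(self, layout8):
        with pytest.raises(ValueError):
            spline_interpolate_array(layout8.positions[:3], np.zeros(3),
                                     layout8.positions[3:])

    def test_recording_level_interpolation(self, layout32, rng):
        d = np.array([0.1, 0.2, 0.97])
        field = layout32.positions @ d
        rec = _recording(layout32, np.tile(field[:, None], (1, 5)))
        out = spline_interpolate(rec, ["E7"])
        i = layout32.index("E7")
        assert out.data[i, 0] == pytest.approx(field[i], rel=0.05)


class TestEpoching:
    def _rec_with_events(self, layout, onsets, labels, n=3000, srate=500.0,
                         value=None, rng=None):
        data = (np.full((layout.n_channels, n), value) if value is not None
                else rng.standard_normal((layout.n_channels, n)))
        ev = EventSchedule(np.asarray(onsets, float), labels,
                           np.zeros(len(labels), int))
        return Recording(data, srate, layout, ev)

    def test_constant_channel_zero_after_baseline(self, layout8):
        rec = self._rec_with_events(layout8, [1.0, 2.5], ["SON", "OFN"],
                                    value=4.2)
        ep = epoch_and_baseline(rec)
        assert np.allclose(ep.data, 0, atol=1e-12)
        assert ep.data.shape == (2, 8, 601)

    def test_baseline_mean_invariant(self, layout8, rng):
        rec = self._rec_with_events(layout8, [1.0, 2.5, 4.0],
                                    ["SON", "OFN", "SON"], rng=rng)
        ep = epoch_and_baseline(rec)
        bl = ep.times <= 0
        assert np.max(np.abs(ep.data[:, :, bl].mean(axis=2))) < 1e-9

    def test_partial_window_dropped(self, layout8, rng):
        rec = self._rec_with_events(layout8, [0.1, 2.0], ["SON", "OFN"],
                                    rng=rng)
        ep = epoch_and_baseline(rec)  # first event lacks the -200 ms margin
        assert ep.n_trials == 1 and ep.labels == ["OFN"]

    def test_no_retainable_events(self, layout8, rng):
        rec = self._rec_with_events(layout8, [0.05], ["SON"], n=100, rng=rng)
        with pytest.raises(ValueError):
            epoch_and_baseline(rec)


class TestAutoreject:
    def _epochs(self, layout, rng, n_trials=20):
        data = rng.standard_normal((n_trials, layout.n_channels, 601)) * 5
        return EpochSet(data, -0.2, 1.0, 500.0, ["SON"] * n_trials, layout)

    def test_clean_epochs_untouched(self, layout32, rng):
        ep = autoreject_like(self._epochs(layout32, rng))
        assert ep.rejected_mask.sum() == 0
        assert ep.provenance["autoreject"]["n_repaired"] == 0

    def test_wide_burst_rejects_trial(self, layout32, rng):
        ep = self._epochs(layout32, rng)
        bad = rng.choice(32, size=10, replace=False)  # 30 % of channels
        ep.data[3, bad, 200:300] += 500.0
        out = autoreject_like(ep)
        assert out.rejected_mask[3]
        assert out.rejected_mask.sum() == 1

    def test_single_channel_burst_repaired(self, layout32, rng):
        ep = self._epochs(layout32, rng)
        i = layout32.index("E11")
        ep.data[5, i, 250:350] += 400.0
        out = autoreject_like(ep)
        assert not out.rejected_mask[5]
        assert out.provenance["autoreject"]["n_repaired"] == 1
        ptp = np.ptp(out.data[5, i])
        others = np.ptp(ep.data[:, i, :], axis=1)
        assert ptp < np.median(others) + 6 * 1.4826 * np.median(
            np.abs(others - np.median(others)))

    def test_needs_enough_trials(self, layout8, rng):
        with pytest.raises(ValueError):
            autoreject_like(self._epochs(layout8, rng, n_trials=5))
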