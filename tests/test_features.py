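import math

import numpy as np
import pytest

import connspeech as cs
from connspeech.audio import AudioBuffer
from connspeech.features import (FeatureExtractor, ast, average_runs, dpi,
                                 dus, dvi, est, gvi, lre, pir, rlr, rsr, rst,
                                 saturate_pauses)
from connspeech.intervals import LabeledInterval

from conftest import make_tiers


def regular_tiers(n=20, step=0.5, dur=0.25):
    """Voiced intervals at a regular cadence separated by pauses."""
    pattern = []
    t = 0.0
    for _ in range(n):
        pattern.append((t, t + dur, "voiced"))
        pattern.append((t + dur, t + step, "pause"))
        t += step
    return make_tiers(pattern)


class TestSaturation:
    def test_long_pause_capped(self):
        tiers = make_tiers([(0, 1, "voiced"), (1, 4.5, "pause")])
        sat = saturate_pauses(tiers)
        assert sat.pause[0].duration_s == pytest.approx(2.0)

    def test_short_pause_unchanged_and_identity(self):
        tiers = make_tiers([(0, 1, "voiced"), (1, 2.9, "pause")])
        assert saturate_pauses(tiers).pause[0].duration_s == pytest.approx(1.9)
        none = make_tiers([(0, 1, "voiced")])
        assert saturate_pauses(none).pause == []


class TestTimingFeatures:
    def test_rst_regular_intervals_exact(self):
        # one interval per 0.25 s of occurrence spacing -> slope 4.0
        tiers = regular_tiers(n=20, step=0.5)
        assert rst(tiers) == pytest.approx(4.0, abs=1e-9)

    def test_rst_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        t = 0.0
        pattern = []
        for i in range(30):
            d = rng.uniform(0.1, 0.6)
            pattern.append((t, t + d, "voiced" if i % 2 else "pause"))
            t += d
        tiers = make_tiers(pattern)
        occ = np.sort([iv.mid_s for iv in tiers.all_speech_intervals()])
        c = np.arange(1, len(occ) + 1)
        slope = np.linalg.lstsq(np.column_stack([occ, np.ones_like(occ)]),
                                c.astype(float), rcond=None)[0][0]
        assert rst(tiers) == pytest.approx(slope, abs=1e-9)

    def test_rst_undefined_below_two_intervals(self):
        assert math.isnan(rst(make_tiers([(0, 1, "voiced")])))

    def test_ast_stationary_is_zero(self):
        assert ast(regular_tiers(n=40)) == pytest.approx(0.0, abs=1e-6)

    def test_ast_sign_for_accelerating_speech(self):
        pattern = []
        t = 0.0
        for i in range(10):  # sparse first half
            pattern.append((t, t + 0.5, "voiced")); t += 0.5
            pattern.append((t, t + 0.5, "pause")); t += 0.5
        for i in range(40):  # dense second half
            pattern.append((t, t + 0.125, "voiced")); t += 0.125
            pattern.append((t, t + 0.125, "pause")); t += 0.125
        assert ast(make_tiers(pattern)) > 0

    def test_ast_recovers_programmed_ramp(self):
        # recordings generated with interval rate doubling over duration
        signs = []
        for seed in range(20):
            _, tiers = cs.generate_recording(
                cs.make_spec("control", seed=seed, duration_s=20,
                             rate_ramp=2.0),
                render_audio=False)
            signs.append(ast(tiers) > 0)
        assert np.mean(signs) >= 0.9

    def test_dpi_median_and_saturation(self):
        tiers = make_tiers([(0, 1, "voiced"), (1, 1.1, "pause"),
                            (1.1, 2, "voiced"), (2, 2.3, "pause"),
                            (2.3, 3, "voiced"), (3, 3.5, "pause")])
        assert dpi(tiers) == pytest.approx(300.0, abs=1e-9)
        single = saturate_pauses(make_tiers([(0, 1, "voiced"),
                                             (1, 4, "pause")]))
        assert dpi(single) == pytest.approx(2000.0, abs=1e-9)

    def test_dvi_mean(self):
        tiers = make_tiers([(0, 0.2, "voiced"), (0.2, 0.3, "pause"),
                            (0.3, 0.7, "voiced")])
        assert dvi(tiers) == pytest.approx(300.0, abs=1e-9)

    def test_est_uniform_and_degenerate_and_hand_case(self):
        uniform = make_tiers(
            [(i, i + 0.5, k) for i, k in
             zip(np.arange(0, 20, 0.5),
                 ["voiced", "unvoiced", "pause", "respiration"] * 10)])
        assert est(uniform) == pytest.approx(2.0, abs=1e-12)
        only_voiced = make_tiers([(0, 1, "voiced"), (1, 2, "voiced")])
        assert est(only_voiced) == pytest.approx(0.0, abs=1e-12)
        # nv=2, nu=1, np=1 -> -0.5 log 0.5 - 2 * 0.25 log 0.25 = 1.5 bits
        mixed = make_tiers([(0, 1, "voiced"), (1, 2, "voiced"),
                            (2, 3, "unvoiced"), (3, 4, "pause")])
        assert est(mixed) == pytest.approx(1.5, abs=1e-12)

    def test_est_always_within_two_bits(self):
        for seed in range(10):
            _, tiers = cs.generate_recording(
                cs.make_spec("pd_like", seed=seed, duration_s=8),
                render_audio=False)
            assert 0.0 <= est(tiers) <= 2.0


class TestMixtureFeatures:
    def test_dus_recovers_planted_stop_mode(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            durs = np.concatenate([rng.normal(0.030, 0.005, 15),
                                   rng.normal(0.120, 0.015, 15)])
            durs = np.clip(durs, 0.008, None)
            t, pattern = 0.0, []
            for d in durs:
                pattern.append((t, t + d, "unvoiced")); t += d
                pattern.append((t, t + 0.2, "voiced")); t += 0.2
            v = dus(make_tiers(pattern), seed=0)
            if abs(v - 30.0) <= 8.0:
                hits += 1
        assert hits >= 18

    def test_dus_degenerate_identical_durations(self):
        pattern = []
        t = 0.0
        for _ in range(6):
            pattern.append((t, t + 0.05, "unvoiced")); t += 0.05
            pattern.append((t, t + 0.2, "voiced")); t += 0.2
        assert dus(make_tiers(pattern)) == pytest.approx(50.0, abs=1e-6)

    def test_dus_direction_on_cohorts(self):
        vals = {"control": [], "pd_like": []}
        for preset in vals:
            for seed in range(15):
                _, tiers = cs.generate_recording(
                    cs.make_spec(preset, seed=seed, duration_s=20),
                    render_audio=False)
                v = dus(tiers)
                if not math.isnan(v):
                    vals[preset].append(v)
        assert np.mean(vals["pd_like"]) > np.mean(vals["control"])

    def test_gvi_counts_planted_clear_gaps(self):
        rng = np.random.default_rng(1)
        durs = np.concatenate([rng.normal(0.050, 0.010, 20),
                               rng.normal(0.400, 0.050, 20)])
        durs = np.clip(durs, 0.01, None)
        t, pattern = 0.0, []
        for d in durs:
            pattern.append((t, t + 0.5, "voiced")); t += 0.5
            pattern.append((t, t + d, "pause")); t += d
        pattern.append((t, t + 0.5, "voiced")); t += 0.5
        tiers = make_tiers(pattern, duration=60.0)
        assert gvi(tiers) == pytest.approx(20 / 60.0, rel=0.15)

    def test_gvi_undefined_without_qualifying_pauses(self):
        tiers = make_tiers([(0, 1, "voiced"), (1, 1.2, "pause"),
                            (1.2, 1.5, "unvoiced")])
        assert math.isnan(gvi(tiers))

    def test_gvi_respiration_rejection_monotonic(self):
        pattern = [(0, 0.5, "voiced"), (0.5, 1.0, "pause"),
                   (1.0, 1.5, "voiced"), (1.5, 1.9, "pause"),
                   (1.9, 2.4, "voiced"), (2.4, 2.6, "pause"),
                   (2.6, 3.1, "voiced"), (3.1, 3.25, "pause"),
                   (3.25, 3.8, "voiced")]
        with_resp = make_tiers(pattern + [(0.6, 0.9, "respiration")])
        without = make_tiers(pattern)
        from connspeech.features import _qualifying_gaps
        assert len(_qualifying_gaps(without)) >= len(_qualifying_gaps(with_resp))


class TestRespirationFeatures:
    def test_rsr_regular_breathing(self):
        tiers = make_tiers([(0, 10, "pause"),
                            (0.9, 1.1, "respiration"),
                            (2.9, 3.1, "respiration"),
                            (4.9, 5.1, "respiration")])
        assert rsr(tiers) == pytest.approx(30.0, abs=1e-9)

    def test_pir_median_pause_count(self):
        pattern = [(0, 20, "pause")]
        resp_mids = [1, 5, 10, 16]
        for m in resp_mids:
            pattern.append((m - 0.1, m + 0.1, "respiration"))
        tiers = make_tiers(pattern)
        # plant 2, 3 and 4 pause mid-times between consecutive breaths
        tiers.pause = [LabeledInterval(a, a + 0.2, "pause") for a in
                       [2, 3, 6, 7, 8, 11, 12, 13, 14]]
        assert pir(tiers) == pytest.approx(3.0, abs=1e-9)

    def test_lre_latency(self):
        tiers = make_tiers([(0, 1.0, "voiced"), (1.0, 2.0, "pause"),
                            (1.2, 1.5, "respiration")])
        assert lre(tiers) == pytest.approx(200.0, abs=1e-9)

    def test_rlr_construction(self):
        rate = 8000
        rng = np.random.default_rng(0)
        x = np.zeros(4 * rate)
        x[:rate] = rng.normal(size=rate) * 0.2          # "speech"
        x[2 * rate:3 * rate] = rng.normal(size=rate) * 0.1  # breath at -6 dB
        tiers = make_tiers([(0, 1, "voiced"), (1, 4, "pause"),
                            (2, 3, "respiration")])
        audio = AudioBuffer(x, rate)
        assert rlr(tiers, audio) == pytest.approx(-6.0, abs=1.0)
        # equal levels -> ~0 dB
        x2 = np.zeros(4 * rate)
        x2[:rate] = rng.normal(size=rate) * 0.2
        x2[2 * rate:3 * rate] = rng.normal(size=rate) * 0.2
        assert rlr(tiers, AudioBuffer(x2, rate)) == pytest.approx(0.0, abs=0.5)
        # microphone gain cancels
        assert rlr(tiers, AudioBuffer(10 * x, rate)) == \
            pytest.approx(rlr(tiers, audio), abs=0.01)


class TestExtractAll:
    def test_all_fields_populated_or_nan(self, segmented_recording):
        pre, _, detected = segmented_recording
        fs = cs.extract_all(pre, detected)
        for name in cs.FEATURE_NAMES:
            assert isinstance(fs.as_dict()[name], float)
        assert fs.nt == fs.nv + fs.nu + fs.np_ + fs.nr

    def test_gain_invariance_fixed_tiers(self, segmented_recording):
        pre, _, detected = segmented_recording
        a = cs.extract_all(pre, detected)
        loud = AudioBuffer(pre.samples * 3.0, pre.rate)
        b = cs.extract_all(loud, detected)
        for name in cs.FEATURE_NAMES:
            va, vb = a.as_dict()[name], b.as_dict()[name]
            if math.isnan(va):
                assert math.isnan(vb)
            elif name == "rlr_db":
                assert va == pytest.approx(vb, abs=0.01)
            else:
                assert va == pytest.approx(vb, abs=1e-6)

    def test_time_shift_adds_one_pause_only(self):
        base = make_tiers([(0, 0.5, "voiced"), (0.5, 0.8, "pause"),
                           (0.8, 1.4, "voiced"), (1.4, 1.8, "pause"),
                           (1.8, 2.2, "voiced")])
        shifted_pattern = [(0, 1.0, "pause")] + \
            [(iv.start_s + 1.0, iv.end_s + 1.0, iv.klass)
             for iv in base.to_flat()]
        shifted = make_tiers(shifted_pattern)
        assert len(shifted.pause) == len(base.pause) + 1
        assert dvi(shifted) == pytest.approx(dvi(base), abs=1e-9)
        assert dus(shifted) if not math.isnan(dus(shifted)) else True

    def test_two_identical_runs_average_to_single_run(self, segmented_recording):
        pre, _, detected = segmented_recording
        fs = cs.extract_all(pre, detected)
        avg = average_runs([fs, fs])
        for name in cs.FEATURE_NAMES:
            va, vb = fs.as_dict()[name], avg.as_dict()[name]
            assert (math.isnan(va) and math.isnan(vb)) or va == pytest.approx(vb)
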