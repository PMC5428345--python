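"""Synthetic connected-speech generator with exact ground-truth labels.

Real recordings of the kind this package analyses are not publicly
deposited, so every downstream stage is exercised on synthetic speech
whose class-conditional acoustics match the discriminative axes the
segmenter uses:

* voiced segments — impulse train at f0 through two formant resonators
  (~500 and ~1500 Hz): periodic, low-frequency-dominant (high ACR, low
  ZCR, high PWR);
* unvoiced fricatives — noise high-pass filtered above 2.5 kHz;
* unvoiced stops — closure (background noise only) followed by a short
  broadband burst;
* pauses — background noise only;
* respirations — noise band-pass filtered to the 500-2000 Hz resonance
  characteristic of audible inspiration, placed only inside pauses of
  at least 300 ms.

Group-level presets shift the timing distributions in the direction of
parkinsonian dysarthria (prolonged pauses, prolonged stops, fewer
intervals per second, quieter respiration).  Interval durations are
lognormal; ``(mean_s, sigma)`` parameterize the median duration in
seconds and the log-space spread.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .audio import AudioBuffer
from .intervals import LabeledInterval, SegmentTiers

SYNTH_RATE = 48000

PD_LIKE_SHIFTS = {
    "pause_mean": 1.5,
    "stop_scale": 1.4,
    "voiced_mean": 1.2,
    "respiration_level_shift_db": -6.0,
}


@dataclass
class SynthSpec:
    """Parameters of one synthetic recording."""

    seed: int = 0
    duration_s: float = 20.0
    f0_hz: float = 120.0
    voiced_dur: tuple = (0.25, 0.35)        # lognormal (median_s, sigma)
    fricative_dur: tuple = (0.12, 0.25)
    stop_closure_dur: tuple = (0.045, 0.25)
    stop_burst_dur: tuple = (0.015, 0.2)
    pause_dur: tuple = (0.30, 0.45)
    respiration_dur: tuple = (0.35, 0.20)
    respiration_every_n_pauses: int = 3
    snr_db: float = -40.0                   # background noise re voiced RMS
    respiration_level_db: float = -18.0     # respiration re voiced RMS
    fricative_level_db: float = -10.0
    burst_level_db: float = -6.0
    group_preset: str = "control"
    rate: int = SYNTH_RATE
    # optional linear rate modulation (interval rate multiplier at t=T vs t=0)
    rate_ramp: float = 1.0

    def validate(self) -> None:
        if self.group_preset not in ("control", "pd_like"):
            raise ValueError(f"unknown group_preset {self.group_preset!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("voiced_dur", "fricative_dur", "stop_closure_dur",
                     "stop_burst_dur", "respiration_dur"):
            m, s = getattr(self, name)
            if m <= 0 or s < 0:
                raise ValueError(f"{name} must have positive median")
        if self.pause_dur[0] < 0 or self.pause_dur[1] < 0:
            raise ValueError("pause_dur must be non-negative")


def make_spec(group_preset: str = "control", **overrides) -> SynthSpec:
    """Build a control or pd_like :class:`SynthSpec`.

    The pd_like preset multiplies the median pause duration by 1.5, stop
    closure/burst durations by 1.4 and the median voiced duration by
    1.2, and lowers the respiration level by 6 dB — the direction of the
    group effects the features are designed to capture.
    """
    spec = SynthSpec(group_preset=group_preset, **overrides)
    if group_preset == "pd_like":
        spec = replace(
            spec,
            pause_dur=(spec.pause_dur[0] * PD_LIKE_SHIFTS["pause_mean"],
                       spec.pause_dur[1]),
            stop_closure_dur=(spec.stop_closure_dur[0] * PD_LIKE_SHIFTS["stop_scale"],
                              spec.stop_closure_dur[1]),
            stop_burst_dur=(spec.stop_burst_dur[0] * PD_LIKE_SHIFTS["stop_scale"],
                            spec.stop_burst_dur[1]),
            voiced_dur=(spec.voiced_dur[0] * PD_LIKE_SHIFTS["voiced_mean"],
                        spec.voiced_dur[1]),
            respiration_level_db=spec.respiration_level_db
            + PD_LIKE_SHIFTS["respiration_level_shift_db"],
        )
    spec.validate()
    return spec


def _lognormal(rng, params, scale=1.0):
    median, sigma = params
    if median <= 0:
        return 0.0
    return float(median * scale * np.exp(sigma * rng.standard_normal()))


# ---------------------------------------------------------------------------
# timeline construction

def _plan_timeline(spec: SynthSpec, rng, fixed_sequence: bool = False):
    """Build the ground-truth event list: (class, duration, subkind).

    A phrase is a few voiced intervals separated by consonants, closed
    by a pause; every n-th pause hosts a respiration.  ``rate_ramp``
    linearly rescales durations over the course of the recording so a
    programmed acceleration of interval rate can be planted.
    """
    events = []  # (klass, dur, subkind)
    t = 0.0
    pause_count = 0
    phrase_pattern = ["fricative", "stop"]
    while t < spec.duration_s:
        n_voiced = 3 if fixed_sequence else int(rng.integers(2, 5))
        # duration scale from the linear rate ramp (rate x => durations /x)
        for j in range(n_voiced):
            frac = min(t / spec.duration_s, 1.0)
            sc = 1.0 / (1.0 + (spec.rate_ramp - 1.0) * frac)
            dv = max(0.04, _lognormal(rng, spec.voiced_dur, sc))
            events.append(("voiced", dv, None))
            t += dv
            if j < n_voiced - 1:
                if fixed_sequence:
                    kind = phrase_pattern[j % 2]
                else:
                    kind = "fricative" if rng.random() < 0.5 else "stop"
                if kind == "fricative":
                    dfr = max(0.02, _lognormal(rng, spec.fricative_dur, sc))
                    events.append(("unvoiced", dfr, "fricative"))
                    t += dfr
                else:
                    # stop = closure silence then burst; the closure is
                    # ground-truth pause (a pause preceding speech ends at
                    # the initial burst of an explosive consonant)
                    dc = max(0.03, _lognormal(rng, spec.stop_closure_dur, sc))
                    db = max(0.008, _lognormal(rng, spec.stop_burst_dur, sc))
                    events.append(("pause", dc, "closure"))
                    events.append(("unvoiced", db, "burst"))
                    t += dc + db
        dp = _lognormal(rng, spec.pause_dur)
        if dp <= 0:
            continue
        dp = max(0.08, dp)
        pause_count += 1
        resp = None
        if (spec.respiration_every_n_pauses > 0
                and pause_count % spec.respiration_every_n_pauses == 0):
            dr = max(0.08, _lognormal(rng, spec.respiration_dur))
            # host pause must fit the respiration with >= 100 ms margins
            dp = max(dp, dr + 0.30)
            off = 0.10 + rng.random() * max(dp - dr - 0.22, 0.0)
            resp = (off, dr)
        events.append(("pause", dp, resp))
        t += dp
    return events


# ---------------------------------------------------------------------------
# waveform synthesis

def _voiced_wave(n, rate, f0, rng):
    """Impulse train through two formant resonators, unit RMS."""
    x = np.zeros(n)
    period = max(int(rate / f0), 1)
    x[::period] = 1.0
    for fc, bw in ((500.0, 120.0), (1500.0, 200.0)):
        r = np.exp(-np.pi * bw / rate)
        theta = 2 * np.pi * fc / rate
        b = [1.0 - r]
        a = [1.0, -2 * r * np.cos(theta), r * r]
        x = sps.lfilter(b, a, x)
    rms = np.sqrt(np.mean(x ** 2))
    return x / max(rms, 1e-12)


_SOS_CACHE = {}


def _sos(kind, rate):
    key = (kind, rate)
    if key not in _SOS_CACHE:
        if kind == "fric":
            _SOS_CACHE[key] = sps.butter(4, 2500.0, "highpass", fs=rate,
                                         output="sos")
        else:
            _SOS_CACHE[key] = sps.butter(4, [500.0, 2000.0], "bandpass",
                                         fs=rate, output="sos")
    return _SOS_CACHE[key]


def _noise(n, rng, sos=None):
    x = rng.standard_normal(n)
    if sos is not None:
        x = sps.sosfilt(sos, x)
    rms = np.sqrt(np.mean(x ** 2))
    return x / max(rms, 1e-12)


def _fade(x, rate, ms=5.0):
    k = min(int(rate * ms / 1000.0), len(x) // 2)
    if k > 0:
        ramp = np.linspace(0.0, 1.0, k)
        x[:k] *= ramp
        x[-k:] *= ramp[::-1]
    return x


def generate_recording(spec: SynthSpec, fixed_sequence: bool = False,
                       render_audio: bool = True):
    """Generate one recording and its exact ground-truth tiers.

    Returns ``(AudioBuffer | None, SegmentTiers)``.  The waveform is
    synthesized at 48 kHz (so the preprocessing decimation path is
    exercised); identical specs produce bit-identical output.  With
    ``render_audio=False`` only the tiers are built (fast path for
    large timing-only cohorts).
    """
    spec.validate()
    if spec.duration_s < 5:
        raise ValueError("duration_s must be at least 5 s")
    rng = np.random.default_rng(spec.seed)
    events = _plan_timeline(spec, rng, fixed_sequence)
    duration = sum(d for _, d, _ in events)
    rate = spec.rate

    tiers = SegmentTiers(duration_s=duration)
    t = 0.0
    spans = []  # (klass, t0, t1, subkind)
    for klass, d, sub in events:
        tiers.tier(klass if klass != "pause" else "pause").append(
            LabeledInterval(round(t, 6), round(t + d, 6), klass))
        if klass == "pause" and isinstance(sub, tuple):
            off, dr = sub
            tiers.respiration.append(
                LabeledInterval(round(t + off, 6), round(t + off + dr, 6),
                                "respiration"))
        spans.append((klass, t, t + d, sub))
        t += d

    if not render_audio:
        return None, tiers

    n_total = int(round(duration * rate))
    amp = lambda db: 10.0 ** (db / 20.0)
    x = _noise(n_total, rng) * amp(spec.snr_db)  # background noise floor
    for klass, t0, t1, sub in spans:
        i0, i1 = int(round(t0 * rate)), int(round(t1 * rate))
        n = i1 - i0
        if n <= 0:
            continue
        if klass == "voiced":
            x[i0:i1] += _fade(_voiced_wave(n, rate, spec.f0_hz, rng), rate)
        elif klass == "unvoiced":
            if sub == "fricative":
                x[i0:i1] += _fade(_noise(n, rng, _sos("fric", rate)), rate) \
                    * amp(spec.fricative_level_db)
            else:  # stop burst: short broadband noise
                x[i0:i1] += _fade(_noise(n, rng), rate, ms=2.0) \
                    * amp(spec.burst_level_db)
        elif klass == "pause" and isinstance(sub, tuple):
            off, dr = sub
            j0 = i0 + int(round(off * rate))
            j1 = min(j0 + int(round(dr * rate)), i1)
            if j1 > j0:
                x[j0:j1] += _fade(_noise(j1 - j0, rng, _sos("resp", rate)),
                                  rate, ms=20.0) * amp(spec.respiration_level_db)
    peak = np.max(np.abs(x))
    if peak > 1.0:
        x = x / (peak * 1.01)
    return AudioBuffer(x, rate, meta={"synthetic": True,
                                      "group": spec.group_preset}), tiers


# ---------------------------------------------------------------------------
# cohorts

@dataclass
class CohortEntry:
    subject_id: str
    group: str
    task: str            # "reading" or "monologue"
    audio: AudioBuffer | None
    tiers: SegmentTiers
    updrs3_star: int | None = None


def generate_cohort(n_per_group: int, presets: dict, seed: int = 0,
                    reading_duration_s: float = 20.0,
                    monologue_duration_s: float = 25.0,
                    render_audio: bool = True,
                    updrs_by_group: dict | None = None) -> list:
    """Generate a balanced cohort: two tasks per subject.

    ``presets`` maps group name -> base :class:`SynthSpec`.  Task A
    emulates the reading passage (fixed segment sequence); task B the
    monologue (random sequence, longer pauses).  ``updrs_by_group``
    optionally maps group -> (low, high) inclusive range from which a
    motor score is drawn per subject.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    entries = []
    for group, base in presets.items():
        for i in range(n_per_group):
            sid = f"{group}_{i:03d}"
            updrs = None
            if updrs_by_group and group in updrs_by_group:
                lo, hi = updrs_by_group[group]
                updrs = int(rng.integers(lo, hi + 1))
            for task, dur, fixed in (("reading", reading_duration_s, True),
                                     ("monologue", monologue_duration_s, False)):
                # per-recording seed derived from the cohort stream
                sub_seed = int(rng.integers(0, 2 ** 31 - 1))
                spec = replace(base, seed=sub_seed, duration_s=dur)
                if task == "monologue":
                    spec = replace(spec, pause_dur=(spec.pause_dur[0] * 1.25,
                                                    spec.pause_dur[1]))
                audio, tiers = generate_recording(spec, fixed_sequence=fixed,
                                                  render_audio=render_audio)
                entries.append(CohortEntry(sid, group, task, audio, tiers,
                                           updrs))
    return entries
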