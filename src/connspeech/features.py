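"""The 12 acoustic features of connected speech.

Timing: RST (rate of speech timing, intervals/s), AST (acceleration of
speech timing, intervals/s^2), DPI (duration of pause intervals, ms),
EST (entropy of speech timing, bits).  Articulation: DUS (duration of
unvoiced stops, ms), DUF (decay of unvoiced fricatives, per mille).
Phonation: DVI (duration of voiced intervals, ms), GVI (gaping
in-between voiced intervals, gaps/s).  Respiration: RSR (rate of speech
respiration, breaths/min), PIR (pause intervals per respiration), RLR
(relative loudness of respiration, dB), LRE (latency of respiratory
exchange, ms).

Pauses longer than 2 s are saturated to 2 s before any feature is
computed.  Features that are undefined for a recording (too few
intervals of the required kind) are reported as NaN, never as silent
zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .audio import AudioBuffer
from .intervals import LabeledInterval, SegmentTiers

PAUSE_SATURATION_S = 2.0

FEATURE_NAMES = ("rst", "ast", "dpi_ms", "est_bits", "dus_ms", "duf",
                 "dvi_ms", "gvi", "rsr", "pir", "rlr_db", "lre_ms")


@dataclass
class FeatureSet:
    """The 12 named features plus the interval counts behind EST."""

    rst: float = math.nan
    ast: float = math.nan
    dpi_ms: float = math.nan
    est_bits: float = math.nan
    dus_ms: float = math.nan
    duf: float = math.nan
    dvi_ms: float = math.nan
    gvi: float = math.nan
    rsr: float = math.nan
    pir: float = math.nan
    rlr_db: float = math.nan
    lre_ms: float = math.nan
    nv: int = 0
    nu: int = 0
    np_: int = 0
    nr: int = 0

    @property
    def nt(self) -> int:
        return self.nv + self.nu + self.np_ + self.nr

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def saturate_pauses(tiers: SegmentTiers,
                    max_s: float = PAUSE_SATURATION_S) -> SegmentTiers:
    """Cap every pause's effective duration at ``max_s``.

    Long pauses keep their start; the effective end (hence the
    occurrence mid-time) is recomputed from the saturated duration.
    The timeline is not re-tiled — this copy is for feature arithmetic.
    """
    out = SegmentTiers(duration_s=tiers.duration_s)
    out.voiced = list(tiers.voiced)
    out.unvoiced = list(tiers.unvoiced)
    out.respiration = list(tiers.respiration)
    for p in tiers.pause:
        if p.duration_s > max_s:
            p = LabeledInterval(p.start_s, p.start_s + max_s, "pause")
        out.pause.append(p)
    return out


def _occurrences(intervals):
    """Occurrence time of each interval: mean of start and end."""
    return np.array(sorted(iv.mid_s for iv in intervals))


def _slope(t: np.ndarray) -> float:
    """OLS slope of cumulative interval count vs occurrence time."""
    c = np.arange(1, len(t) + 1, dtype=float)
    tc = t - t.mean()
    denom = (tc ** 2).sum()
    if denom <= 0:
        return math.nan
    return float((tc * (c - c.mean())).sum() / denom)


def rst(tiers: SegmentTiers) -> float:
    """Rate of speech timing: regression slope of the cumulative count
    of voiced, unvoiced and pause intervals over their occurrence times."""
    ivs = tiers.all_speech_intervals()
    if len(ivs) < 2:
        return math.nan
    return _slope(_occurrences(ivs))


def _halftimes(T: float):
    # equal halves sharing 25% of the total duration
    return (0.0, 0.625 * T), (0.375 * T, T)


def ast(tiers: SegmentTiers) -> float:
    """Acceleration of speech timing: difference of the two halftime
    RSTs (halves overlap by 25% of the duration) over total duration."""
    T = tiers.duration_s
    occ = _occurrences(tiers.all_speech_intervals())
    (a1, b1), (a2, b2) = _halftimes(T)
    t1 = occ[(occ >= a1) & (occ <= b1)]
    t2 = occ[(occ >= a2) & (occ <= b2)]
    if len(t1) < 2 or len(t2) < 2 or T <= 0:
        return math.nan
    return (_slope(t2) - _slope(t1)) / T


def dpi(tiers: SegmentTiers) -> float:
    """Median pause duration in ms (saturated durations)."""
    if not tiers.pause:
        return math.nan
    return float(np.median([p.duration_s for p in tiers.pause]) * 1000.0)


def dvi(tiers: SegmentTiers) -> float:
    """Mean voiced-interval duration in ms."""
    if not tiers.voiced:
        return math.nan
    return float(np.mean([v.duration_s for v in tiers.voiced]) * 1000.0)


def est(tiers: SegmentTiers) -> float:
    """Shannon entropy (bits) of the interval-class occurrence counts."""
    counts = np.array([len(tiers.voiced), len(tiers.unvoiced),
                       len(tiers.pause), len(tiers.respiration)], dtype=float)
    nt = counts.sum()
    if nt < 1:
        return math.nan
    p = counts[counts > 0] / nt
    return float(-(p * np.log2(p)).sum())


def _fit_two_mode(durations, seed: int = 0):
    """1-D two-component GMM on durations; returns (labels, means)."""
    d = np.asarray(durations, dtype=float).reshape(-1, 1)
    if np.ptp(d) < 1e-12:
        return np.zeros(len(d), dtype=int), np.array([d[0, 0], d[0, 0]])
    gm = GaussianMixture(n_components=2, covariance_type="full",
                         reg_covar=1e-10, random_state=seed,
                         init_params="k-means++", n_init=1, max_iter=200)
    labels = gm.fit_predict(d)
    return labels, gm.means_.ravel()


def dus(tiers: SegmentTiers, seed: int = 0) -> float:
    """Median duration (ms) of unvoiced stops.

    Unvoiced-interval durations form a bimodal mixture of (shorter)
    stops and (longer) fricatives; the smaller-mean component is taken
    as the stops.
    """
    durations = [u.duration_s for u in tiers.unvoiced]
    if len(durations) < 4:
        return math.nan
    labels, means = _fit_two_mode(durations, seed)
    stop_comp = int(np.argmin(means))
    sel = np.asarray(durations)[labels == stop_comp]
    if len(sel) == 0:
        return math.nan
    return float(np.median(sel) * 1000.0)


def duf(tiers: SegmentTiers, track=None, seed: int = 0) -> float:
    """Decay of unvoiced fricatives, in parts per thousand.

    Fricatives (the larger-mean duration mixture component) are
    recognized per halftime; the mean MFCC_2 over their frames is
    compared between halftimes and normalized by total duration.  A
    positive value means the high-frequency bulk is damped over the
    course of the recording.
    """
    if track is None:
        return math.nan
    T = tiers.duration_s
    if T <= 0:
        return math.nan
    means = []
    for a, b in _halftimes(T):
        ivs = [u for u in tiers.unvoiced if a <= u.mid_s <= b]
        if len(ivs) < 4:
            return math.nan
        durations = [iv.duration_s for iv in ivs]
        labels, mode_means = _fit_two_mode(durations, seed)
        fric_comp = int(np.argmax(mode_means))
        frics = [iv for iv, lab in zip(ivs, labels) if lab == fric_comp]
        if len(frics) < 2:
            return math.nan
        sel = np.zeros(len(track.times), dtype=bool)
        for iv in frics:
            sel |= (track.times >= iv.start_s) & (track.times < iv.end_s)
        if not sel.any():
            return math.nan
        means.append(float(track.mfcc[sel, 1].mean()))
    return 1000.0 * (means[0] - means[1]) / T


def _qualifying_gaps(tiers: SegmentTiers):
    """Pauses flanked by voiced intervals on both sides, containing no
    respiration (candidate 'gaps' within voicing)."""
    ivs = tiers.all_speech_intervals()
    out = []
    for i, iv in enumerate(ivs):
        if iv.klass != "pause" or i == 0 or i == len(ivs) - 1:
            continue
        if ivs[i - 1].klass != "voiced" or ivs[i + 1].klass != "voiced":
            continue
        if any(r.start_s < iv.end_s and r.end_s > iv.start_s
               for r in tiers.respiration):
            continue
        out.append(iv)
    return out


def gvi(tiers: SegmentTiers, seed: int = 0) -> float:
    """Gaping in-between voiced intervals: clear gaps per second.

    Qualifying pauses (both neighbours voiced, no respiration inside)
    form a bimodal duration mixture of short 'clear gaps' and longer
    formal pauses; GVI counts the smaller-mean component per total
    recording time.
    """
    gaps = _qualifying_gaps(tiers)
    if len(gaps) < 4 or tiers.duration_s <= 0:
        return math.nan
    durations = [g.duration_s for g in gaps]
    labels, means = _fit_two_mode(durations, seed)
    clear_comp = int(np.argmin(means))
    n_clear = int((labels == clear_comp).sum())
    return n_clear / tiers.duration_s


def rsr(tiers: SegmentTiers) -> float:
    """Breaths per minute from consecutive respiration mid-times."""
    mids = _occurrences(tiers.respiration)
    if len(mids) < 2:
        return math.nan
    med = float(np.median(np.diff(mids)))
    if med <= 0:
        return math.nan
    return 60.0 / med


def pir(tiers: SegmentTiers) -> float:
    """Median number of pause intervals framed between consecutive
    respirations (pause occurrence mid-time strictly between the two
    respiration mid-times)."""
    mids = _occurrences(tiers.respiration)
    if len(mids) < 2:
        return math.nan
    pauses = _occurrences(tiers.pause)
    counts = [int(((pauses > a) & (pauses < b)).sum())
              for a, b in zip(mids[:-1], mids[1:])]
    return float(np.median(counts))


def lre(tiers: SegmentTiers) -> float:
    """Mean latency (ms) from the end of the nearest preceding speech
    interval (voiced or unvoiced) to the start of each respiration."""
    speech_ends = sorted(iv.end_s for iv in
                         list(tiers.voiced) + list(tiers.unvoiced))
    if not tiers.respiration or not speech_ends:
        return math.nan
    ends = np.array(speech_ends)
    lat = []
    for r in tiers.respiration:
        prior = ends[ends <= r.start_s]
        if len(prior):
            lat.append(r.start_s - prior[-1])
    if not lat:
        return math.nan
    return float(np.mean(lat) * 1000.0)


def rlr(tiers: SegmentTiers, audio: AudioBuffer,
        movavg_order: int = 120) -> float:
    """Relative loudness of respiration, dB.

    The squared signal is smoothed by a 120-point moving average (at the
    8 kHz analysis rate), log-scaled into loudness, and the median
    loudness over respiration samples is referenced to the median over
    speech (voiced plus unvoiced) samples.  Independent of microphone
    gain by construction.
    """
    if not tiers.respiration or (not tiers.voiced and not tiers.unvoiced):
        return math.nan
    x = audio.samples
    env = np.convolve(x ** 2, np.ones(movavg_order) / movavg_order,
                      mode="same")
    loud = 10.0 * np.log10(env + 1e-20)
    n = len(x)

    def sel(ivs):
        m = np.zeros(n, dtype=bool)
        for iv in ivs:
            a = int(iv.start_s * audio.rate)
            b = min(int(iv.end_s * audio.rate), n)
            m[a:b] = True
        return m

    resp = sel(tiers.respiration)
    speech = sel(list(tiers.voiced) + list(tiers.unvoiced))
    if not resp.any() or not speech.any():
        return math.nan
    return float(np.median(loud[resp]) - np.median(loud[speech]))


# ---------------------------------------------------------------------------

class FeatureExtractor(BaseEstimator):
    """Compute the 12-feature set from a segmentation (plus audio).

    ``transform(tiers, audio=None, track=None)`` returns a
    :class:`FeatureSet`.  ``audio`` (8 kHz, preprocessed) is needed for
    RLR and ``track`` (or audio, from which it is computed) for DUF;
    without them those two features are NaN.
    """

    def __init__(self, saturation_s: float = PAUSE_SATURATION_S, seed: int = 0):
        self.saturation_s = saturation_s
        self.seed = seed

    def fit(self, X=None, y=None):
        return self

    def transform(self, tiers: SegmentTiers, audio: AudioBuffer | None = None,
                  track=None) -> FeatureSet:
        sat = saturate_pauses(tiers, self.saturation_s)
        if track is None and audio is not None:
            from .frames import compute_track
            track = compute_track(audio)
        fs = FeatureSet(
            rst=rst(sat), ast=ast(sat), dpi_ms=dpi(sat), est_bits=est(sat),
            dus_ms=dus(sat, self.seed), duf=duf(sat, track, self.seed),
            dvi_ms=dvi(sat), gvi=gvi(sat, self.seed), rsr=rsr(sat),
            pir=pir(sat),
            rlr_db=rlr(sat, audio) if audio is not None else math.nan,
            lre_ms=lre(sat),
            nv=len(sat.voiced), nu=len(sat.unvoiced), np_=len(sat.pause),
            nr=len(sat.respiration),
        )
        return fs


def extract_all(audio: AudioBuffer | None, tiers: SegmentTiers,
                track=None, **params) -> FeatureSet:
    """Thin wrapper over :class:`FeatureExtractor`."""
    return FeatureExtractor(**params).transform(tiers, audio, track)


def average_runs(runs: list) -> FeatureSet:
    """Average FeatureSets over repeated runs of the same task.

    NaNs are ignored per feature unless all runs are NaN; counts are
    averaged and rounded.
    """
    out = FeatureSet()
    for name in FEATURE_NAMES:
        vals = [getattr(r, name) for r in runs]
        vals = [v for v in vals if not math.isnan(v)]
        setattr(out, name, float(np.mean(vals)) if vals else math.nan)
    for name in ("nv", "nu", "np_", "nr"):
        setattr(out, name, int(round(np.mean([getattr(r, name) for r in runs]))))
    return out
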