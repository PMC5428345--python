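"""Sequential adaptive segmentation into voiced, unvoiced, pause, respiration.

The recording is parameterized per frame (see :mod:`connspeech.frames`)
and the four classes are recognized class by class, each inside a long
sliding *recognition window* so that the decision adapts to the speaker
and ambient noise:

1. voiced speech — Gaussian-mixture clustering in (PWR, ACR, ZCR)
   inside 20 s windows advanced by 6 s; the mixture component with the
   highest mean PWR is voiced;
2. unvoiced speech — frames in voiceless runs shorter than 300 ms
   (which excludes most respirations) clustered on the first five LFCC
   inside 60 s windows advanced by 20 s; the component with the highest
   mean LFCC_1 (loudness) is unvoiced speech;
3. respiration — residual runs longer than 200 ms clustered the same
   way; again the loudest component is respiration;
4. pause — everything that is neither voiced nor unvoiced, including
   the time taken by respiration.

The number of mixture components (2 or 3) is chosen per window by the
Calinski-Harabasz index; mixtures are fitted by EM and frames assigned
by the Bayes discriminant rule (maximum posterior with mixture weights
as priors).  Rule-based smoothing with duration gates approximating the
natural timing of the speech apparatus follows each stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt
from sklearn.base import BaseEstimator
from sklearn.metrics import calinski_harabasz_score
from sklearn.mixture import GaussianMixture

from .audio import AudioBuffer, preprocess
from .frames import FrameTrack, compute_track
from .intervals import LabeledInterval, SegmentTiers


@dataclass
class GmmFit:
    """A fitted per-window Gaussian mixture with hard frame assignments."""

    k: int
    means: np.ndarray
    covariances: np.ndarray
    weights: np.ndarray
    labels: np.ndarray
    fallback: bool = False


def cluster_window(points: np.ndarray, k: int, seed: int = 0,
                   reg_covar: float = 1e-6) -> GmmFit:
    """Fit a k-component full-covariance GMM by EM (k-means++ init).

    On a degenerate fit (singular covariance) the ridge is increased
    100-fold and the fit retried once; if that also fails, hard k-means
    assignments are returned with a warning.
    """
    points = np.asarray(points, dtype=float)
    for ridge in (reg_covar, reg_covar * 100):
        try:
            gm = GaussianMixture(n_components=k, covariance_type="full",
                                 reg_covar=ridge, random_state=seed,
                                 init_params="k-means++", n_init=1,
                                 max_iter=200)
            labels = gm.fit_predict(points)
            return GmmFit(k, gm.means_, gm.covariances_, gm.weights_, labels)
        except Exception:
            continue
    from sklearn.cluster import KMeans
    warnings.warn("EM degenerate; falling back to k-means assignment")
    km = KMeans(n_clusters=k, n_init=3, random_state=seed).fit(points)
    means = km.cluster_centers_
    d = points.shape[1]
    cov = np.tile(np.eye(d), (k, 1, 1))
    w = np.bincount(km.labels_, minlength=k) / len(points)
    return GmmFit(k, means, cov, w, km.labels_, fallback=True)


def select_k(points: np.ndarray, seed: int = 0, k_range=(2, 3)):
    """Choose the number of mixture components by the Calinski-Harabasz index.

    Candidate clusterings for each k are fitted and the index evaluated
    on their hard assignments; the argmax k (and its fit) is returned.
    Fewer than 10 points falls back to k=2.
    """
    points = np.asarray(points, dtype=float)
    if len(points) < 10:
        warnings.warn("fewer than 10 points; falling back to k=2")
        fit = cluster_window(points, 2, seed) if len(points) >= 2 else None
        return 2, fit
    best = (-np.inf, k_range[0], None)
    for k in k_range:
        fit = cluster_window(points, k, seed)
        if len(np.unique(fit.labels)) < 2:
            score = -np.inf
        else:
            score = calinski_harabasz_score(points, fit.labels)
        if score > best[0]:
            best = (score, k, fit)
    if best[2] is None:  # every candidate collapsed to one cluster
        return 2, cluster_window(points, 2, seed)
    return best[1], best[2]


# ---------------------------------------------------------------------------
# mask utilities on the 5 ms frame grid

def runs_of(mask: np.ndarray):
    """Yield (start, stop, value) runs of a boolean/int vector."""
    mask = np.asarray(mask)
    if len(mask) == 0:
        return []
    change = np.flatnonzero(np.diff(mask) != 0) + 1
    bounds = np.concatenate(([0], change, [len(mask)]))
    return [(int(a), int(b), mask[a]) for a, b in zip(bounds[:-1], bounds[1:])]


def _suppress_short_runs(mask: np.ndarray, value: bool, min_frames: int) -> np.ndarray:
    out = mask.copy()
    for a, b, v in runs_of(mask):
        if bool(v) == value and (b - a) < min_frames:
            out[a:b] = not value
    return out


class _Votes:
    """Per-frame majority vote across overlapping recognition windows.

    Ties are broken by the earliest window's decision.
    """

    def __init__(self, n: int):
        self.pos = np.zeros(n, dtype=int)
        self.tot = np.zeros(n, dtype=int)
        self.first = np.full(n, -1, dtype=int)  # -1 unseen, else 0/1

    def add(self, idx: np.ndarray, decision: np.ndarray) -> None:
        self.tot[idx] += 1
        self.pos[idx] += decision.astype(int)
        unseen = self.first[idx] == -1
        self.first[idx[unseen]] = decision[unseen].astype(int)

    def result(self) -> np.ndarray:
        out = np.zeros(len(self.tot), dtype=bool)
        seen = self.tot > 0
        maj = self.pos * 2
        out[seen & (maj > self.tot)] = True
        tie = seen & (maj == self.tot)
        out[tie] = self.first[tie] == 1
        return out


def _window_slices(n: int, win: int, step: int):
    """Start indices of sliding recognition windows over n frames."""
    if n <= win:
        return [(0, n)]
    starts = list(range(0, n - win + 1, step))
    if starts[-1] + win < n:
        starts.append(n - win)
    return [(s, s + win) for s in starts]


# ---------------------------------------------------------------------------

def detect_voiced(track: FrameTrack, win_s: float = 20.0, step_s: float = 6.0,
                  seed: int = 0, min_voiced_s: float = 0.030,
                  max_voiceless_gap_s: float = 0.020,
                  median_order: int = 5) -> np.ndarray:
    """Per-frame voiced mask via clustering in (PWR, ACR, ZCR)."""
    n = len(track)
    if n == 0:
        return np.zeros(0, dtype=bool)
    step = track.step_s
    pts = np.column_stack([track.pwr, track.acr, track.zcr])
    votes = _Votes(n)
    for a, b in _window_slices(n, int(round(win_s / step)), int(round(step_s / step))):
        idx = np.arange(a, b)
        w = pts[idx]
        degenerate = (track.degenerate is not None
                      and bool(track.degenerate[idx].all()))
        if degenerate or np.ptp(w[:, 0]) < 1e-9 or len(idx) < 2:
            votes.add(idx, np.zeros(len(idx), dtype=bool))
            continue
        _, fit = select_k(w, seed)
        voiced_comp = int(np.argmax(fit.means[:, 0]))  # highest mean PWR
        votes.add(idx, fit.labels == voiced_comp)
    mask = votes.result()
    mask = medfilt(mask.astype(float), kernel_size=median_order) > 0.5
    mask = _suppress_short_runs(mask, True, int(round(min_voiced_s / step)))
    mask = _suppress_short_runs(mask, False, int(round(max_voiceless_gap_s / step)))
    return mask


def _gap_to_voiced(a: int, b: int, voiced_idx: np.ndarray) -> float:
    """Gap in frames between run [a, b) and the nearest voiced frame."""
    if len(voiced_idx) == 0:
        return np.inf
    before = voiced_idx[voiced_idx < a]
    after = voiced_idx[voiced_idx >= b]
    gap = np.inf
    if len(before):
        gap = min(gap, a - before[-1] - 1)
    if len(after):
        gap = min(gap, after[0] - b)
    return gap


def detect_unvoiced(track: FrameTrack, voiced: np.ndarray,
                    win_s: float = 60.0, step_s: float = 20.0, seed: int = 0,
                    max_run_s: float = 0.300, min_unvoiced_s: float = 0.005,
                    max_dist_to_voiced_s: float = 0.030,
                    edge_guard: int = 2) -> np.ndarray:
    """Per-frame unvoiced-consonant mask from voiceless runs < 300 ms.

    Frames within ``edge_guard`` steps of a voiced boundary still carry
    voiced energy inside their 15 ms analysis window and would form a
    spurious loud cluster, so they are excluded from the clustering.
    """
    n = len(track)
    step = track.step_s
    cand = np.zeros(n, dtype=bool)
    for a, b, v in runs_of(~voiced):
        if v and (b - a) * step < max_run_s:
            ga = a + edge_guard if a > 0 else a
            gb = b - edge_guard if b < n else b
            if gb > ga:
                cand[ga:gb] = True
    if track.degenerate is not None:
        cand &= ~track.degenerate
    mask = _vote_loudest(track, cand, win_s, step_s, seed, mode="speech")
    # rejection rules
    voiced_idx = np.flatnonzero(voiced)
    out = mask.copy()
    for a, b, v in runs_of(mask):
        if not v:
            continue
        if (b - a) * step < min_unvoiced_s:
            out[a:b] = False
        elif _gap_to_voiced(a, b, voiced_idx) * step > max_dist_to_voiced_s:
            out[a:b] = False
    return out


def _vote_loudest(track: FrameTrack, cand: np.ndarray, win_s: float,
                  step_s: float, seed: int,
                  mode: str = "loudest") -> np.ndarray:
    """Cluster candidate frames on LFCC_1..5 per recognition window and
    keep the loud fraction, ranked by mean LFCC_1 (loudness).

    ``mode="loudest"`` keeps only the loudest component;
    ``mode="speech"`` keeps every component except the quietest, so a
    3-component fit that splits consonant subtypes (e.g. fricatives vs
    stop bursts) still separates the candidates into the two fractions
    speech vs silence.
    """
    n = len(track)
    step = track.step_s
    votes = _Votes(n)
    for a, b in _window_slices(n, int(round(win_s / step)), int(round(step_s / step))):
        idx = np.flatnonzero(cand[a:b]) + a
        if len(idx) < 10:
            if len(idx):
                votes.add(idx, np.zeros(len(idx), dtype=bool))
            continue
        _, fit = select_k(track.lfcc[idx], seed)
        if mode == "speech":
            quiet = int(np.argmin(fit.means[:, 0]))
            votes.add(idx, fit.labels != quiet)
        else:
            loud = int(np.argmax(fit.means[:, 0]))
            votes.add(idx, fit.labels == loud)
    return votes.result() & cand


def detect_respiration(track: FrameTrack, voiced: np.ndarray,
                       unvoiced: np.ndarray, win_s: float = 60.0,
                       step_s: float = 20.0, seed: int = 0,
                       min_run_s: float = 0.200, min_resp_s: float = 0.040,
                       min_dist_to_voiced_s: float = 0.030,
                       merge_gap_s: float = 0.400):
    """Respiration mask plus the frames reassigned to unvoiced speech.

    Returns ``(respiration_mask, extra_unvoiced_mask)``: respirations
    closer than 30 ms to voiced speech are inspiration-implausible
    (inspirations are bounded by silence) and become unvoiced speech.
    """
    n = len(track)
    step = track.step_s
    residual = ~voiced & ~unvoiced
    cand = np.zeros(n, dtype=bool)
    for a, b, v in runs_of(residual):
        if v and (b - a) * step > min_run_s:
            cand[a:b] = True
    if track.degenerate is not None:
        cand &= ~track.degenerate
    mask = _vote_loudest(track, cand, win_s, step_s, seed)

    extra_unvoiced = np.zeros(n, dtype=bool)
    voiced_idx = np.flatnonzero(voiced)
    out = mask.copy()
    for a, b, v in runs_of(mask):
        if not v:
            continue
        if (b - a) * step < min_resp_s:
            out[a:b] = False
        elif _gap_to_voiced(a, b, voiced_idx) * step < min_dist_to_voiced_s:
            out[a:b] = False
            extra_unvoiced[a:b] = True
    # merge respirations across short, speech-free gaps
    rr = [(a, b) for a, b, v in runs_of(out) if v]
    for (a1, b1), (a2, b2) in zip(rr[:-1], rr[1:]):
        gap = slice(b1, a2)
        if (a2 - b1) * step < merge_gap_s and not voiced[gap].any() \
                and not unvoiced[gap].any():
            out[gap] = True
    return out, extra_unvoiced


def assemble_tiers(voiced: np.ndarray, unvoiced: np.ndarray,
                   respiration: np.ndarray, duration_s: float,
                   step_s: float = 0.005, window_s: float = 0.015,
                   min_pause_s: float = 0.030) -> SegmentTiers:
    """Combine the per-frame masks into a tiling :class:`SegmentTiers`.

    The pause tier is the complement of voiced and unvoiced speech;
    pause runs shorter than 30 ms are absorbed into the temporally
    longer adjacent speech interval.  Respirations are clipped to lie
    within pauses.
    """
    n = len(voiced)
    klass = np.full(n, 2, dtype=int)  # 0 voiced, 1 unvoiced, 2 pause
    klass[unvoiced] = 1
    klass[voiced] = 0
    # absorb sub-minimum pauses into the longer neighbouring speech run
    runs = runs_of(klass)
    min_frames = int(round(min_pause_s / step_s))
    for i, (a, b, v) in enumerate(runs):
        if v != 2 or (b - a) >= min_frames:
            continue
        left = runs[i - 1] if i > 0 else None
        right = runs[i + 1] if i < len(runs) - 1 else None
        target = None
        if left and right:
            target = left if (left[1] - left[0]) >= (right[1] - right[0]) else right
        else:
            target = left or right
        if target is not None:
            klass[a:b] = target[2]

    # frame i's decision refers to its window center (i*step + window/2);
    # run boundaries are placed midway between consecutive frame centers
    # so interval edges are unbiased with respect to the analysis window
    offset = window_s / 2.0 - step_s / 2.0

    def frame_time(i: int) -> float:
        if i <= 0:
            return 0.0
        return round(min(offset + i * step_s, duration_s), 6)

    tiers = SegmentTiers(duration_s=duration_s)
    names = {0: "voiced", 1: "unvoiced", 2: "pause"}
    for a, b, v in runs_of(klass):
        start = frame_time(a)
        end = duration_s if b >= n else frame_time(b)
        tiers.tier(names[int(v)]).append(LabeledInterval(start, end, names[int(v)]))

    min_resp_frames = 8  # 40 ms on the 5 ms grid
    for a, b, v in runs_of(respiration & (klass == 2)):
        if v and (b - a) >= min_resp_frames:
            start = frame_time(a)
            end = min(duration_s, frame_time(b))
            tiers.respiration.append(
                LabeledInterval(start, end, "respiration"))
    return tiers


# ---------------------------------------------------------------------------

class SpeechSegmenter(BaseEstimator):
    """Adaptive four-class segmenter of connected speech.

    A stateless transformer in the scikit-learn idiom: ``transform``
    maps an :class:`AudioBuffer` (any rate >= 8 kHz) to
    :class:`SegmentTiers`.  All duration gates are in seconds.

    Parameters
    ----------
    voiced_win_s, voiced_step_s : recognition window for the voiced stage.
    unvoiced_win_s, unvoiced_step_s : recognition window for the
        unvoiced and respiration stages (longer, to compensate for the
        low occurrence of consonants).
    max_unvoiced_run_s : voiceless runs at least this long are excluded
        from the unvoiced stage (they are respiration candidates).
    min_respiration_run_s : minimum residual-run length entering the
        respiration stage.
    seed : random state for EM initialization (reproducibility).
    """

    def __init__(self, voiced_win_s=20.0, voiced_step_s=6.0,
                 unvoiced_win_s=60.0, unvoiced_step_s=20.0,
                 max_unvoiced_run_s=0.300, min_respiration_run_s=0.200,
                 min_voiced_s=0.030, max_voiceless_gap_s=0.020,
                 min_unvoiced_s=0.005, max_unvoiced_dist_s=0.030,
                 min_respiration_s=0.040, respiration_voiced_dist_s=0.030,
                 respiration_merge_gap_s=0.400, min_pause_s=0.030,
                 median_order=5, seed=0):
        self.voiced_win_s = voiced_win_s
        self.voiced_step_s = voiced_step_s
        self.unvoiced_win_s = unvoiced_win_s
        self.unvoiced_step_s = unvoiced_step_s
        self.max_unvoiced_run_s = max_unvoiced_run_s
        self.min_respiration_run_s = min_respiration_run_s
        self.min_voiced_s = min_voiced_s
        self.max_voiceless_gap_s = max_voiceless_gap_s
        self.min_unvoiced_s = min_unvoiced_s
        self.max_unvoiced_dist_s = max_unvoiced_dist_s
        self.min_respiration_s = min_respiration_s
        self.respiration_voiced_dist_s = respiration_voiced_dist_s
        self.respiration_merge_gap_s = respiration_merge_gap_s
        self.min_pause_s = min_pause_s
        self.median_order = median_order
        self.seed = seed

    def fit(self, X=None, y=None):
        """No-op (the segmenter is unsupervised and stateless)."""
        return self

    def transform(self, audio: AudioBuffer, preprocessed: bool = False) -> SegmentTiers:
        if not preprocessed:
            audio = preprocess(audio)
        track = compute_track(audio)
        duration = audio.duration_s
        if len(track) == 0:
            tiers = SegmentTiers(duration_s=duration)
            tiers.pause.append(LabeledInterval(0.0, duration, "pause"))
            return tiers
        voiced = detect_voiced(track, self.voiced_win_s, self.voiced_step_s,
                               self.seed, self.min_voiced_s,
                               self.max_voiceless_gap_s, self.median_order)
        unvoiced = detect_unvoiced(track, voiced, self.unvoiced_win_s,
                                   self.unvoiced_step_s, self.seed,
                                   self.max_unvoiced_run_s,
                                   self.min_unvoiced_s,
                                   self.max_unvoiced_dist_s)
        resp, extra_unvoiced = detect_respiration(
            track, voiced, unvoiced, self.unvoiced_win_s,
            self.unvoiced_step_s, self.seed, self.min_respiration_run_s,
            self.min_respiration_s, self.respiration_voiced_dist_s,
            self.respiration_merge_gap_s)
        unvoiced = unvoiced | extra_unvoiced
        tiers = assemble_tiers(voiced, unvoiced & ~voiced, resp, duration,
                               track.step_s, track.window_s, self.min_pause_s)
        tiers.validate()
        return tiers


def segment(audio: AudioBuffer, **params) -> SegmentTiers:
    """Segment a recording; thin wrapper over :class:`SpeechSegmenter`."""
    return SpeechSegmenter(**params).transform(audio)
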