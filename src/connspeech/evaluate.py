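"""Detector evaluation against reference labels with tolerance fields.

A detection matches a reference interval when both of its boundaries
lie within the tolerance field around the corresponding reference
boundaries: a quarter of the reference duration for pauses, the full
reference duration for respirations.  Matching is one-to-one (greedy,
closest boundary distance first); unpaired references are false
negatives and unpaired detections false positives, scored by
precision, recall and their harmonic mean F.

Any callable AudioBuffer -> interval list can be scored, so external
baseline detectors can be plugged in without being bundled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

THRESHOLD_GRID_MS = (50, 100, 150, 200, 250, 300)


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    pairs: list = field(default_factory=list)  # (ref, det-or-None)
    degenerate: bool = False  # no detections: precision forced to 0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0


def _check_intervals(ivs, name):
    prev = -np.inf
    for iv in sorted(ivs, key=lambda v: v.start_s):
        if iv.start_s < prev - 1e-9:
            raise ValueError(f"{name} intervals overlap")
        prev = iv.end_s


def _match(reference, detected, tol_of) -> MatchReport:
    """Greedy one-to-one matching, closest boundary distance first."""
    _check_intervals(reference, "reference")
    # detections are not required to be disjoint: plugin detectors may
    # emit duplicates, which the one-to-one rule scores as extra FPs
    cands = []
    for i, ref in enumerate(reference):
        tol = tol_of(ref)
        for j, det in enumerate(detected):
            ds = abs(det.start_s - ref.start_s)
            de = abs(det.end_s - ref.end_s)
            if ds <= tol and de <= tol:
                cands.append((ds + de, i, j))
    cands.sort()
    used_ref, used_det = set(), set()
    pairs = {}
    for _, i, j in cands:
        if i in used_ref or j in used_det:
            continue
        used_ref.add(i)
        used_det.add(j)
        pairs[i] = j
    tp = len(pairs)
    fn = len(reference) - tp
    fp = len(detected) - tp
    pair_list = [(ref, detected[pairs[i]] if i in pairs else None)
                 for i, ref in enumerate(reference)]
    return MatchReport(tp, fp, fn, pair_list,
                       degenerate=(len(detected) == 0))


def match_pauses(reference, detected) -> MatchReport:
    """Match with tolerance +/- d/4 around each reference pause boundary."""
    return _match(reference, detected, lambda ref: ref.duration_s / 4.0)


def match_respirations(reference, detected) -> MatchReport:
    """Match with tolerance +/- d (full duration) around each boundary."""
    return _match(reference, detected, lambda ref: ref.duration_s)


@dataclass
class EfficiencyCurve:
    thresholds_ms: tuple
    f_mean: np.ndarray
    f_sd: np.ndarray

    def as_dict(self) -> dict:
        return {int(t): float(m) for t, m in zip(self.thresholds_ms, self.f_mean)}


def efficiency_curve(ref_det_pairs, thresholds_ms=THRESHOLD_GRID_MS,
                     matcher=match_pauses) -> EfficiencyCurve:
    """Mean +/- SD F across recordings, stratified by reference duration.

    ``ref_det_pairs`` is a list of (reference intervals, detected
    intervals) per recording.  For each progressive threshold,
    reference intervals shorter than the threshold are dropped together
    with the detections matched only to them, and F is recomputed.
    """
    if not ref_det_pairs:
        raise ValueError("need at least one recording")
    f_mat = np.zeros((len(ref_det_pairs), len(thresholds_ms)))
    for r, (refs, dets) in enumerate(ref_det_pairs):
        full = matcher(refs, dets)
        matched_to = {}  # detection id -> its matched reference
        for ref, det in full.pairs:
            if det is not None:
                matched_to[id(det)] = ref
        for c, thr in enumerate(thresholds_ms):
            thr_s = thr / 1000.0
            keep_refs = [iv for iv in refs if iv.duration_s >= thr_s]
            keep_dets = [d for d in dets
                         if id(d) not in matched_to
                         or matched_to[id(d)].duration_s >= thr_s]
            f_mat[r, c] = matcher(keep_refs, keep_dets).f
    return EfficiencyCurve(tuple(thresholds_ms), f_mat.mean(axis=0),
                           f_mat.std(axis=0))


def score_detector(detector, recordings, matcher=match_pauses,
                   tier: str = "pause") -> EfficiencyCurve:
    """Score any detector callable on (audio, reference tiers) pairs."""
    pairs = []
    for audio, ref_tiers in recordings:
        detected = detector(audio)
        pairs.append((ref_tiers.tier(tier), list(detected)))
    return efficiency_curve(pairs, matcher=matcher)
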