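import numpy as np
import pytest

import connspeech as cs
from connspeech.classify import SubjectRecord
from connspeech.features import FEATURE_NAMES, FeatureExtractor
from connspeech.intervals import LabeledInterval, SegmentTiers


@pytest.fixture(scope="session")
def clean_recording():
    """One 20 s control-preset recording with ground truth."""
    spec = cs.make_spec("control", seed=42, duration_s=20)
    audio, tiers = cs.generate_recording(spec)
    return audio, tiers


@pytest.fixture(scope="session")
def segmented_recording(clean_recording):
    audio, tiers = clean_recording
    pre = cs.preprocess(audio)
    detected = cs.SpeechSegmenter().transform(pre, preprocessed=True)
    return pre, tiers, detected


def make_tiers(pattern, duration=None):
    """Build SegmentTiers from (start, end, klass) triples."""
    tiers = SegmentTiers()
    end = 0.0
    for s, e, k in pattern:
        tiers.tier(k).append(LabeledInterval(s, e, k))
        end = max(end, e)
    tiers.duration_s = duration if duration is not None else end
    return tiers


def cohort_records(seed, n_per_group=30, heldout=False):
    """Subject records with features computed from ground-truth tiers."""
    if heldout:
        presets = {"heldpos": cs.make_spec("pd_like"),
                   "heldneg": cs.make_spec("control")}
        updrs = {"heldpos": (4, 20), "heldneg": (0, 3)}
    else:
        presets = {"control": cs.make_spec("control"),
                   "PD": cs.make_spec("pd_like")}
        updrs = None
    entries = cs.generate_cohort(n_per_group, presets, seed=seed,
                                 render_audio=False, updrs_by_group=updrs)
    fx = FeatureExtractor()
    by = {}
    for e in entries:
        fs = fx.transform(e.tiers).as_dict()
        group = "heldout" if heldout else e.group
        rec = by.setdefault(e.subject_id,
                            SubjectRecord(e.subject_id, group, {},
                                          e.updrs3_star))
        for k in FEATURE_NAMES:
            rec.features[f"{k}:{e.task}"] = fs[k]
    return list(by.values())
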