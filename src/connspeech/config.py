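"""Run configuration, serialization and provenance stamping.

Every numeric gate of the segmenter and feature extractor lives in a
flat :class:`RunConfig`; the defaults are the method's published
constants.  The config (and its hash) is embedded in every output
artifact so a run can be audited and a resume with a different config
refuses to overwrite.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml


@dataclass
class RunConfig:
    # preprocessing
    target_rate: int = 8000
    hp_order: int = 4
    hp_cutoff_hz: float = 130.0
    hp_ripple_db: float = 0.5
    # parameterization
    window_s: float = 0.015
    step_s: float = 0.005
    n_lfcc_filters: int = 24
    n_lfcc_keep: int = 5
    n_mfcc: int = 24
    # segmenter recognition windows and gates
    voiced_win_s: float = 20.0
    voiced_step_s: float = 6.0
    unvoiced_win_s: float = 60.0
    unvoiced_step_s: float = 20.0
    max_unvoiced_run_s: float = 0.300
    min_respiration_run_s: float = 0.200
    min_voiced_s: float = 0.030
    max_voiceless_gap_s: float = 0.020
    min_unvoiced_s: float = 0.005
    max_unvoiced_dist_s: float = 0.030
    min_respiration_s: float = 0.040
    respiration_voiced_dist_s: float = 0.030
    respiration_merge_gap_s: float = 0.400
    min_pause_s: float = 0.030
    median_order: int = 5
    # features
    pause_saturation_s: float = 2.0
    # reproducibility
    seed: int = 0

    def segmenter_params(self) -> dict:
        keys = ("voiced_win_s", "voiced_step_s", "unvoiced_win_s",
                "unvoiced_step_s", "max_unvoiced_run_s",
                "min_respiration_run_s", "min_voiced_s",
                "max_voiceless_gap_s", "min_unvoiced_s",
                "max_unvoiced_dist_s", "min_respiration_s",
                "respiration_voiced_dist_s", "respiration_merge_gap_s",
                "min_pause_s", "median_order", "seed")
        d = asdict(self)
        return {k: d[k] for k in keys}

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
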