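"""Pipeline configuration: every threshold defaults to the study protocol
(16-35 nt window, mean Q >= 30, Ct <= 32 in >= 20% of samples, detection in
>= 2 samples, p < 0.05, |FC| >= 1.5, BLAST coverage > 0.85).

Loaded from a flat YAML file; unknown keys are rejected by name.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .synth import DEFAULT_ADAPTER3, DEFAULT_ADAPTER5


@dataclass
class PipelineConfig:
    # preprocessing
    min_len: int = 16
    max_len: int = 35
    min_mean_q: float = 30.0
    adapter3: str = DEFAULT_ADAPTER3
    adapter5: str = DEFAULT_ADAPTER5
    min_overlap: int = 6
    max_mismatch_rate: float = 0.1
    # cascade
    tier_order: tuple[str, ...] = ("rat", "mouse", "human")
    # quantification / DE
    normalization: str = "tmm"
    de_method: str = "welch_log"
    min_detected_samples: int = 2
    p_threshold: float = 0.05
    fc_threshold: float = 1.5
    coverage_threshold: float = 0.85
    # qPCR
    max_ct: float = 32.0
    ct_min_fraction: float = 0.20
    ct_normalization: str = "global_mean"
    lowess_span: float = 0.5
    invariant_k: int = 10
    # simulation
    n_reads: int = 20000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        if "tier_order" in raw:
            raw["tier_order"] = tuple(raw["tier_order"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["tier_order"] = list(d["tier_order"])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
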