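"""Run configuration: one validated object drives the whole pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    """All pipeline switches in one place.

    Unknown keys in a config file are rejected up front; the canonical
    JSON serialization is hashed into the run manifest so a run can be
    re-executed identically.
    """

    out_dir: str = "run"
    seed: int = 0
    # synthetic cohort
    n_patients: int = 1003
    n_clusters: int = 11
    min_separation: float = 6.0
    # study-sample accounting planted into the synthetic enrollment manifest
    n_no_mri: int = 19
    n_missing_sequences: int = 239
    n_artefacts: int = 48
    # clustering
    k_range: tuple[int, int] = (2, 20)
    force_k: int | None = None
    # shape / classification switches
    lesion_class_rule: str = "any"  # 'any' or 'majority'
    # statistics
    covariates: tuple[str, ...] = ("age", "sex")
    reference_subgroups: tuple[int, ...] | None = None  # None -> (1,2,3,7) at k=11
    tie_handling: str = "efron"
    normality_overrides: dict = field(default_factory=dict)
    # phantom demo stage (small head phantom through volumetrics + shape)
    phantom_demo: bool = True

    def __post_init__(self) -> None:
        if self.lesion_class_rule not in ("any", "majority"):
            raise ValueError(f"unknown lesion_class_rule {self.lesion_class_rule!r}")
        if self.tie_handling != "efron":
            raise ValueError(f"unsupported tie_handling {self.tie_handling!r}")
        self.k_range = tuple(int(k) for k in self.k_range)
        if len(self.k_range) != 2:
            raise ValueError("k_range must be (low, high)")
        if self.reference_subgroups is not None:
            self.reference_subgroups = tuple(int(g) for g in self.reference_subgroups)
        self.covariates = tuple(self.covariates)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(d) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
        return cls.from_dict(data)

    def resolved_reference(self) -> tuple[int, ...]:
        if self.reference_subgroups is not None:
            return self.reference_subgroups
        return (1, 2, 3, 7) if self.n_clusters == 11 else (1,)

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:16]
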