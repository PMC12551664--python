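"""Run configuration: documented defaults for every pipeline knob."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import yaml


@dataclass
class RunConfig:
    """Resolved settings for a classification run.

    ``fixed_k`` pins the cluster count per stage (key ``"tier1"`` or a
    region name); a missing / ``None`` entry means choose k by
    validity-index voting.  ``indices`` of ``None`` selects the default
    closed-form index set.  ``subgroup_names`` maps automatic subgroup
    labels to preferred names per region; ``label_overrides`` forces a
    subgroup for specific sites (applied last).
    """

    # input CSVs (None = synthetic)
    sites_csv: str | None = None
    surveys_csv: str | None = None
    chemistry_csv: str | None = None
    stressors_csv: str | None = None

    seed: int = 0
    restarts: int = 25
    k_range: tuple = (2, 15)
    indices: list | None = None
    parsimony_margin: int = 1
    fixed_k: dict = field(default_factory=lambda: {"tier1": 2})
    tree: dict = field(
        default_factory=lambda: {"min_split": 20, "min_bucket": 7, "complexity": 0.01}
    )
    n_permutations: int = 999
    span_threshold: float = 0.5
    span_axes: int = 2
    subgroup_names: dict = field(default_factory=dict)
    label_overrides: dict = field(default_factory=dict)
    # synthetic generator overrides (passed to SyntheticConfig)
    synthetic: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["k_range"] = list(self.k_range)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:8]

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        bad = sorted(set(raw) - known)
        if bad:
            raise KeyError(f"unknown config keys: {bad}")
        if "k_range" in raw:
            raw = dict(raw)
            raw["k_range"] = tuple(raw["k_range"])
        return cls(**raw)

    def dump_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
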