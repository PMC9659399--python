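"""Run configuration and deterministic seed derivation.

Every stochastic stage receives its own child seed derived from the global
seed and a stable stage label, so adding a stage never perturbs the
randomness of existing stages.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .ga_engine import GAConfig
from .observers import CohortSpec


def derive_seed(global_seed: int, label: str) -> int:
    """Child seed for a named operation, stable across runs and platforms."""
    key = zlib.crc32(label.encode("utf-8"))
    ss = np.random.SeedSequence(entropy=int(global_seed), spawn_key=(key,))
    return int(ss.generate_state(1)[0] % (2**31))


def rng_for(global_seed: int, label: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, label))


@dataclass
class AnalysisConfig:
    n_iter: int = 500  # noise-threshold simulation iterations per emotion
    n_perm: int = 10_000  # permutation iterations
    n_bins: int = 4
    pcs: int = 10
    k_clusters: int = 4
    svm_folds: int = 5
    recognition_temperature: float = 0.05
    n_perceivers: int = 12


@dataclass
class RunConfig:
    seed: int = 0
    ga: GAConfig = field(default_factory=GAConfig)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    out_dir: str = "evoface_out"

    def to_dict(self) -> dict:
        d = asdict(self)
        # category means are data, not config; persist only their presence
        if d["cohort"].get("category_means") is not None:
            d["cohort"]["category_means"] = "custom"
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        ga = GAConfig(**data.pop("ga", {}))
        cohort_kw = dict(data.pop("cohort", {}))
        cohort_kw.pop("category_means", None)
        cohort = CohortSpec(**cohort_kw)
        analysis = AnalysisConfig(**data.pop("analysis", {}))
        return cls(ga=ga, cohort=cohort, analysis=analysis, **data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        """Digest of the scientific configuration (output paths excluded)."""
        payload = self.to_dict()
        payload.pop("out_dir", None)
        canonical = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]
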