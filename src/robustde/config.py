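"""Run configuration: every tunable of the pipeline in one record.

Round-trips losslessly through YAML so a benchmark is reproducible from
its config file plus a seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, fields

import yaml

from .evaluate import BenchmarkConfig
from .simulate import (DEFAULT_FC_CONFIG, DEFAULT_MAGNITUDE_CONFIG,
                       DEFAULT_NB_CONFIG)

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """All pipeline tunables with their documented defaults."""

    beta: float = 0.2
    alpha: float = 0.05
    fc_threshold: float = 1.5          # on the log2 scale
    pseudocount: float = 1.0
    tol: float = 1e-6
    max_iter: int = 100
    G: int = 1000
    n_de: int = 100
    n1: int = 3
    n2: int = 3
    nb_config: dict = field(default_factory=lambda: dict(DEFAULT_NB_CONFIG))
    fc_config: dict = field(default_factory=lambda: dict(DEFAULT_FC_CONFIG))
    magnitude_config: dict = field(
        default_factory=lambda: dict(DEFAULT_MAGNITUDE_CONFIG))
    outlier_levels: list = field(
        default_factory=lambda: [0.0, 0.05, 0.10, 0.15, 0.20])
    n_replicates: int = 50
    pauc_fpr_max: float = 0.1
    methods: list = field(default_factory=lambda: ["robust_t", "classical_t"])
    seed: int = 0

    def to_yaml(self, path=None):
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source):
        """Load from a YAML string or file path."""
        try:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        except (OSError, TypeError):
            data = yaml.safe_load(source)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self):
        """Short stable digest of the canonical YAML form."""
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def benchmark_config(self):
        return BenchmarkConfig(
            G=self.G, n_de=self.n_de, n1=self.n1, n2=self.n2,
            nb_config=self.nb_config, fc_config=self.fc_config,
            magnitude_config=self.magnitude_config,
            outlier_levels=tuple(self.outlier_levels),
            n_replicates=self.n_replicates, alpha=self.alpha,
            beta=self.beta, pauc_fpr_max=self.pauc_fpr_max,
            methods=tuple(self.methods), seed=self.seed,
        )
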