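"""Cascade configuration: one dataclass, YAML-loadable, with the defaults
used throughout the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import yaml

from .features import FEATURE_TYPES
from .topology import TopologyConfig


@dataclass(frozen=True)
class CascadeConfig:
    # feature extraction
    feature_types: tuple[str, ...] = FEATURE_TYPES
    # dataset construction
    n_negative_splits: int = 3
    n_subfamily_subsets: int = 10
    per_class_cap: int = 500
    redundancy_filter: bool = False
    redundancy_threshold: float = 0.85
    scheme_min_members: int = 20
    smote_k: int = 5
    # member training / evaluation
    algorithms: tuple[str, ...] = ("lda", "knn")
    selection_folds: int = 3
    crossval_folds: int = 10
    metrics_average: str = "macro"
    # topology heuristics
    topology: TopologyConfig = field(default_factory=TopologyConfig)
    # Bayesian combination
    bayes_alpha0: float = 1.0
    bayes_beta0: float = 1.0
    dirichlet_alpha0: float = 1.0
    # decision rule
    cutoff_c1: float = 0.6
    cutoff_c2: float = 0.6
    cutoff_c3: float = 0.7
    decision_weights: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)
    decision_prior: tuple[float, float] = (0.5, 0.5)

    @property
    def cutoffs(self) -> dict:
        return {"c1": self.cutoff_c1, "c2": self.cutoff_c2, "c3": self.cutoff_c3}


_TOPOLOGY_KEYS = {"window", "threshold", "min_tm_len", "merge_gap"}


def load_config(path: Optional[str] = None, **overrides) -> CascadeConfig:
    """Build a config from an optional YAML file plus keyword overrides.

    The YAML may be flat (keys matching the dataclass fields) or grouped
    under ``topology:``, ``bayes:``, ``decision:`` and ``train:`` blocks.
    """
    config = CascadeConfig()
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat: dict = {}
        topo: dict = {}
        for key, value in raw.items():
            if key == "topology" and isinstance(value, dict):
                topo.update(value)
            elif key in ("bayes", "decision", "train") and isinstance(value, dict):
                prefix = {"bayes": "bayes_", "decision": "", "train": ""}[key]
                for k, v in value.items():
                    name = k if k.startswith(prefix) else prefix + k
                    if key == "decision" and k in ("c1", "c2", "c3"):
                        name = f"cutoff_{k}"
                    if key == "decision" and k in ("weights", "prior"):
                        name = f"decision_{k}"
                    flat[name] = v
            else:
                flat[key] = value
        for seq_key in ("feature_types", "algorithms", "decision_weights",
                        "decision_prior"):
            if seq_key in flat and isinstance(flat[seq_key], Sequence):
                flat[seq_key] = tuple(flat[seq_key])
        if topo:
            flat["topology"] = TopologyConfig(
                **{k: v for k, v in topo.items() if k in _TOPOLOGY_KEYS}
            )
        config = replace(config, **flat)
    if overrides:
        config = replace(config, **overrides)
    return config
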