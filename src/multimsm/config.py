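"""Run configuration: YAML loading, validation, and defaults.

A config names one of the built-in systems and carries the parameter blocks
of the modules it touches.  Unknown keys are rejected by name; a missing
seed is filled with the documented default (0) and logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field

import yaml

from .adaptive import AdaptivePolicy, ExploreParams
from .discretize import DiscretizerParams
from .simulate import BDParams, NestedChainSpec, PotentialSpec
from .update import CommunityParams

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "load_config"]

_SYSTEMS = ("two_spheres", "nested_chain", "external_stream", "custom_simulator")

_KNOWN_KEYS = {
    "system", "seed", "output_dir", "kappa", "tau0", "diameter",
    "max_representatives", "explore", "community", "bd", "potential",
    "chain", "stream",
}
_BLOCK_KEYS = {
    "explore": {"tmax", "ninit", "k", "m", "adaptive_rate", "seed"},
    "community": {"resolution", "min_update_frames", "overlap_match_threshold"},
    "bd": {"temperature", "dt", "stokes_radius", "seed"},
    "potential": {"domain", "tilt", "scales", "wall_k", "barrier_anchor"},
    "chain": {"tiers"},
    "stream": {"path", "chunk_frames", "stride"},
}


@dataclass
class RunConfig:
    system: str = "two_spheres"
    seed: int = 0
    output_dir: str = "."
    kappa: int = 2
    tau0: float = 0.03
    diameter: float = 0.05
    max_representatives: int = 10
    explore: dict = field(default_factory=dict)
    community: dict = field(default_factory=dict)
    bd: dict = field(default_factory=dict)
    potential: dict = field(default_factory=dict)
    chain: dict = field(default_factory=dict)
    stream: dict = field(default_factory=dict)

    def discretizer_params(self) -> DiscretizerParams:
        return DiscretizerParams(diameter=self.diameter,
                                 max_representatives=self.max_representatives)

    def community_params(self) -> CommunityParams:
        return CommunityParams(**self.community)

    def explore_params(self) -> ExploreParams:
        kw = dict(self.explore)
        kw.setdefault("seed", self.seed)
        return ExploreParams(**kw)

    def bd_params(self) -> BDParams:
        kw = dict(self.bd)
        kw.setdefault("seed", self.seed)
        return BDParams(**kw)

    def potential_spec(self) -> PotentialSpec:
        kw = dict(self.potential)
        if "domain" in kw:
            kw["domain"] = tuple(kw["domain"])
        if "scales" in kw:
            kw["scales"] = tuple(tuple(s) for s in kw["scales"])
        return PotentialSpec(**kw)

    def chain_spec(self) -> NestedChainSpec:
        return NestedChainSpec(tiers=tuple(tuple(t) for t in self.chain["tiers"]))

    def digest(self) -> str:
        """Stable hash of the full config, recorded for exact replay."""
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    unknown = sorted(set(raw) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys: {', '.join(unknown)}")
    for block, allowed in _BLOCK_KEYS.items():
        sub = raw.get(block) or {}
        bad = sorted(set(sub) - allowed)
        if bad:
            raise ValueError(
                f"{path}: unknown keys under '{block}': {', '.join(bad)}")
    system = raw.get("system", "two_spheres")
    if system not in _SYSTEMS:
        raise ValueError(f"{path}: unknown system {system!r}; expected one of {_SYSTEMS}")
    if "seed" not in raw:
        logger.info("no seed given; using documented default 0")
    cfg = RunConfig(**{k: v for k, v in raw.items()})
    # validate eagerly so schema errors surface at load time with key paths
    cfg.discretizer_params()
    cfg.community_params()
    if cfg.system == "two_spheres":
        cfg.bd_params()
        if cfg.potential:
            cfg.potential_spec()
    if cfg.system == "nested_chain" and cfg.chain:
        cfg.chain_spec()
    return cfg
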