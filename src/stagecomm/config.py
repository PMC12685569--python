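"""Configuration schema (YAML/JSON) and run manifests.

A config file describes either an unstructured community::

    kind: community
    S: 200
    C: 1.0
    d: 1.0
    type: random            # interaction type
    sigma: 0.05             # or gamma
    distribution: normal_signed
    seed: 1

or a structured one (K = 2 block aliases M1..M4 are accepted alongside
explicit "r,c" keys)::

    kind: structured
    S: 200
    K: 2
    C: 1.0
    d: 1.0
    seed: 1
    blocks:
      M1: {type: random, gamma: 1.2}
      M2: {type: predation, gamma: 0.5}
      M3: {type: predation, gamma: 0.5}
      M4: {type: random, gamma: 0.0}

Every run of the command-line layer writes a JSON manifest holding the fully
resolved config, the seed and the output inventory; re-running a command from
a manifest reproduces the outputs byte-for-byte.
"""

from __future__ import annotations

import datetime
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .assembly import BlockSpec, StructuredConfig
from .errors import ConfigurationError
from .random_community import (
    CommunityConfig,
    InteractionType,
    MagnitudeDistribution,
)

__all__ = ["load_config", "config_from_dict", "config_to_dict",
           "RunManifest", "read_manifest"]

_BLOCK_ALIASES = {"M1": (1, 1), "M2": (1, 2), "M3": (2, 1), "M4": (2, 2)}


def _require(mapping: Mapping[str, Any], key: str, path: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"{path}{key}: missing required field")
    return mapping[key]


def _block_from_dict(rc: tuple[int, int], data: Mapping[str, Any],
                     path: str) -> BlockSpec:
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"{path}: expected a mapping")
    known = {"type", "sigma", "gamma", "family"}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown fields {sorted(unknown)}")
    return BlockSpec(
        row_block=rc[0], col_block=rc[1],
        interaction_type=data.get("type", "random"),
        sigma=data.get("sigma"), gamma=data.get("gamma"),
        family=data.get("family"),
    )


def config_from_dict(data: Mapping[str, Any]
                     ) -> CommunityConfig | StructuredConfig:
    """Build a validated config object from a plain mapping; schema errors
    are reported with field paths."""
    if not isinstance(data, Mapping):
        raise ConfigurationError("config: expected a mapping at top level")
    kind = data.get("kind", "community")
    if kind == "community":
        dist = MagnitudeDistribution(
            family=data.get("distribution", "normal_signed"),
            sigma=float(data.get("sigma", 0.0)))
        if "gamma" in data:
            from .assembly import gamma_to_sigma
            if "sigma" in data:
                raise ConfigurationError(
                    "config: give exactly one of sigma / gamma")
            sigma = gamma_to_sigma(float(data["gamma"]), int(_require(data, "S", "")),
                                   float(_require(data, "C", "")),
                                   data.get("type", "random"))
            dist = MagnitudeDistribution(
                family=data.get("distribution", "normal_signed"), sigma=sigma)
        return CommunityConfig(
            S=int(_require(data, "S", "")),
            C=float(_require(data, "C", "")),
            d=float(data.get("d", 1.0)),
            interaction_type=data.get("type", "random"),
            distribution=dist,
            seed=int(data.get("seed", 0)),
        )
    if kind == "structured":
        K = int(data.get("K", 2))
        raw_blocks = _require(data, "blocks", "")
        if not isinstance(raw_blocks, Mapping):
            raise ConfigurationError("blocks: expected a mapping")
        blocks: dict[tuple[int, int], BlockSpec] = {}
        for key, value in raw_blocks.items():
            if key in _BLOCK_ALIASES:
                if K != 2:
                    raise ConfigurationError(
                        f"blocks.{key}: M1..M4 aliases require K = 2")
                rc = _BLOCK_ALIASES[key]
            else:
                try:
                    r, c = (int(x) for x in str(key).split(","))
                    rc = (r, c)
                except ValueError:
                    raise ConfigurationError(
                        f"blocks.{key}: expected 'r,c' or an M1..M4 alias"
                    ) from None
            blocks[rc] = _block_from_dict(rc, value, f"blocks.{key}")
        stage_counts = data.get("stage_counts")
        return StructuredConfig(
            S=int(_require(data, "S", "")),
            K=K,
            C=float(_require(data, "C", "")),
            d=float(data.get("d", 1.0)),
            blocks=blocks,
            seed=int(data.get("seed", 0)),
            stage_counts=None if stage_counts is None else tuple(stage_counts),
        )
    raise ConfigurationError(
        f"kind: expected 'community' or 'structured', got {kind!r}")


def load_config(path) -> CommunityConfig | StructuredConfig:
    """Load a YAML or JSON config file (JSON is a YAML subset)."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"{path}: cannot parse ({exc})") from exc
    return config_from_dict(data)


def config_to_dict(config: CommunityConfig | StructuredConfig) -> dict:
    """Serialisable dict representation (round-trips through
    :func:`config_from_dict`)."""
    if isinstance(config, CommunityConfig):
        return {
            "kind": "community",
            "S": config.S, "C": config.C, "d": config.d,
            "type": config.interaction_type.value,
            "distribution": config.distribution.family,
            "sigma": config.distribution.sigma,
            "seed": config.seed,
        }
    if isinstance(config, StructuredConfig):
        blocks = {}
        for (r, c), spec in sorted(config.blocks.items()):
            entry: dict[str, Any] = {"type": spec.interaction_type.value}
            if spec.sigma is not None:
                entry["sigma"] = spec.sigma
            else:
                entry["gamma"] = spec.gamma
            if spec.family is not None:
                entry["family"] = spec.family
            blocks[f"{r},{c}"] = entry
        out: dict[str, Any] = {
            "kind": "structured",
            "S": config.S, "K": config.K, "C": config.C, "d": config.d,
            "blocks": blocks, "seed": config.seed,
        }
        if config.stage_counts is not None:
            out["stage_counts"] = list(config.stage_counts)
        return out
    raise ConfigurationError(f"cannot serialise {type(config).__name__}")


@dataclass
class RunManifest:
    """Record of one command-line run, sufficient to reproduce it."""

    command: str
    resolved_config: dict | None
    seed: int
    options: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.datetime.now(
            datetime.timezone.utc).isoformat())

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def read_manifest(path) -> RunManifest:
    data = json.loads(Path(path).read_text())
    return RunManifest(**data)
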