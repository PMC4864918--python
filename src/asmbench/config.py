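"""Seed derivation, config hashing and YAML round-tripping.

Every stochastic stage receives a seed derived deterministically from the
master seed and the stage's key, so replicates are independent draws yet
the whole run is reproducible from one integer.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["derive_seed", "config_hash", "load_yaml", "dump_yaml", "provenance_header"]

TOOL_VERSION = "0.1.0"


def derive_seed(master: int, *parts: object) -> int:
    """Deterministic 31-bit seed from the master seed and a stage key."""
    payload = repr((int(master),) + tuple(parts)).encode()
    h = hashlib.blake2b(payload, digest_size=4).digest()
    return int.from_bytes(h, "big") & 0x7FFFFFFF


def config_hash(config: Mapping[str, Any] | Any) -> str:
    """Short stable hash of a config mapping (or object with to_dict())."""
    if hasattr(config, "to_dict"):
        config = config.to_dict()
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:12]


def load_yaml(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data


def dump_yaml(data: Mapping[str, Any], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(data), fh, sort_keys=True)


def provenance_header(cfg_hash: str, master_seed: int) -> list[str]:
    """Commented header lines for report outputs."""
    return [
        f"# asmbench v{TOOL_VERSION}",
        f"# config_hash={cfg_hash}",
        f"# master_seed={master_seed}",
    ]
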