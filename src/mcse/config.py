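"""Run configuration and logging setup shared by the CLI subcommands."""

from __future__ import annotations

import hashlib
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .hierarchy import DEFAULT_LAMBDA_LADDER
from .weighting import DEFAULT_ALPHA

__all__ = ["RunConfig", "load_config", "setup_logging", "file_checksum"]


@dataclass
class RunConfig:
    """All tunables of one detection run, with the package defaults."""

    alpha: float = DEFAULT_ALPHA
    lambda_th: float = 0.5
    lambdas: tuple[float, ...] = DEFAULT_LAMBDA_LADDER
    seed_strategy: str = "union"
    rng_seed: int | None = None
    unweighted_expansion: bool = False
    link_threshold: float = 0.5
    network: str | None = None
    essential: str | None = None
    weighted_input: bool = False
    extras: dict = field(default_factory=dict)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file mirroring the CLI flags (keys use underscores)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return {k.replace("-", "_"): v for k, v in data.items()}


def setup_logging(level: str = "info") -> None:
    """Route package logs to stderr at the requested level."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(levelname)s %(name)s: %(message)s",
        force=True,
    )


def file_checksum(path: str | Path) -> str:
    """Short SHA-256 of an input file, for provenance headers."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:12]
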