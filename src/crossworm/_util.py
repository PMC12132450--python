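"""Shared plumbing: seeding, logging, small validation helpers."""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger("crossworm")


def rng_for(seed: int | None, *key: int) -> np.random.Generator:
    """Return a Generator for a (root seed, stream key) pair.

    Streams are derived with ``SeedSequence(seed, spawn_key=key)``, so the
    i-th lineage (or replicate) of a run always sees the same stream
    regardless of execution order: a documented counter scheme rather than
    sequential state sharing.
    """
    if seed is None:
        return np.random.default_rng()
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=tuple(int(k) for k in key)))


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(level=getattr(logging, level.upper(), logging.INFO),
                        format="%(levelname)s %(name)s: %(message)s")


class FormatError(ValueError):
    """A file does not conform to the expected tabular/sequence format."""


class ConfigError(ValueError):
    """An option combination or configuration value is invalid."""
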