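"""Shared helpers: error types and deterministic seed derivation."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["ConfigurationError", "ZeroNormError", "derive_rng", "derive_seed"]


class ConfigurationError(ValueError):
    """Raised when a simulation or benchmark parameter is invalid."""


class ZeroNormError(ValueError):
    """Raised when a template with zero norm enters a similarity computation."""


def _stream_key(stream: tuple) -> tuple[int, ...]:
    # Strings are hashed with crc32 so that stream names give stable,
    # platform-independent spawn keys.
    key = []
    for item in stream:
        if isinstance(item, str):
            key.append(zlib.crc32(item.encode("utf-8")))
        else:
            key.append(int(item) & 0xFFFFFFFF)
    return tuple(key)


def derive_rng(master_seed: int, *stream) -> np.random.Generator:
    """Return an independent Generator for a named sub-stream of ``master_seed``.

    The same (master_seed, stream) pair always yields the same stream, and
    distinct stream identifiers yield statistically independent streams.
    """
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_stream_key(stream))
    return np.random.default_rng(ss)


def derive_seed(master_seed: int, *stream) -> int:
    """Derive a 31-bit integer child seed from a master seed and stream id."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=_stream_key(stream))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
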