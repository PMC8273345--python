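"""Shared helpers: deterministic seeding, config hashing, output headers."""

from __future__ import annotations

import hashlib
import json
import zlib
from typing import Any, Mapping

import numpy as np

__version__ = "0.1.0"


def child_rng(master_seed: int, key: str) -> np.random.Generator:
    """Return a generator seeded from a master seed plus a stable string key.

    Keyed on the string (via CRC32) rather than on positional index so the
    same sample gets the same stream regardless of column order.
    """
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(key.encode())]))


def config_hash(params: Mapping[str, Any]) -> str:
    """Short stable hash of a parameter mapping, for output provenance headers."""

    def _norm(v: Any) -> Any:
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating,)):
            return float(v)
        if isinstance(v, Mapping):
            return {str(k): _norm(x) for k, x in sorted(v.items())}
        if isinstance(v, (list, tuple)):
            return [_norm(x) for x in v]
        return v

    blob = json.dumps(_norm(dict(params)), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def output_header(cfg_hash: str = "na") -> str:
    return f"# aortax {__version__} config={cfg_hash}"
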