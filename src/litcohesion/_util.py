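"""Small shared helpers: seeded RNG streams, hashing, sorting."""

from __future__ import annotations

import hashlib
import json
import math
import zlib

import numpy as np


def _label_code(label: str) -> int:
    return zlib.crc32(label.encode("utf-8"))


def seed_sequence(master: int, label: str) -> np.random.SeedSequence:
    """Deterministic per-stage seed stream derived from a master seed and a label."""
    return np.random.SeedSequence([int(master), _label_code(label)])


def rng_for(master: int, label: str) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(master, label))


def derive_seed(master: int, label: str) -> int:
    """A plain integer sub-seed, for APIs that take an int rather than a Generator."""
    return int(seed_sequence(master, label).generate_state(1, np.uint32)[0])


def stable_digest(obj) -> str:
    """SHA-1 of a JSON-serialized object; used to tie artifacts to their config."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode("utf-8")
    return hashlib.sha1(payload).hexdigest()


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 going up (2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def natural_key(s: str):
    """Sort numeric identifiers numerically, everything else lexicographically."""
    return (0, int(s), "") if s.isdigit() else (1, 0, s)
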