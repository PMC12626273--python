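"""Deterministic random-stream derivation.

Substreams are keyed by a stable hash of a string label so that results do
not depend on the order in which genes or groups happen to be stored.
"""

from __future__ import annotations

import hashlib

import numpy as np


def substream(master_seed: int, label: str) -> np.random.Generator:
    """A generator keyed by (master_seed, label), independent of ordering."""
    digest = hashlib.blake2b(label.encode("utf-8"), digest_size=8).digest()
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key]))
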