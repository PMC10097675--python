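"""Deterministic hierarchical seeding.

Every random draw in the pipeline is made from a generator obtained via
:func:`derive_rng`, keyed by the master seed plus a tuple of stable tokens
(stage name, pair index, trial index, ...).  Any sub-computation can thus be
reproduced in isolation without replaying the whole run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["derive_rng", "derive_seed_sequence"]


def _token_to_int(token) -> int:
    if isinstance(token, (int, np.integer)):
        return int(token) & 0xFFFFFFFFFFFFFFFF
    digest = hashlib.sha256(str(token).encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "little")


def derive_seed_sequence(master_seed: int, *key) -> np.random.SeedSequence:
    """Seed sequence for the sub-stream identified by ``key``."""
    entropy = [int(master_seed) & 0xFFFFFFFFFFFFFFFF] + [_token_to_int(t) for t in key]
    return np.random.SeedSequence(entropy)


def derive_rng(master_seed: int, *key) -> np.random.Generator:
    """Generator for the sub-stream identified by ``key``."""
    return np.random.default_rng(derive_seed_sequence(master_seed, *key))
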