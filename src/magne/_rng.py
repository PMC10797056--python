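"""Seed derivation helpers.

Every stochastic operation draws from its own child stream, derived from the
root seed plus a fixed string/integer label path. Adding a new operator
therefore never shifts the draws of existing ones, and the same
(config, seed) pair reproduces byte-identical output.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MASK31 = 0x7FFFFFFF


def _label_words(label: str | int) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    digest = hashlib.sha256(str(label).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def child_sequence(root_seed: int, *labels: str | int) -> np.random.SeedSequence:
    entropy = [int(root_seed) & _MASK31] + [_label_words(lab) for lab in labels]
    return np.random.SeedSequence(entropy)


def child_rng(root_seed: int, *labels: str | int) -> np.random.Generator:
    """Generator for the child stream identified by ``labels``."""
    return np.random.default_rng(child_sequence(root_seed, *labels))


def child_seed(root_seed: int, *labels: str | int) -> int:
    """A plain integer seed (< 2**31) derived from the child stream."""
    state = child_sequence(root_seed, *labels).generate_state(1, np.uint32)[0]
    return int(state) & _MASK31
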