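"""Deterministic per-stage random streams.

Every stochastic operation draws from its own named stream derived from one
integer seed, so a stage can be re-run in isolation and reproduce the exact
realization it produced inside a full pipeline run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stream", "substream_seed"]


def _label_key(label: str) -> int:
    digest = hashlib.sha256(label.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def stream(seed: int, label: str) -> np.random.Generator:
    """Return a Generator keyed by (seed, label); same pair, same stream."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_label_key(label),))
    return np.random.default_rng(ss)


def substream_seed(seed: int, label: str) -> int:
    """A derived integer seed (< 2**31) for libraries that take one."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_label_key(label),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1)) + 1
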