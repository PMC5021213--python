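"""Deterministic seed derivation.

Every stochastic stage of the pipeline draws from its own stream derived by
stable hashing of (root seed, stage label, ...). This keeps stages isolated —
changing the number of repetitions in one stage does not perturb another —
while a single root seed reproduces the whole run.
"""

from __future__ import annotations

import hashlib

import numpy as np

_MOD = 2**31 - 1


def derive_seed(root: int, *labels: object) -> int:
    """Derive a child seed (< 2**31) from a root seed and a label path."""
    key = ":".join([str(int(root))] + [str(lab) for lab in labels])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MOD


def derive_rng(root: int, *labels: object) -> np.random.Generator:
    """A numpy Generator seeded from :func:`derive_seed`."""
    return np.random.default_rng(derive_seed(root, *labels))
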