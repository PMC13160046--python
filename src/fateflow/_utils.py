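"""Small shared helpers (dense conversion, seeding)."""

from __future__ import annotations

import zlib

import numpy as np
import scipy.sparse as sp


def as_dense(X) -> np.ndarray:
    """Return a dense float64 ndarray view/copy of a (possibly sparse) matrix."""
    if sp.issparse(X):
        return np.asarray(X.todense(), dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def child_seed(seed: int, *keys) -> int:
    """Derive a reproducible sub-seed < 2**31 from a base seed and keys.

    Uses a process-independent hash (crc32 of the repr) so derived seeds
    are stable across interpreter sessions.
    """
    parts = [int(seed) % (2**31)]
    parts += [zlib.crc32(repr(k).encode()) % (2**31) for k in keys]
    ss = np.random.SeedSequence(parts)
    return int(ss.generate_state(1)[0] % (2**31))
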