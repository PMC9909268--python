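"""Shared helpers: seeded substreams and input validation."""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

__all__ = ["substream", "rng_for", "as_count_frame"]


def substream(seed: int, *tokens) -> np.random.SeedSequence:
    """Derive a named, order-stable seed substream from a master seed.

    Each (stage-name, index, ...) token tuple maps to its own SeedSequence so
    adding draws in one pipeline stage never perturbs another stage's stream.
    """
    keys = [zlib.crc32(str(t).encode()) for t in tokens]
    return np.random.SeedSequence(entropy=int(seed) & 0x7FFFFFFF, spawn_key=tuple(keys))


def rng_for(seed: int, *tokens) -> np.random.Generator:
    return np.random.default_rng(substream(seed, *tokens))


def as_count_frame(table) -> pd.DataFrame:
    """Validate a samples x taxa count table and return it as a DataFrame."""
    df = pd.DataFrame(table)
    values = df.to_numpy()
    if values.size == 0:
        raise ValueError("count table is empty")
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("count table contains non-numeric entries")
    if (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    if df.columns.duplicated().any():
        raise ValueError("duplicate taxon identifiers in count table")
    if df.index.duplicated().any():
        raise ValueError("duplicate sample identifiers in count table")
    return df
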