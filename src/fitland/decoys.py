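"""Sequence decoy generators.

Two families of decoys, both mounted on native structures so that every
native contact is retained (which makes them hard to discriminate):

* gapless threading: every contiguous window of a longer guest
  protein's sequence is mounted on the structure of a shorter host,
  giving exactly L - l + 1 decoys per (host, guest) pair;
* composition-preserving swaps: the native sequence is permuted by a
  fixed number of random transpositions, conserving the amino-acid
  composition exactly while lowering sequence identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from fitland.contacts import ContactVector, LengthModel, contact_vector, normalize_length

#: Swap counts used for the swap-decoy series, low to high.
DEFAULT_SWAP_SCHEDULE: tuple[int, ...] = (1, 2, 4, 8, 16, 32)


@dataclass(frozen=True)
class ThreadingDecoy:
    host_chain_id: str
    guest_chain_id: str
    window_start: int
    vector: ContactVector
    is_native: bool = False  # window happens to equal the host's own sequence


@dataclass(frozen=True)
class SwapDecoy:
    source_chain_id: str
    n_swaps: int
    replicate: int
    sequence: tuple[str, ...]
    identity: float
    vector: ContactVector


def sequence_identity(a: Sequence[str], b: Sequence[str]) -> float:
    """Fraction of positions at which two equal-length sequences agree."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("empty sequences")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def thread_decoys(
    host_id: str,
    host_sequence: Sequence[str],
    host_map: Iterable[tuple[int, int]],
    guest_id: str,
    guest_sequence: Sequence[str],
    normalizer: LengthModel | None = None,
) -> list[ThreadingDecoy]:
    """Gapless threading of a guest sequence through the host structure.

    Returns one decoy per contiguous window of ``guest_sequence`` of the
    host's length: exactly len(guest) - len(host) + 1 decoys.  Each
    decoy vector is the host contact map recounted under the window's
    residue types, then length-normalized with the host length if a
    ``normalizer`` is given.  Windows identical to the host's native
    sequence are flagged ``is_native`` rather than dropped.
    """
    l, L = len(host_sequence), len(guest_sequence)
    if L < l:
        raise ValueError(f"guest (length {L}) shorter than host (length {l})")
    host_map = list(host_map)
    native = tuple(host_sequence)
    out: list[ThreadingDecoy] = []
    for start in range(L - l + 1):
        window = tuple(guest_sequence[start : start + l])
        vec = contact_vector(window, host_map, length=l)
        if normalizer is not None:
            vec = normalize_length(vec, normalizer)
        out.append(
            ThreadingDecoy(
                host_chain_id=host_id,
                guest_chain_id=guest_id,
                window_start=start,
                vector=vec,
                is_native=window == native,
            )
        )
    return out


def swap_decoys(
    chain_id: str,
    native_sequence: Sequence[str],
    contact_map: Iterable[tuple[int, int]],
    n_swaps: int,
    n_replicates: int,
    seed: int,
    normalizer: LengthModel | None = None,
) -> list[SwapDecoy]:
    """Decoys from random residue swaps of the native sequence.

    Each replicate applies ``n_swaps`` independent uniformly random
    transpositions of two distinct positions.  Swapping two positions
    that hold the same residue type still counts as one swap, so the
    identity to the native sequence after one swap of distinct types on
    a length-L chain is exactly (L - 2) / L.  ``n_swaps = 0`` is allowed
    as a control and reproduces the native sequence.
    """
    if n_swaps < 0:
        raise ValueError("n_swaps must be >= 0")
    if n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    n = len(native_sequence)
    if n < 2:
        raise ValueError("sequence must have length >= 2")
    contact_map = list(contact_map)
    native = list(native_sequence)
    rng = np.random.default_rng(seed)
    out: list[SwapDecoy] = []
    for rep in range(n_replicates):
        seq = native.copy()
        for _ in range(n_swaps):
            i, j = rng.choice(n, size=2, replace=False)
            seq[i], seq[j] = seq[j], seq[i]
        vec = contact_vector(seq, contact_map, length=n)
        if normalizer is not None:
            vec = normalize_length(vec, normalizer)
        out.append(
            SwapDecoy(
                source_chain_id=chain_id,
                n_swaps=n_swaps,
                replicate=rep,
                sequence=tuple(seq),
                identity=sequence_identity(seq, native),
                vector=vec,
            )
        )
    return out


def swap_decoy_series(
    chain_id: str,
    native_sequence: Sequence[str],
    contact_map: Iterable[tuple[int, int]],
    schedule: Sequence[int] = DEFAULT_SWAP_SCHEDULE,
    n_replicates: int = 1000,
    seed: int = 0,
    normalizer: LengthModel | None = None,
) -> dict[int, list[SwapDecoy]]:
    """Swap decoys at every swap count of ``schedule`` (default 1..32).

    ``n_replicates`` defaults to 1,000 sequences per swap count.  Each
    swap count gets an independent seed derived from ``seed`` so any
    level of the series can be regenerated in isolation.
    """
    out: dict[int, list[SwapDecoy]] = {}
    for k, n_swaps in enumerate(schedule):
        out[n_swaps] = swap_decoys(
            chain_id,
            native_sequence,
            contact_map,
            n_swaps=n_swaps,
            n_replicates=n_replicates,
            seed=(seed * 10007 + k) % (2**31),
            normalizer=normalizer,
        )
    return out
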