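"""Sliding-window fragment extraction with pseudo-residue padding.

Every residue of a chain becomes the centre of exactly one length-L
fragment; (L-1)/2 pseudo-residues are appended at both chain ends so that
terminal residues can be centred too.  Pseudo-residues occupy the vacancy
category of every track.  A fragment is positive iff its central residue is
a binding residue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .discretizers import DiscretizedChain, vacancy_row


@dataclass
class Fragment:
    """A length-L window of per-residue category codes centred on one residue."""

    chain_id: str
    center_index: int  # 0-based residue index in the chain
    states: np.ndarray  # (L, 8) int16 category codes, TRACKS order
    label: int  # 1 = binding (positive), 0 = non-binding

    @property
    def window_length(self) -> int:
        return self.states.shape[0]


def make_fragments(chain: DiscretizedChain, window_length: int) -> Iterator[Fragment]:
    """Yield one fragment per residue of ``chain`` (lazy, deterministic order).

    Raises ``ValueError`` for even or non-positive window lengths.
    """
    L = window_length
    if L < 1 or L % 2 == 0:
        raise ValueError(f"window length must be an odd positive integer, got {L}")
    n = len(chain)
    half = (L - 1) // 2
    padded = np.vstack(
        [np.tile(vacancy_row(), (half, 1)), chain.codes, np.tile(vacancy_row(), (half, 1))]
    )
    for k in range(n):
        yield Fragment(
            chain_id=chain.chain_id,
            center_index=k,
            states=padded[k : k + L],
            label=int(chain.labels[k]),
        )


def fragments_from_chains(
    chains: Sequence[DiscretizedChain], window_length: int
) -> list[Fragment]:
    """Materialize fragments for several chains, chain order then residue order."""
    out: list[Fragment] = []
    for ch in chains:
        out.extend(make_fragments(ch, window_length))
    return out


def fragment_labels(fragments: Sequence[Fragment]) -> np.ndarray:
    return np.fromiter((f.label for f in fragments), dtype=np.int8, count=len(fragments))
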