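"""Median-based majority voting over five independent reasoning chains.

Each chain contributes a 7-region likelihood vector L_ij (region i, chain j).
Per region, the median across the five chains defines the consensus; each
chain's adjusted score A_ij is its absolute deviation from that median, and the
winning chain W minimizes the summed deviation over regions. The winner's
vector is returned *unchanged* — voting selects a chain, it never averages.
Failed chains participate as all-zero vectors so the five-chain contract holds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .parsing import RegionLikelihood

N_CHAINS = 5


@dataclass(frozen=True)
class ChainSet:
    """Outcome of one self-consistency vote."""

    chains: tuple[RegionLikelihood, ...]   # the 5 input vectors, in order
    adjusted: np.ndarray                   # A_ij = |L_ij - median_i|, shape (7, 5)
    winner: int                            # 0-based winning chain index

    @property
    def result(self) -> RegionLikelihood:
        return self.chains[self.winner]


def median_vote(chains: Sequence[RegionLikelihood]) -> ChainSet:
    """Select the chain closest (L1) to the per-region median vector.

    Ties on the minimal adjusted sum break toward the lowest chain index.
    Raises ValueError unless exactly five chains are supplied.
    """
    if len(chains) != N_CHAINS:
        raise ValueError(f"self-consistency requires exactly {N_CHAINS} chains, got {len(chains)}")
    matrix = np.column_stack([c.as_array() for c in chains])  # (7, 5)
    medians = np.median(matrix, axis=1)                       # middle order statistic
    adjusted = np.abs(matrix - medians[:, None])
    sums = adjusted.sum(axis=0)
    winner = int(np.argmin(sums))  # argmin returns the first minimum: lowest index
    return ChainSet(chains=tuple(chains), adjusted=adjusted, winner=winner)
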