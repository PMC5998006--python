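"""Native single-position liftover over an interval index of chains.

The index stores, per source sequence, every aligned block of every
loaded chain in an interval tree.  A query position falling inside a
block is mapped by block arithmetic; positions inside chain gaps or
outside all chains are unmapped.  When several chains cover the same
source position the highest-scoring chain wins; equal scores are broken
by the lexicographically smallest (destination name, plus-strand
position) so that answers form a total, reproducible order.

Mapped positions are always reported in plus-strand coordinates of the
destination assembly; the strand of the chain used is recorded
separately (segment and probe tables are strandless).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .chain import Chain

__all__ = ["MappedPosition", "LiftIndex", "build_index", "lift_position"]


@dataclass(frozen=True)
class MappedPosition:
    """Image of a source position: destination sequence name, 0-based
    plus-strand position, strand of the chain used, and that chain's score."""

    chrom: str
    pos: int
    strand: str
    chain_score: int


@dataclass(frozen=True)
class _BlockRef:
    """Payload attached to each indexed block interval."""

    score: int
    q_name: str
    q_strand: str
    q_size: int
    t_block_start: int
    q_block_start: int  # strand-local


class LiftIndex:
    """Queryable source-position -> destination-position index over a
    chain set.  Build with :func:`build_index`."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n_blocks = 0

    def add_chain(self, chain: Chain) -> None:
        h = chain.header
        tree = self._trees.get(h.t_name)
        if tree is None:
            tree = self._trees[h.t_name] = IntervalTree()
        t = h.t_start
        q = h.q_start
        for b in chain.blocks:
            tree.addi(
                t,
                t + b.size,
                _BlockRef(
                    score=h.score,
                    q_name=h.q_name,
                    q_strand=h.q_strand,
                    q_size=h.q_size,
                    t_block_start=t,
                    q_block_start=q,
                ),
            )
            self._n_blocks += 1
            t += b.size + b.dt
            q += b.size + b.dq

    @property
    def n_blocks(self) -> int:
        return self._n_blocks

    @property
    def source_names(self) -> list[str]:
        return sorted(self._trees)

    def lift(self, chrom: str, pos: int) -> Optional[MappedPosition]:
        """Map a single 0-based source position; ``None`` when unmapped.

        An unknown sequence name is unmapped, not an error.
        """
        if pos < 0:
            raise ValueError(f"position must be >= 0, got {pos}")
        tree = self._trees.get(chrom)
        if tree is None:
            return None
        best: tuple[int, str, int, str, int] | None = None
        for iv in tree.at(pos):
            ref: _BlockRef = iv.data
            local = ref.q_block_start + (pos - ref.t_block_start)
            if ref.q_strand == "+":
                plus = local
            else:
                plus = ref.q_size - 1 - local
            key = (-ref.score, ref.q_name, plus, ref.q_strand, ref.score)
            if best is None or key < best:
                best = key
        if best is None:
            return None
        _, q_name, plus, strand, score = best
        return MappedPosition(chrom=q_name, pos=plus, strand=strand, chain_score=score)


def build_index(chains: Iterable[Chain]) -> LiftIndex:
    """Build a :class:`LiftIndex` covering exactly the union of aligned
    blocks of *chains* (gap bases are not covered).  Loading order does
    not affect query results."""
    index = LiftIndex()
    for chain in chains:
        index.add_chain(chain)
    return index


def lift_position(index: LiftIndex, chrom: str, pos: int) -> Optional[MappedPosition]:
    """Functional wrapper around :meth:`LiftIndex.lift`."""
    return index.lift(chrom, pos)
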