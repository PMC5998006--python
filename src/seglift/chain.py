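"""UCSC chain format: parsing, validation and serialization.

A chain file describes pairwise alignments between two genome assemblies.
Each chain is a scored, gapped alignment between a region of the *source*
assembly (UCSC "target", ``t``) and a region of the *query*/*destination*
assembly (``q``).  The header line carries thirteen whitespace-separated
fields::

    chain score tName tSize tStrand tStart tEnd qName qSize qStrand qStart qEnd id

followed by alignment data lines, one per ungapped block::

    size dt dq     # block length, gap on source, gap on query
    size           # final block carries no gaps

Coordinates are 0-based half-open.  The source strand is always ``+``;
when the query strand is ``-``, query coordinates are *strand-local*
(counted from the end of the reverse-complemented sequence), so the
plus-strand position of strand-local position ``p`` is ``qSize - 1 - p``.

The parser is strict: structural problems raise :class:`ChainParseError`
(with a line number) and arithmetic inconsistencies raise
:class:`ChainValidationError` (naming the chain id) instead of being
silently skipped.  Lines starting with ``#`` are treated as comments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Iterator

__all__ = [
    "ChainHeader",
    "ChainBlock",
    "Chain",
    "ChainParseError",
    "ChainValidationError",
    "parse_chain_file",
    "parse_chain_text",
    "validate_chain",
    "write_chain_file",
    "chains_to_text",
]


class ChainParseError(ValueError):
    """Raised for structurally malformed chain input.

    Carries the 1-based line number where the problem was detected.
    """

    def __init__(self, line_no: int, message: str) -> None:
        self.line_no = line_no
        super().__init__(f"line {line_no}: {message}")


class ChainValidationError(ValueError):
    """Raised when a structurally parsed chain violates its arithmetic
    invariants (block sums, coordinate bounds, gap rules)."""

    def __init__(self, chain_id: str, violations: list[str]) -> None:
        self.chain_id = chain_id
        self.violations = list(violations)
        detail = "; ".join(violations)
        super().__init__(f"chain {chain_id!r}: {detail}")


@dataclass(frozen=True)
class ChainHeader:
    """Header of one alignment chain.

    ``t_*`` fields describe the source assembly, ``q_*`` fields the
    destination.  Spans are 0-based half-open; ``q_start``/``q_end`` are
    strand-local when ``q_strand`` is ``-``.
    """

    score: int
    t_name: str
    t_size: int
    t_strand: str
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned block: ``size`` aligned bases, followed by a
    gap of ``dt`` bases on the source and ``dq`` bases on the destination.
    The final block of a chain has ``dt == dq == 0``."""

    size: int
    dt: int
    dq: int


@dataclass(frozen=True)
class Chain:
    """A parsed chain: header plus its ordered block list."""

    header: ChainHeader
    blocks: tuple[ChainBlock, ...]

    def source_span(self) -> int:
        return self.header.t_end - self.header.t_start

    def dest_span(self) -> int:
        return self.header.q_end - self.header.q_start


_HEADER_FIELDS = 13


def _parse_header(line: str, line_no: int) -> ChainHeader:
    fields = line.split()
    if len(fields) != _HEADER_FIELDS:
        raise ChainParseError(
            line_no,
            f"chain header has {len(fields)} fields, expected {_HEADER_FIELDS}",
        )
    try:
        score = int(fields[1])
        t_size, t_start, t_end = int(fields[3]), int(fields[5]), int(fields[6])
        q_size, q_start, q_end = int(fields[8]), int(fields[10]), int(fields[11])
    except ValueError as exc:
        raise ChainParseError(line_no, f"non-integer coordinate in header: {exc}") from None
    return ChainHeader(
        score=score,
        t_name=fields[2],
        t_size=t_size,
        t_strand=fields[4],
        t_start=t_start,
        t_end=t_end,
        q_name=fields[7],
        q_size=q_size,
        q_strand=fields[9],
        q_start=q_start,
        q_end=q_end,
        chain_id=fields[12],
    )


def validate_chain(chain: Chain) -> list[str]:
    """Return every violated invariant of *chain* as a human-readable
    description; an empty list means the chain is internally consistent.

    Checked: strand conventions, coordinate bounds on both assemblies,
    positive block sizes and non-negative gaps, the no-gap rule for the
    final block, mergeable (zero-gap) interior blocks, and the two block
    sum identities against the header spans.
    """
    v: list[str] = []
    h = chain.header
    if h.score < 0:
        v.append(f"negative score {h.score}")
    if h.t_strand != "+":
        v.append(f"source strand must be '+', got {h.t_strand!r}")
    if h.q_strand not in ("+", "-"):
        v.append(f"destination strand must be '+' or '-', got {h.q_strand!r}")
    if not (0 <= h.t_start < h.t_end <= h.t_size):
        v.append(
            f"source span violates 0 <= t_start < t_end <= t_size: "
            f"start={h.t_start} end={h.t_end} size={h.t_size}"
        )
    if not (0 <= h.q_start < h.q_end <= h.q_size):
        v.append(
            f"destination span violates 0 <= q_start < q_end <= q_size: "
            f"start={h.q_start} end={h.q_end} size={h.q_size}"
        )
    if not chain.blocks:
        v.append("chain has no alignment blocks")
        return v
    last = len(chain.blocks) - 1
    for i, b in enumerate(chain.blocks):
        if b.size <= 0:
            v.append(f"block {i} has non-positive size {b.size}")
        if b.dt < 0 or b.dq < 0:
            v.append(f"block {i} has negative gap (dt={b.dt}, dq={b.dq})")
        if i == last:
            if b.dt != 0 or b.dq != 0:
                v.append(f"final block carries gaps (dt={b.dt}, dq={b.dq})")
        elif b.dt == 0 and b.dq == 0:
            v.append(f"block {i} has zero gaps but is not final (blocks should be merged)")
    t_sum = sum(b.size + b.dt for b in chain.blocks)
    q_sum = sum(b.size + b.dq for b in chain.blocks)
    if t_sum != h.t_end - h.t_start:
        v.append(f"source block sum {t_sum} != header span {h.t_end - h.t_start}")
    if q_sum != h.q_end - h.q_start:
        v.append(f"destination block sum {q_sum} != header span {h.q_end - h.q_start}")
    return v


def _finish_chain(header: ChainHeader, blocks: list[ChainBlock]) -> Chain:
    chain = Chain(header=header, blocks=tuple(blocks))
    violations = validate_chain(chain)
    if violations:
        raise ChainValidationError(header.chain_id, violations)
    return chain


def parse_chain_file(stream: IO[str] | Iterable[str]) -> list[Chain]:
    """Parse a UCSC chain file from a text stream (or any iterable of
    lines) and return every chain in file order.

    Every chain is validated with :func:`validate_chain`; a violation
    raises :class:`ChainValidationError`.  Blank lines separate chains and
    ``#`` comment lines are skipped.  Duplicate chain ids are accepted.
    """
    chains: list[Chain] = []
    header: ChainHeader | None = None
    blocks: list[ChainBlock] = []
    last_line_no = 0
    for line_no, raw in enumerate(stream, start=1):
        last_line_no = line_no
        line = raw.strip()
        if line.startswith("#"):
            continue
        if not line:
            if header is not None:
                raise ChainParseError(line_no, "chain truncated: missing final block line")
            continue
        if line.split(None, 1)[0] == "chain":
            if header is not None:
                raise ChainParseError(
                    line_no, "new chain header before previous chain's final block"
                )
            header = _parse_header(line, line_no)
            blocks = []
            continue
        if header is None:
            raise ChainParseError(line_no, f"alignment data outside any chain: {line!r}")
        fields = line.split()
        try:
            values = [int(f) for f in fields]
        except ValueError:
            raise ChainParseError(line_no, f"non-integer alignment data: {line!r}") from None
        if len(values) == 3:
            blocks.append(ChainBlock(size=values[0], dt=values[1], dq=values[2]))
        elif len(values) == 1:
            blocks.append(ChainBlock(size=values[0], dt=0, dq=0))
            chains.append(_finish_chain(header, blocks))
            header, blocks = None, []
        else:
            raise ChainParseError(
                line_no, f"alignment line has {len(values)} fields, expected 1 or 3"
            )
    if header is not None:
        raise ChainParseError(last_line_no, "unexpected end of file inside a chain")
    return chains


def parse_chain_text(text: str) -> list[Chain]:
    """Parse chains from an in-memory string (see :func:`parse_chain_file`)."""
    return parse_chain_file(iter(text.splitlines(keepends=True)))


def _chain_lines(chain: Chain) -> Iterator[str]:
    h = chain.header
    yield (
        f"chain {h.score} {h.t_name} {h.t_size} {h.t_strand} {h.t_start} {h.t_end} "
        f"{h.q_name} {h.q_size} {h.q_strand} {h.q_start} {h.q_end} {h.chain_id}"
    )
    last = len(chain.blocks) - 1
    for i, b in enumerate(chain.blocks):
        if i == last:
            yield f"{b.size}"
        else:
            yield f"{b.size}\t{b.dt}\t{b.dq}"


def write_chain_file(chains: Iterable[Chain], stream: IO[str]) -> None:
    """Serialize *chains* in UCSC chain format.  Parsing the output yields
    an equivalent chain set (same headers, same block lists)."""
    for chain in chains:
        for line in _chain_lines(chain):
            stream.write(line + "\n")
        stream.write("\n")


def chains_to_text(chains: Iterable[Chain]) -> str:
    """Serialize *chains* to a string (see :func:`write_chain_file`)."""
    import io

    buf = io.StringIO()
    write_chain_file(chains, buf)
    return buf.getvalue()
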