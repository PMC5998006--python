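"""Integrity-preserving conversion of segments and probes.

Unlike general-purpose liftover tools, which split a segment whose
continuity is disrupted in the destination assembly into sub-segments,
this module converts only the two *endpoints* of each segment and then
checks that the resulting interval is still a faithful image of the
original.  A segment conversion succeeds only when four criteria hold:

1. the start position has an image in the destination assembly;
2. the end position has an image in the destination assembly;
3. both images land on the same destination chromosome;
4. the length ratio is bounded: ``1/beta < len(old)/len(new) < beta``
   (strict inequalities; ``beta`` defaults to 2).

When criterion 1 or 2 fails directly, an *approximate* conversion
searches the source neighbourhood on a step grid (``pos +/- k*step_size``
for ``k*step_size <= range``, nearest candidates first, the lower source
coordinate winning ties) for a liftable surrogate position.  A segment
still failing 1/2 after approximation is *unconvertible*; a segment
whose endpoints map but which fails 3/4 (or whose endpoints map through
chains of opposite strands) is *rejected*.  Every input row receives
exactly one of the four statuses, so the per-file status tally always
partitions the row count.

File coordinates are 1-based inclusive (the de-facto convention of CNV
segment tables) and are converted to 0-based internally; the end
coordinate is lifted as the base *at* position ``end``.  Segment length
is ``end - start + 1`` on both assemblies.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

from .engine import LiftIndex, MappedPosition

__all__ = [
    "ConversionStatus",
    "Reason",
    "QCParams",
    "ApproxParams",
    "Segment",
    "Probe",
    "SegmentConversionResult",
    "ProbeConversionResult",
    "RowError",
    "FileConversionResult",
    "approximate_position",
    "convert_segment",
    "convert_probe",
    "convert_segment_file",
    "convert_probe_file",
    "read_segment_file",
    "read_probe_file",
    "write_segment_outputs",
    "write_probe_outputs",
]


class ConversionStatus(str, enum.Enum):
    """The four-way outcome vocabulary; every processed row gets exactly one."""

    DIRECT = "directly_converted"
    APPROX = "approximately_converted"
    REJECTED = "rejected"
    UNCONVERTIBLE = "unconvertible"

    def __str__(self) -> str:  # tidy log output
        return self.value


class Reason(str, enum.Enum):
    """Machine-readable failure codes recorded in logs and side files."""

    START_UNMAPPED = "start_unmapped"
    END_UNMAPPED = "end_unmapped"
    POSITION_UNMAPPED = "position_unmapped"  # probes
    CHROMOSOME_MISMATCH = "chromosome_mismatch"
    LENGTH_RATIO_OUT_OF_BOUNDS = "length_ratio_out_of_bounds"
    STRAND_MISMATCH = "strand_mismatch"
    INVERTED_ORDER = "inverted_order"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class QCParams:
    """Quality-control parameters.  ``beta`` (> 1) bounds the old/new
    length ratio; the conventional default is 2."""

    beta: float = 2.0

    def __post_init__(self) -> None:
        if not self.beta > 1:
            raise ValueError(f"beta must be > 1, got {self.beta}")


@dataclass(frozen=True)
class ApproxParams:
    """Neighbourhood-search parameters for approximate conversion.

    ``range``: maximum distance (bp) from the failed position that is
    searched; 0 disables approximation.  ``step_size``: grid resolution
    (bp) of the search.
    """

    range: int = 10_000
    step_size: int = 100

    def __post_init__(self) -> None:
        if self.range < 0:
            raise ValueError(f"range must be >= 0, got {self.range}")
        if self.step_size < 1:
            raise ValueError(f"step_size must be >= 1, got {self.step_size}")


@dataclass(frozen=True)
class Segment:
    """A valued genomic interval in 1-based inclusive file coordinates.

    ``payload`` carries any extra columns (probe counts, log2 ratios, ...)
    untouched.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    payload: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start > self.end:  # normalize; files occasionally swap
            s, e = self.start, self.end
            object.__setattr__(self, "start", e)
            object.__setattr__(self, "end", s)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class Probe:
    """A single genomic position with payload, 1-based file coordinates."""

    probe_id: str
    chrom: str
    pos: int
    payload: tuple[str, ...] = ()


@dataclass(frozen=True)
class SegmentConversionResult:
    input: Segment
    status: ConversionStatus
    new_chrom: Optional[str] = None
    new_start: Optional[int] = None  # 1-based inclusive, like the input
    new_end: Optional[int] = None
    length_ratio: Optional[float] = None
    reason: Optional[Reason] = None
    approx_shift_start: int = 0
    approx_shift_end: int = 0
    orientation_flipped: bool = False

    @property
    def converted(self) -> bool:
        return self.status in (ConversionStatus.DIRECT, ConversionStatus.APPROX)


@dataclass(frozen=True)
class ProbeConversionResult:
    input: Probe
    status: ConversionStatus
    new_chrom: Optional[str] = None
    new_pos: Optional[int] = None  # 1-based
    reason: Optional[Reason] = None
    approx_shift: int = 0

    @property
    def converted(self) -> bool:
        return self.status in (ConversionStatus.DIRECT, ConversionStatus.APPROX)


def approximate_position(
    index: LiftIndex, chrom: str, pos: int, params: ApproxParams
) -> Optional[tuple[MappedPosition, int]]:
    """Find the nearest liftable source position to 0-based ``pos`` on the
    search grid and return its image plus the signed source shift used.

    Candidates ``pos - k*step``, ``pos + k*step`` are examined in order of
    increasing distance (``k = 0, 1, 2, ...`` while ``k*step <= range``);
    at equal distance the lower source coordinate wins.  ``k = 0`` means a
    directly liftable position returns itself with shift 0.  Returns
    ``None`` when no candidate within range is liftable.
    """
    direct = index.lift(chrom, pos)
    if direct is not None:
        return direct, 0
    step = params.step_size
    max_k = params.range // step
    for k in range(1, max_k + 1):
        for cand in (pos - k * step, pos + k * step):
            if cand < 0:
                continue
            hit = index.lift(chrom, cand)
            if hit is not None:
                return hit, cand - pos
    return None


def convert_segment(
    seg: Segment,
    index: LiftIndex,
    qc: QCParams = QCParams(),
    approx: ApproxParams = ApproxParams(),
) -> SegmentConversionResult:
    """Convert one segment: lift both endpoints (direct first, then
    approximate), then apply the four-criterion QC.

    Endpoints that map through chains of opposite strands are rejected
    with ``strand_mismatch``.  If the lifted endpoints come out in
    inverted order the coordinates are swapped and the segment is kept
    (flagged via ``orientation_flipped``) provided the remaining criteria
    pass.  Never raises: every input yields a result record.
    """
    start0, end0 = seg.start - 1, seg.end - 1
    lifted_start = approximate_position(index, seg.chrom, start0, approx)
    if lifted_start is None:
        return SegmentConversionResult(
            input=seg, status=ConversionStatus.UNCONVERTIBLE, reason=Reason.START_UNMAPPED
        )
    lifted_end = approximate_position(index, seg.chrom, end0, approx)
    if lifted_end is None:
        return SegmentConversionResult(
            input=seg, status=ConversionStatus.UNCONVERTIBLE, reason=Reason.END_UNMAPPED
        )
    (mp_start, shift_start), (mp_end, shift_end) = lifted_start, lifted_end

    if mp_start.chrom != mp_end.chrom:
        return SegmentConversionResult(
            input=seg,
            status=ConversionStatus.REJECTED,
            reason=Reason.CHROMOSOME_MISMATCH,
            approx_shift_start=shift_start,
            approx_shift_end=shift_end,
        )
    if mp_start.strand != mp_end.strand:
        return SegmentConversionResult(
            input=seg,
            status=ConversionStatus.REJECTED,
            reason=Reason.STRAND_MISMATCH,
            approx_shift_start=shift_start,
            approx_shift_end=shift_end,
        )

    new_start0, new_end0 = mp_start.pos, mp_end.pos
    flipped = new_start0 > new_end0
    if flipped:
        new_start0, new_end0 = new_end0, new_start0

    old_len = seg.end - seg.start + 1
    new_len = new_end0 - new_start0 + 1
    ratio = old_len / new_len
    # 1/beta < old/new < beta, strict on both sides; compare by
    # multiplication so the boundary cases are exact in float arithmetic.
    if not (old_len < qc.beta * new_len and new_len < qc.beta * old_len):
        return SegmentConversionResult(
            input=seg,
            status=ConversionStatus.REJECTED,
            reason=Reason.LENGTH_RATIO_OUT_OF_BOUNDS,
            length_ratio=ratio,
            approx_shift_start=shift_start,
            approx_shift_end=shift_end,
            orientation_flipped=flipped,
        )

    status = (
        ConversionStatus.DIRECT
        if shift_start == 0 and shift_end == 0
        else ConversionStatus.APPROX
    )
    return SegmentConversionResult(
        input=seg,
        status=status,
        new_chrom=mp_start.chrom,
        new_start=new_start0 + 1,
        new_end=new_end0 + 1,
        length_ratio=ratio,
        approx_shift_start=shift_start,
        approx_shift_end=shift_end,
        orientation_flipped=flipped,
    )


def convert_probe(
    probe: Probe, index: LiftIndex, approx: ApproxParams = ApproxParams()
) -> ProbeConversionResult:
    """Convert one probe position: direct lift, then approximation.  No QC
    criteria apply (a single position has no length or chromosome pairing),
    so probes are never *rejected*."""
    hit = approximate_position(index, probe.chrom, probe.pos - 1, approx)
    if hit is None:
        return ProbeConversionResult(
            input=probe, status=ConversionStatus.UNCONVERTIBLE, reason=Reason.POSITION_UNMAPPED
        )
    mp, shift = hit
    status = ConversionStatus.DIRECT if shift == 0 else ConversionStatus.APPROX
    return ProbeConversionResult(
        input=probe, status=status, new_chrom=mp.chrom, new_pos=mp.pos + 1, approx_shift=shift
    )


# ---------------------------------------------------------------------------
# File-level operations.  Tab-separated, first line is a header; required
# leading columns are (sample, chrom, start, end) for segments and
# (id, chrom, pos) for probes; any further columns are preserved verbatim.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RowError:
    """A row that could not be parsed; processing continues past it."""

    line_no: int
    message: str
    raw: str


SegmentRow = tuple[int, Segment]
ProbeRow = tuple[int, Probe]


def read_segment_file(
    path: Union[str, Path],
) -> tuple[list[str], list[SegmentRow], list[RowError]]:
    """Read a segment table; returns (header columns, (line_no, Segment)
    rows, row errors)."""
    return _read_table(path, _parse_segment_row, min_cols=4)


def read_probe_file(
    path: Union[str, Path],
) -> tuple[list[str], list[ProbeRow], list[RowError]]:
    """Read a probe table; returns (header columns, (line_no, Probe) rows,
    row errors)."""
    return _read_table(path, _parse_probe_row, min_cols=3)


def _parse_segment_row(cols: Sequence[str]) -> Segment:
    return Segment(
        sample_id=cols[0],
        chrom=cols[1],
        start=int(cols[2]),
        end=int(cols[3]),
        payload=tuple(cols[4:]),
    )


def _parse_probe_row(cols: Sequence[str]) -> Probe:
    return Probe(
        probe_id=cols[0], chrom=cols[1], pos=int(cols[2]), payload=tuple(cols[3:])
    )


def _read_table(path, row_parser, min_cols):
    header: list[str] = []
    rows = []
    errors: list[RowError] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if line_no == 1:
                header = line.split("\t")
                continue
            if not line.strip():
                continue
            cols = line.split("\t")
            if len(cols) < min_cols:
                errors.append(
                    RowError(line_no, f"expected >= {min_cols} columns, got {len(cols)}", line)
                )
                continue
            try:
                rows.append((line_no, row_parser(cols)))
            except ValueError as exc:
                errors.append(RowError(line_no, f"bad coordinate: {exc}", line))
    return header, rows, errors


@dataclass
class FileConversionResult:
    """Outcome of converting one file: per-row results in input order, the
    four-status tally, and any row-level parse errors."""

    path: str
    header: list[str]
    results: list[tuple[int, Union[SegmentConversionResult, ProbeConversionResult]]]
    errors: list[RowError]
    tally: dict[ConversionStatus, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.tally:
            self.tally = {s: 0 for s in ConversionStatus}
            for _, res in self.results:
                self.tally[res.status] += 1

    @property
    def n_rows(self) -> int:
        return len(self.results)

    def rows_with_status(self, *statuses: ConversionStatus):
        return [(ln, r) for ln, r in self.results if r.status in statuses]


def convert_segment_file(
    path: Union[str, Path],
    index: LiftIndex,
    qc: QCParams = QCParams(),
    approx: ApproxParams = ApproxParams(),
) -> FileConversionResult:
    """Convert every row of a segment file, preserving input order and
    payload columns.  Unparseable rows are recorded as errors and skipped;
    the tally counts sum to the number of parsed rows."""
    header, rows, errors = read_segment_file(path)
    results = [(ln, convert_segment(seg, index, qc, approx)) for ln, seg in rows]
    return FileConversionResult(path=str(path), header=header, results=results, errors=errors)


def convert_probe_file(
    path: Union[str, Path],
    index: LiftIndex,
    approx: ApproxParams = ApproxParams(),
) -> FileConversionResult:
    """Convert every row of a probe file (no *rejected* class)."""
    header, rows, errors = read_probe_file(path)
    results = [(ln, convert_probe(probe, index, approx)) for ln, probe in rows]
    return FileConversionResult(path=str(path), header=header, results=results, errors=errors)


# ---------------------------------------------------------------------------
# Output writers.  The converted file keeps the input shape with the
# coordinate columns replaced; rejected and unconvertible rows go to side
# files carrying the original coordinates plus a trailing reason column.
# ---------------------------------------------------------------------------


def _segment_out_row(res: SegmentConversionResult) -> str:
    seg = res.input
    cols = [seg.sample_id, res.new_chrom, str(res.new_start), str(res.new_end), *seg.payload]
    return "\t".join(cols)


def _segment_side_row(res: SegmentConversionResult) -> str:
    seg = res.input
    cols = [
        seg.sample_id,
        seg.chrom,
        str(seg.start),
        str(seg.end),
        *seg.payload,
        str(res.reason),
    ]
    return "\t".join(cols)


def _probe_out_row(res: ProbeConversionResult) -> str:
    p = res.input
    return "\t".join([p.probe_id, res.new_chrom, str(res.new_pos), *p.payload])


def _probe_side_row(res: ProbeConversionResult) -> str:
    p = res.input
    return "\t".join([p.probe_id, p.chrom, str(p.pos), *p.payload, str(res.reason)])


def _failure_log_rows(rel_path: str, fr: FileConversionResult) -> list[str]:
    rows = []
    for ln, res in fr.results:
        if res.status in (ConversionStatus.DIRECT,):
            continue
        if isinstance(res, SegmentConversionResult):
            ident, chrom = res.input.sample_id, res.input.chrom
            start, end = res.input.start, res.input.end
            sh_s, sh_e = res.approx_shift_start, res.approx_shift_end
        else:
            ident, chrom = res.input.probe_id, res.input.chrom
            start = end = res.input.pos
            sh_s = sh_e = res.approx_shift
        rows.append(
            "\t".join(
                [
                    rel_path,
                    str(ln),
                    ident,
                    chrom,
                    str(start),
                    str(end),
                    str(res.status),
                    str(res.reason) if res.reason else ".",
                    str(sh_s),
                    str(sh_e),
                ]
            )
        )
    for err in fr.errors:
        rows.append(
            "\t".join([rel_path, str(err.line_no), ".", ".", ".", ".", "row_error", err.message, "0", "0"])
        )
    return rows


FAILURE_LOG_COLUMNS = [
    "file",
    "line",
    "id",
    "chrom",
    "start",
    "end",
    "status",
    "reason",
    "shift_start",
    "shift_end",
]


def _write_outputs(
    fr: FileConversionResult,
    out_path: Path,
    rel_path: str,
    out_row,
    side_row,
) -> None:
    """Write the converted file and (when non-empty) the ``.rejected``,
    ``.unconvertible`` and ``.log`` side files, atomically: everything is
    written to temporaries and renamed into place together."""
    out_path.parent.mkdir(parents=True, exist_ok=True)
    header_line = "\t".join(fr.header)
    pending: list[tuple[Path, str]] = []

    converted_lines = [header_line] + [
        out_row(res) for _, res in fr.results if res.converted
    ]
    pending.append((out_path, "\n".join(converted_lines) + "\n"))

    for status, suffix in (
        (ConversionStatus.REJECTED, ".rejected"),
        (ConversionStatus.UNCONVERTIBLE, ".unconvertible"),
    ):
        picked = fr.rows_with_status(status)
        side = Path(str(out_path) + suffix)
        if picked:
            lines = [header_line + "\treason"] + [side_row(res) for _, res in picked]
            pending.append((side, "\n".join(lines) + "\n"))
        elif side.exists():
            side.unlink()

    log_rows = _failure_log_rows(rel_path, fr)
    log_path = Path(str(out_path) + ".log")
    if log_rows:
        pending.append((log_path, "\n".join(log_rows) + "\n"))
    elif log_path.exists():
        log_path.unlink()

    tmp_paths = []
    for target, content in pending:
        tmp = Path(str(target) + ".part")
        tmp.write_text(content, encoding="utf-8")
        tmp_paths.append((tmp, target))
    for tmp, target in tmp_paths:
        tmp.replace(target)


def write_segment_outputs(fr: FileConversionResult, out_path: Union[str, Path], rel_path: str) -> None:
    _write_outputs(fr, Path(out_path), rel_path, _segment_out_row, _segment_side_row)


def write_probe_outputs(fr: FileConversionResult, out_path: Union[str, Path], rel_path: str) -> None:
    _write_outputs(fr, Path(out_path), rel_path, _probe_out_row, _probe_side_row)
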