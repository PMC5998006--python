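"""Synthetic assembly pairs with known per-base ground truth.

This module fabricates a "source" and a "destination" assembly related by
a list of rearrangement events, and emits two *independently constructed*
views of the relationship:

* a UCSC chain file, built by walking the event list with block/gap
  arithmetic (consumed by the chain parser and lift engine); and
* a :class:`TruthMap`, built by simulating the fate of every single
  source base, one at a time, from the same event list.

Because the two constructions share nothing but the event list, their
base-by-base agreement under the lift engine is a genuine cross-check of
the whole parsing/indexing/arithmetic stack, and the TruthMap doubles as
a brute-force oracle for segment and probe conversion.

Event kinds (coordinates are on the source assembly; destination
coordinates are derived):

* ``deletion_in_target``  — the source bases have no image (a source-side
  gap, ``dt``, within a chain);
* ``insertion_in_target`` — extra destination bases appear between two
  source positions (a destination-side gap, ``dq``); consumes no source;
* ``unplaced_region``     — the source bases have no image and the
  alignment chain breaks around them;
* ``inversion``           — the source bases map reversed, on the minus
  strand, via a separate minus-strand chain;
* ``split_to_new_chrom``  — the source bases map to a fresh destination
  sequence named ``<chrom>_alt<k>``.

Only coordinates exist; no nucleotide sequences are generated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .chain import Chain, ChainBlock, ChainHeader, chains_to_text
from .segments import (
    ApproxParams,
    ConversionStatus,
    Probe,
    QCParams,
    Reason,
    Segment,
)

__all__ = [
    "EVENT_KINDS",
    "Event",
    "RearrangementSpec",
    "TruthMap",
    "generate_assembly_pair",
    "random_rearrangement_spec",
    "generate_case_files",
    "ExpectedFate",
    "truth_lift",
    "truth_approximate",
    "truth_convert_segment",
    "truth_convert_probe",
]

EVENT_KINDS = (
    "deletion_in_target",
    "insertion_in_target",
    "split_to_new_chrom",
    "inversion",
    "unplaced_region",
)

# source bases consumed by each kind (insertions consume none)
_CONSUMING = {k: True for k in EVENT_KINDS}
_CONSUMING["insertion_in_target"] = False


@dataclass(frozen=True)
class Event:
    kind: str
    chrom: str
    start: int  # 0-based source coordinate
    length: int

    def footprint(self) -> tuple[int, int]:
        """Half-open source interval this event occupies for overlap
        checks; an insertion blocks only its anchor base."""
        if _CONSUMING[self.kind]:
            return self.start, self.start + self.length
        return self.start, self.start + 1


@dataclass(frozen=True)
class RearrangementSpec:
    """Seeded description of a source assembly and its rearrangements."""

    seed: int
    chrom_sizes: dict[str, int]
    events: tuple[Event, ...]

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[Event]] = {}
        for e in self.events:
            if e.kind not in EVENT_KINDS:
                raise ValueError(f"unknown event kind {e.kind!r}")
            if e.length < 1:
                raise ValueError(f"event length must be >= 1, got {e.length}")
            if e.chrom not in self.chrom_sizes:
                raise ValueError(f"event on unknown chromosome {e.chrom!r}")
            size = self.chrom_sizes[e.chrom]
            lo, hi = e.footprint()
            if lo < 0 or hi > size:
                raise ValueError(f"event {e} outside chromosome bounds [0, {size})")
            by_chrom.setdefault(e.chrom, []).append(e)
        for chrom, evs in by_chrom.items():
            evs.sort(key=lambda e: e.start)
            for a, b in zip(evs, evs[1:]):
                if b.footprint()[0] < a.footprint()[1]:
                    raise ValueError(f"overlapping events on {chrom}: {a} and {b}")

    def events_for(self, chrom: str) -> list[Event]:
        return sorted((e for e in self.events if e.chrom == chrom), key=lambda e: e.start)


class TruthMap:
    """Ground-truth image of every source base.

    Internally one array triple per source chromosome: destination
    chromosome index (-1 = unmapped), destination plus-strand position,
    and strand (+1/-1).
    """

    def __init__(self) -> None:
        self._names: list[str] = []  # destination chromosome names
        self._name_idx: dict[str, int] = {}
        self._chrom: dict[str, np.ndarray] = {}
        self._pos: dict[str, np.ndarray] = {}
        self._strand: dict[str, np.ndarray] = {}

    def _dest_idx(self, name: str) -> int:
        idx = self._name_idx.get(name)
        if idx is None:
            idx = len(self._names)
            self._names.append(name)
            self._name_idx[name] = idx
        return idx

    def add_source(self, chrom: str, size: int) -> None:
        self._chrom[chrom] = np.full(size, -1, dtype=np.int32)
        self._pos[chrom] = np.full(size, -1, dtype=np.int64)
        self._strand[chrom] = np.zeros(size, dtype=np.int8)

    def set_base(self, chrom: str, pos: int, dest: str, dest_pos: int, strand: str) -> None:
        self._chrom[chrom][pos] = self._dest_idx(dest)
        self._pos[chrom][pos] = dest_pos
        self._strand[chrom][pos] = 1 if strand == "+" else -1

    @property
    def source_sizes(self) -> dict[str, int]:
        return {c: len(a) for c, a in self._chrom.items()}

    def lookup(self, chrom: str, pos: int) -> Optional[tuple[str, int, str]]:
        """Image of 0-based source position ``pos``: (dest chrom, 0-based
        plus-strand dest position, strand), or ``None`` when unmapped or
        out of bounds."""
        arr = self._chrom.get(chrom)
        if arr is None or pos < 0 or pos >= len(arr):
            return None
        ci = arr[pos]
        if ci < 0:
            return None
        strand = "+" if self._strand[chrom][pos] > 0 else "-"
        return self._names[ci], int(self._pos[chrom][pos]), strand

    def n_mapped(self, chrom: Optional[str] = None) -> int:
        chroms = [chrom] if chrom else list(self._chrom)
        return int(sum((self._chrom[c] >= 0).sum() for c in chroms))

    def n_unmapped(self, chrom: Optional[str] = None) -> int:
        chroms = [chrom] if chrom else list(self._chrom)
        return int(sum((self._chrom[c] < 0).sum() for c in chroms))

    def unmapped_positions(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self._chrom[chrom] < 0)


def _alt_names(chrom: str, events: list[Event]) -> dict[int, str]:
    """Deterministic names for split destinations: ``<chrom>_alt<k>`` with
    k numbering split events in source order."""
    names: dict[int, str] = {}
    k = 0
    for e in events:
        if e.kind == "split_to_new_chrom":
            k += 1
            names[e.start] = f"{chrom}_alt{k}"
    return names


def _build_truth(spec: RearrangementSpec) -> TruthMap:
    """Per-base simulation of every event's effect on every source base."""
    truth = TruthMap()
    for chrom, size in spec.chrom_sizes.items():
        truth.add_source(chrom, size)
        events = spec.events_for(chrom)
        alt = _alt_names(chrom, events)
        queue = list(events)
        cursor = 0  # next free position on the main destination sequence
        pos = 0
        while pos < size:
            if queue and queue[0].start == pos:
                e = queue.pop(0)
                if e.kind == "insertion_in_target":
                    cursor += e.length
                    continue  # the anchor base itself maps colinearly below
                if e.kind in ("deletion_in_target", "unplaced_region"):
                    pos += e.length  # bases stay unmapped
                elif e.kind == "inversion":
                    for j in range(e.length):
                        truth.set_base(chrom, pos + j, chrom, cursor + e.length - 1 - j, "-")
                    cursor += e.length
                    pos += e.length
                elif e.kind == "split_to_new_chrom":
                    name = alt[e.start]
                    for j in range(e.length):
                        truth.set_base(chrom, pos + j, name, j, "+")
                    pos += e.length
            else:
                run_end = queue[0].start if queue else size
                for p in range(pos, run_end):
                    truth.set_base(chrom, p, chrom, cursor, "+")
                    cursor += 1
                pos = run_end
        # trailing insertions (anchor at `size`) only grow the destination
    return truth


@dataclass(frozen=True)
class _Run:
    """A colinear aligned run of the main chain."""

    t0: int
    q0: int
    size: int


def _build_chains(spec: RearrangementSpec) -> list[Chain]:
    """Event-walk construction of the chain set by block/gap arithmetic —
    deliberately independent of the per-base simulation."""
    raw: list[tuple[str, object]] = []  # ("main", (chrom, runs)) / ("alt", ...)
    q_sizes: dict[str, int] = {}

    for chrom, size in spec.chrom_sizes.items():
        events = spec.events_for(chrom)
        alt = _alt_names(chrom, events)
        # main destination length by pure arithmetic
        q_len = size
        for e in events:
            if e.kind == "insertion_in_target":
                q_len += e.length
            elif e.kind in ("deletion_in_target", "unplaced_region", "split_to_new_chrom"):
                q_len -= e.length
        q_sizes[chrom] = q_len

        runs: list[_Run] = []
        groups: list[list[_Run]] = [[]]  # chain breaks start a new group
        t = q = 0
        for e in events:
            if e.start > t:
                groups[-1].append(_Run(t, q, e.start - t))
                q += e.start - t
                t = e.start
            if e.kind == "deletion_in_target":
                t += e.length
            elif e.kind == "insertion_in_target":
                q += e.length
            elif e.kind == "unplaced_region":
                t += e.length
                if groups[-1]:
                    groups.append([])
            elif e.kind == "inversion":
                raw.append(("alt", (chrom, chrom, e.start, q, e.length, "-")))
                t += e.length
                q += e.length
            elif e.kind == "split_to_new_chrom":
                name = alt[e.start]
                q_sizes[name] = e.length
                raw.append(("alt", (chrom, name, e.start, 0, e.length, "+")))
                t += e.length
        if t < size:
            groups[-1].append(_Run(t, q, size - t))
        for runs in groups:
            if runs:
                raw.append(("main", (chrom, runs)))

    chains: list[Chain] = []
    next_id = 1
    score = 1000 * (len(raw) + 1)  # distinct, main chains first and highest
    for kind, payload in raw:
        if kind == "main":
            chrom, runs = payload  # type: ignore[misc]
            blocks = []
            for a, b in zip(runs, runs[1:]):
                blocks.append(
                    ChainBlock(size=a.size, dt=b.t0 - (a.t0 + a.size), dq=b.q0 - (a.q0 + a.size))
                )
            blocks.append(ChainBlock(size=runs[-1].size, dt=0, dq=0))
            header = ChainHeader(
                score=score,
                t_name=chrom,
                t_size=spec.chrom_sizes[chrom],
                t_strand="+",
                t_start=runs[0].t0,
                t_end=runs[-1].t0 + runs[-1].size,
                q_name=chrom,
                q_size=q_sizes[chrom],
                q_strand="+",
                q_start=runs[0].q0,
                q_end=runs[-1].q0 + runs[-1].size,
                chain_id=str(next_id),
            )
            chains.append(Chain(header=header, blocks=(tuple(blocks))))
        else:
            src_chrom, dest, t0, p, length, strand = payload  # type: ignore[misc]
            q_size = q_sizes[dest]
            if strand == "+":
                q_start, q_end = p, p + length
            else:
                # plus-strand span [p, p+length) expressed strand-locally
                q_start, q_end = q_size - (p + length), q_size - p
            header = ChainHeader(
                score=score,
                t_name=src_chrom,
                t_size=spec.chrom_sizes[src_chrom],
                t_strand="+",
                t_start=t0,
                t_end=t0 + length,
                q_name=dest,
                q_size=q_size,
                q_strand=strand,
                q_start=q_start,
                q_end=q_end,
                chain_id=str(next_id),
            )
            chains.append(Chain(header=header, blocks=(ChainBlock(length, 0, 0),)))
        next_id += 1
        score -= 1000
    return chains


def generate_assembly_pair(spec: RearrangementSpec) -> tuple[str, TruthMap]:
    """Return ``(chain file text, TruthMap)`` for *spec*.

    The chain text validates under the chain parser; the TruthMap comes
    from an independent per-base simulation of the same events.  The same
    spec always yields byte-identical output.
    """
    chains = _build_chains(spec)
    truth = _build_truth(spec)
    return chains_to_text(chains), truth


def random_rearrangement_spec(
    seed: int,
    n_chroms: int = 1,
    chrom_size_range: tuple[int, int] = (2_000, 8_000),
    max_events: int = 8,
    event_length_range: tuple[int, int] = (10, 400),
) -> RearrangementSpec:
    """Draw a random non-overlapping event landscape.  Deterministic in
    ``seed``."""
    rng = np.random.default_rng(seed)
    chrom_sizes = {
        f"chr{i + 1}": int(rng.integers(chrom_size_range[0], chrom_size_range[1] + 1))
        for i in range(n_chroms)
    }
    events: list[Event] = []
    taken: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    n_target = int(rng.integers(0, max_events + 1))
    attempts = 0
    while len(events) < n_target and attempts < 10 * max_events:
        attempts += 1
        chrom = str(rng.choice(list(chrom_sizes)))
        size = chrom_sizes[chrom]
        kind = EVENT_KINDS[int(rng.integers(0, len(EVENT_KINDS)))]
        length = int(rng.integers(event_length_range[0], event_length_range[1] + 1))
        start_hi = size - (length if _CONSUMING[kind] else 1)
        if start_hi <= 0:
            continue
        start = int(rng.integers(0, start_hi))
        ev = Event(kind, chrom, start, length)
        lo, hi = ev.footprint()
        if any(lo < b and a < hi for a, b in taken[chrom]):
            continue
        taken[chrom].append((lo, hi))
        events.append(ev)
    return RearrangementSpec(seed=seed, chrom_sizes=chrom_sizes, events=tuple(events))


# ---------------------------------------------------------------------------
# Brute-force oracle: segment/probe conversion rules applied directly to
# the TruthMap, mirroring the documented semantics without touching the
# chain/index machinery.
# ---------------------------------------------------------------------------


def truth_lift(truth: TruthMap, chrom: str, pos: int) -> Optional[tuple[str, int, str]]:
    """Direct lift of a 0-based position against the ground truth."""
    return truth.lookup(chrom, pos)


def truth_approximate(
    truth: TruthMap, chrom: str, pos: int, params: ApproxParams
) -> Optional[tuple[tuple[str, int, str], int]]:
    """Grid search identical in semantics to the engine's approximation,
    evaluated against the TruthMap."""
    hit = truth.lookup(chrom, pos)
    if hit is not None:
        return hit, 0
    for k in range(1, params.range // params.step_size + 1):
        for cand in (pos - k * params.step_size, pos + k * params.step_size):
            if cand < 0:
                continue
            hit = truth.lookup(chrom, cand)
            if hit is not None:
                return hit, cand - pos
    return None


@dataclass(frozen=True)
class ExpectedFate:
    status: ConversionStatus
    reason: Optional[Reason]
    new_chrom: Optional[str] = None
    new_start: Optional[int] = None  # 1-based
    new_end: Optional[int] = None
    shift_start: int = 0
    shift_end: int = 0


def truth_convert_segment(
    truth: TruthMap,
    seg: Segment,
    qc: QCParams = QCParams(),
    approx: ApproxParams = ApproxParams(),
) -> ExpectedFate:
    """Expected fate of *seg* by brute-force application of the four
    criteria (plus the strand and orientation policies) to the TruthMap."""
    hit_s = truth_approximate(truth, seg.chrom, seg.start - 1, approx)
    if hit_s is None:
        return ExpectedFate(ConversionStatus.UNCONVERTIBLE, Reason.START_UNMAPPED)
    hit_e = truth_approximate(truth, seg.chrom, seg.end - 1, approx)
    if hit_e is None:
        return ExpectedFate(ConversionStatus.UNCONVERTIBLE, Reason.END_UNMAPPED)
    (c_s, p_s, str_s), sh_s = hit_s
    (c_e, p_e, str_e), sh_e = hit_e
    if c_s != c_e:
        return ExpectedFate(
            ConversionStatus.REJECTED, Reason.CHROMOSOME_MISMATCH, shift_start=sh_s, shift_end=sh_e
        )
    if str_s != str_e:
        return ExpectedFate(
            ConversionStatus.REJECTED, Reason.STRAND_MISMATCH, shift_start=sh_s, shift_end=sh_e
        )
    lo, hi = (p_s, p_e) if p_s <= p_e else (p_e, p_s)
    old_len = seg.end - seg.start + 1
    new_len = hi - lo + 1
    if not (old_len < qc.beta * new_len and new_len < qc.beta * old_len):
        return ExpectedFate(
            ConversionStatus.REJECTED,
            Reason.LENGTH_RATIO_OUT_OF_BOUNDS,
            shift_start=sh_s,
            shift_end=sh_e,
        )
    status = ConversionStatus.DIRECT if sh_s == 0 and sh_e == 0 else ConversionStatus.APPROX
    return ExpectedFate(
        status, None, new_chrom=c_s, new_start=lo + 1, new_end=hi + 1, shift_start=sh_s, shift_end=sh_e
    )


def truth_convert_probe(
    truth: TruthMap, probe: Probe, approx: ApproxParams = ApproxParams()
) -> ExpectedFate:
    hit = truth_approximate(truth, probe.chrom, probe.pos - 1, approx)
    if hit is None:
        return ExpectedFate(ConversionStatus.UNCONVERTIBLE, Reason.POSITION_UNMAPPED)
    (c, p, _), sh = hit
    status = ConversionStatus.DIRECT if sh == 0 else ConversionStatus.APPROX
    return ExpectedFate(status, None, new_chrom=c, new_start=p + 1, new_end=p + 1, shift_start=sh, shift_end=sh)


# ---------------------------------------------------------------------------
# Case-file fabrication with pre-computed expected fates.
# ---------------------------------------------------------------------------

SEGMENT_HEADER = ["sample", "chrom", "start", "end", "probes", "log2"]
PROBE_HEADER = ["probe_id", "chrom", "pos", "log2"]
FATE_HEADER = [
    "record_id",
    "kind",
    "status",
    "reason",
    "new_chrom",
    "new_start",
    "new_end",
    "shift_start",
    "shift_end",
]


def generate_case_files(
    truth: TruthMap,
    n_segments: int,
    n_probes: int,
    seed: int,
    qc: QCParams = QCParams(),
    approx: ApproxParams = ApproxParams(),
) -> tuple[str, str, str]:
    """Fabricate a segment file, a probe file and a tab-separated
    expected-fate table whose statuses are computed from the TruthMap by
    the brute-force oracle under the given parameters.

    A fraction of records is deliberately anchored at unmapped source
    bases so the approximate/unconvertible classes are exercised; the
    rest are uniform.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng(seed)
    sizes = truth.source_sizes
    chroms = sorted(sizes)
    weights = np.array([sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    gap_cache = {c: truth.unmapped_positions(c) for c in chroms}

    seg_lines = ["\t".join(SEGMENT_HEADER)]
    probe_lines = ["\t".join(PROBE_HEADER)]
    fate_lines = ["\t".join(FATE_HEADER)]

    def fate_row(rid: str, kind: str, fate: ExpectedFate) -> str:
        return "\t".join(
            [
                rid,
                kind,
                str(fate.status),
                str(fate.reason) if fate.reason else ".",
                fate.new_chrom or ".",
                str(fate.new_start) if fate.new_start is not None else ".",
                str(fate.new_end) if fate.new_end is not None else ".",
                str(fate.shift_start),
                str(fate.shift_end),
            ]
        )

    for i in range(n_segments):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        size = sizes[chrom]
        gaps = gap_cache[chrom]
        anchor_gap = len(gaps) > 0 and rng.random() < 0.3
        if anchor_gap:
            end1 = int(gaps[int(rng.integers(0, len(gaps)))]) + 1  # 1-based, in a gap
            start1 = max(1, end1 - int(rng.integers(50, 2_000)))
        else:
            start1 = int(rng.integers(1, size + 1))
            length = int(rng.integers(1, max(2, size // 8)))
            end1 = min(size, start1 + length - 1)
        sid = f"S{i:04d}"
        seg = Segment(sid, chrom, start1, end1)
        n_probes_col = int(rng.integers(1, 500))
        log2 = float(np.round(rng.normal(0.0, 0.6), 4))
        seg_lines.append("\t".join([sid, chrom, str(seg.start), str(seg.end), str(n_probes_col), f"{log2:.4f}"]))
        fate_lines.append(fate_row(sid, "segment", truth_convert_segment(truth, seg, qc, approx)))

    for i in range(n_probes):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        size = sizes[chrom]
        gaps = gap_cache[chrom]
        if len(gaps) > 0 and rng.random() < 0.2:
            pos1 = int(gaps[int(rng.integers(0, len(gaps)))]) + 1
        else:
            pos1 = int(rng.integers(1, size + 1))
        pid = f"P{i:05d}"
        probe = Probe(pid, chrom, pos1)
        log2 = float(np.round(rng.normal(0.0, 0.6), 4))
        probe_lines.append("\t".join([pid, chrom, str(pos1), f"{log2:.4f}"]))
        fate_lines.append(fate_row(pid, "probe", truth_convert_probe(truth, probe, approx)))

    return (
        "\n".join(seg_lines) + "\n",
        "\n".join(probe_lines) + "\n",
        "\n".join(fate_lines) + "\n",
    )
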