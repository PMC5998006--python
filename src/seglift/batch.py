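"""Batch conversion: input traversal, mirrored outputs, resumable runs,
and tab-separated logs.

A run takes either a directory tree or an explicit file list, assigns
each matching file a role (segment and/or probe) by filename pattern,
converts the files one by one and writes outputs at the same relative
path under the output root.  A plain-text ledger under the output root
records run parameters, a fingerprint of the chain file, and one line
per completed file; an interrupted run restarted with ``resume=True``
skips every file whose ledger entry is complete, and refuses to reuse a
ledger written under different parameters or a different chain file.

Outputs are written to temporaries and renamed into place before the
ledger line is appended, so a completed ledger entry always has its
outputs present and the resumed run is byte-identical to an
uninterrupted one.
"""

from __future__ import annotations

import fnmatch
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .chain import parse_chain_file
from .engine import build_index
from .segments import (
    FAILURE_LOG_COLUMNS,
    ApproxParams,
    ConversionStatus,
    QCParams,
    convert_probe_file,
    convert_segment_file,
    write_probe_outputs,
    write_segment_outputs,
)

__all__ = [
    "BatchConfig",
    "BatchConfigError",
    "LedgerMismatchError",
    "FileEntry",
    "RunLedger",
    "scan_inputs",
    "run_batch",
    "write_logs",
    "LEDGER_NAME",
    "SUMMARY_NAME",
    "FAILURE_LOG_NAME",
]

logger = logging.getLogger("seglift")

LEDGER_NAME = "seglift_ledger.tsv"
SUMMARY_NAME = "seglift_summary.tsv"
FAILURE_LOG_NAME = "seglift_failures.tsv"

_STATUS_ORDER = [
    ConversionStatus.DIRECT,
    ConversionStatus.APPROX,
    ConversionStatus.REJECTED,
    ConversionStatus.UNCONVERTIBLE,
]


class BatchConfigError(ValueError):
    """Invalid batch configuration (exit code 2 territory)."""


class LedgerMismatchError(RuntimeError):
    """Refusal to resume: the existing ledger was written under a
    different chain file or parameter set."""


@dataclass
class BatchConfig:
    output_root: Union[str, Path]
    chain_path: Union[str, Path]
    input_root: Optional[Union[str, Path]] = None
    file_list: Optional[Union[str, Path]] = None
    segment_pattern: Optional[str] = None
    probe_pattern: Optional[str] = None
    qc: QCParams = field(default_factory=QCParams)
    approx: ApproxParams = field(default_factory=ApproxParams)
    resume: bool = False

    def __post_init__(self) -> None:
        if (self.input_root is None) == (self.file_list is None):
            raise BatchConfigError("exactly one of input_root / file_list must be given")
        if self.segment_pattern is None and self.probe_pattern is None:
            raise BatchConfigError("at least one of segment_pattern / probe_pattern is required")
        self.output_root = Path(self.output_root)
        self.chain_path = Path(self.chain_path)
        if self.input_root is not None:
            self.input_root = Path(self.input_root)
            if self.input_root.resolve() == self.output_root.resolve():
                raise BatchConfigError("output_root must differ from input_root")
        if self.file_list is not None:
            self.file_list = Path(self.file_list)

    def meta(self) -> dict[str, str]:
        """Parameters that must match for a ledger to be resumable."""
        return {
            "chain_sha256": _sha256(self.chain_path),
            "beta": repr(self.qc.beta),
            "range": str(self.approx.range),
            "step_size": str(self.approx.step_size),
            "segment_pattern": self.segment_pattern or "-",
            "probe_pattern": self.probe_pattern or "-",
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class FileEntry:
    rel_path: str
    role: str  # "segment" | "probe"
    state: str  # "complete" | "error"
    tally: dict[ConversionStatus, int] = field(default_factory=dict)
    row_errors: int = 0
    error: Optional[str] = None

    @property
    def n_rows(self) -> int:
        return sum(self.tally.values())


@dataclass
class RunLedger:
    meta: dict[str, str]
    entries: list[FileEntry] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def had_errors(self) -> bool:
        return any(e.state == "error" for e in self.entries)

    def totals(self) -> dict[ConversionStatus, int]:
        out = {s: 0 for s in _STATUS_ORDER}
        for e in self.entries:
            for s, n in e.tally.items():
                out[s] += n
        return out


def scan_inputs(config: BatchConfig) -> list[tuple[str, str]]:
    """Enumerate ``(relative path, role)`` work items in deterministic
    (lexicographic) order.

    A file matching both patterns is returned once per role; files
    matching neither are ignored.  Missing file-list entries are logged
    as warnings, not errors.
    """
    candidates: list[str] = []
    if config.input_root is not None:
        root = Path(config.input_root)
        if not root.is_dir():
            raise BatchConfigError(f"input root {root} is not a readable directory")
        for p in sorted(root.rglob("*")):
            if p.is_file():
                candidates.append(p.relative_to(root).as_posix())
    else:
        flist = Path(config.file_list)
        if not flist.is_file():
            raise BatchConfigError(f"file list {flist} is not readable")
        base = flist.parent.resolve()
        for raw in flist.read_text(encoding="utf-8").splitlines():
            name = raw.strip()
            if not name or name.startswith("#"):
                continue
            p = Path(name)
            if not p.is_absolute():
                p = base / p
            if not p.is_file():
                logger.warning("file list entry not found, skipped: %s", name)
                continue
            try:
                rel = p.resolve().relative_to(base).as_posix()
            except ValueError:
                rel = p.name  # outside the list's directory: mirror by basename
            candidates.append(rel)

    entries: list[tuple[str, str]] = []
    for rel in candidates:
        base_name = Path(rel).name
        if config.segment_pattern and fnmatch.fnmatch(base_name, config.segment_pattern):
            entries.append((rel, "segment"))
        if config.probe_pattern and fnmatch.fnmatch(base_name, config.probe_pattern):
            entries.append((rel, "probe"))
    entries.sort()
    if not entries:
        logger.info("0 files matched the requested patterns")
    return entries


# --- ledger file I/O -------------------------------------------------------

_LEDGER_COLUMNS = ["path", "role", "state"] + [s.value for s in _STATUS_ORDER] + ["row_errors"]


def _ledger_header_lines(meta: dict[str, str]) -> list[str]:
    lines = ["#seglift-ledger\tv1"]
    lines += [f"#{k}\t{v}" for k, v in sorted(meta.items())]
    lines.append("\t".join(_LEDGER_COLUMNS))
    return lines


def _entry_line(e: FileEntry) -> str:
    return "\t".join(
        [e.rel_path, e.role, e.state]
        + [str(e.tally.get(s, 0)) for s in _STATUS_ORDER]
        + [str(e.row_errors)]
    )


def _read_ledger(path: Path) -> tuple[dict[str, str], list[FileEntry]]:
    meta: dict[str, str] = {}
    entries: list[FileEntry] = []
    for line in path.read_text(encoding="utf-8").splitlines():
        if line.startswith("#seglift-ledger"):
            continue
        if line.startswith("#"):
            k, _, v = line[1:].partition("\t")
            meta[k] = v
            continue
        cols = line.split("\t")
        if cols[:3] == ["path", "role", "state"] or len(cols) < len(_LEDGER_COLUMNS):
            continue
        tally = {s: int(cols[3 + i]) for i, s in enumerate(_STATUS_ORDER)}
        entries.append(
            FileEntry(
                rel_path=cols[0],
                role=cols[1],
                state=cols[2],
                tally=tally,
                row_errors=int(cols[3 + len(_STATUS_ORDER)]),
            )
        )
    return meta, entries


def _output_path(config: BatchConfig, rel: str, role: str, dual: bool) -> Path:
    # a file processed under both roles needs two distinct output names
    if dual and role == "probe":
        return Path(config.output_root) / (rel + ".as_probe")
    return Path(config.output_root) / rel


def run_batch(config: BatchConfig) -> RunLedger:
    """Run (or resume) a batch conversion; returns the populated ledger.

    A file failing mid-way is marked ``error`` and processing continues;
    :attr:`RunLedger.had_errors` reports whether any file failed.
    """
    out_root = Path(config.output_root)
    out_root.mkdir(parents=True, exist_ok=True)
    meta = config.meta()
    ledger_path = out_root / LEDGER_NAME

    completed: dict[tuple[str, str], FileEntry] = {}
    if config.resume and ledger_path.exists():
        old_meta, old_entries = _read_ledger(ledger_path)
        if old_meta != meta:
            diff = sorted(
                k for k in set(old_meta) | set(meta) if old_meta.get(k) != meta.get(k)
            )
            raise LedgerMismatchError(
                f"existing ledger was written under different settings ({', '.join(diff)}); "
                "refusing to resume — remove the ledger or rerun without resume"
            )
        for e in old_entries:
            if e.state == "complete":
                completed[(e.rel_path, e.role)] = e
    else:
        ledger_path.write_text("\n".join(_ledger_header_lines(meta)) + "\n", encoding="utf-8")

    with open(config.chain_path, "r", encoding="utf-8") as fh:
        chains = parse_chain_file(fh)
    index = build_index(chains)

    entries = scan_inputs(config)
    roles_per_path: dict[str, set[str]] = {}
    for rel, role in entries:
        roles_per_path.setdefault(rel, set()).add(role)

    ledger = RunLedger(meta=meta)
    for rel, role in entries:
        dual = len(roles_per_path[rel]) == 2
        prior = completed.get((rel, role))
        if prior is not None:
            ledger.entries.append(prior)
            continue
        src = (
            Path(config.input_root) / rel
            if config.input_root is not None
            else _resolve_listed(config, rel)
        )
        out_path = _output_path(config, rel, role, dual)
        try:
            if role == "segment":
                fr = convert_segment_file(src, index, config.qc, config.approx)
                write_segment_outputs(fr, out_path, rel)
            else:
                fr = convert_probe_file(src, index, config.approx)
                write_probe_outputs(fr, out_path, rel)
            entry = FileEntry(
                rel_path=rel,
                role=role,
                state="complete",
                tally=dict(fr.tally),
                row_errors=len(fr.errors),
            )
        except Exception as exc:  # file-level failure: continue with the next file
            logger.error("failed to convert %s (%s): %s", rel, role, exc)
            entry = FileEntry(rel_path=rel, role=role, state="error", error=str(exc))
        ledger.entries.append(entry)
        with open(ledger_path, "a", encoding="utf-8") as fh:
            fh.write(_entry_line(entry) + "\n")

    write_logs(ledger, out_root, config=config)
    return ledger


def _resolve_listed(config: BatchConfig, rel: str) -> Path:
    base = Path(config.file_list).parent
    p = base / rel
    if p.is_file():
        return p
    return Path(rel)  # basename fallback for out-of-tree entries


def write_logs(ledger: RunLedger, output_root: Union[str, Path], config: Optional[BatchConfig] = None) -> None:
    """Write the run-level summary and the aggregated per-row failure log.

    The failure log concatenates the per-file ``.log`` side files (which
    already carry file, line, coordinates, status, reason and shifts) in
    sorted entry order, so a resumed run reproduces it exactly.
    """
    out_root = Path(output_root)
    entries = sorted(ledger.entries, key=lambda e: (e.rel_path, e.role))

    lines = ["#seglift-summary\tv1"]
    lines += [f"#{k}\t{v}" for k, v in sorted(ledger.meta.items())]
    lines.append("\t".join(["path", "role", "state"] + [s.value for s in _STATUS_ORDER] + ["row_errors"]))
    for e in entries:
        lines.append(_entry_line(e))
    totals = ledger.totals()
    lines.append(
        "\t".join(
            ["TOTAL", "-", "-"]
            + [str(totals[s]) for s in _STATUS_ORDER]
            + [str(sum(e.row_errors for e in entries))]
        )
    )
    (out_root / SUMMARY_NAME).write_text("\n".join(lines) + "\n", encoding="utf-8")

    roles_per_path: dict[str, set[str]] = {}
    for e in entries:
        roles_per_path.setdefault(e.rel_path, set()).add(e.role)

    fail_lines = ["\t".join(FAILURE_LOG_COLUMNS)]
    for e in entries:
        if e.state != "complete":
            continue
        # locate the per-file log next to the converted output; the probe
        # role of a dual-role file lives under the ".as_probe" name
        if e.role == "probe" and len(roles_per_path[e.rel_path]) == 2:
            path = out_root / (e.rel_path + ".as_probe.log")
        else:
            path = out_root / (e.rel_path + ".log")
        if path.exists():
            fail_lines.extend(path.read_text(encoding="utf-8").splitlines())
    (out_root / FAILURE_LOG_NAME).write_text("\n".join(fail_lines) + "\n", encoding="utf-8")
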