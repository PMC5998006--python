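"""seglift: continuity-preserving liftover of copy-number segments and
probe positions between genome assemblies.

Instead of splitting a segment whose alignment is interrupted in the
target assembly, seglift converts only the segment's endpoints, rescues
endpoints without a direct image by a bounded neighbourhood search, and
applies a four-criterion quality control (both endpoints mapped, same
target chromosome, bounded length ratio) so that every converted segment
remains a single meaningful interval.
"""

from .chain import (
    Chain,
    ChainBlock,
    ChainHeader,
    ChainParseError,
    ChainValidationError,
    chains_to_text,
    parse_chain_file,
    parse_chain_text,
    validate_chain,
    write_chain_file,
)
from .engine import LiftIndex, MappedPosition, build_index, lift_position
from .segments import (
    ApproxParams,
    ConversionStatus,
    Probe,
    QCParams,
    Reason,
    Segment,
    approximate_position,
    convert_probe,
    convert_probe_file,
    convert_segment,
    convert_segment_file,
)
from .batch import BatchConfig, RunLedger, run_batch, scan_inputs, write_logs

__version__ = "1.0.0"

__all__ = [
    "Chain",
    "ChainBlock",
    "ChainHeader",
    "ChainParseError",
    "ChainValidationError",
    "parse_chain_file",
    "parse_chain_text",
    "validate_chain",
    "write_chain_file",
    "chains_to_text",
    "LiftIndex",
    "MappedPosition",
    "build_index",
    "lift_position",
    "ApproxParams",
    "QCParams",
    "ConversionStatus",
    "Reason",
    "Segment",
    "Probe",
    "approximate_position",
    "convert_segment",
    "convert_probe",
    "convert_segment_file",
    "convert_probe_file",
    "BatchConfig",
    "RunLedger",
    "run_batch",
    "scan_inputs",
    "write_logs",
    "example_chain_path",
]


def example_chain_path():
    """Path to the miniature chain file shipped with the package (a toy
    two-assembly example used in documentation and round-trip tests)."""
    from importlib.resources import files

    return files("seglift").joinpath("data/mini.chain")
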