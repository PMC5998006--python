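import io

import pytest

from seglift import build_index, parse_chain_text

IDENTITY_CHAIN = "chain 100 chr1 1000 + 0 1000 chr1 1000 + 0 1000 1\n1000\n"

# two aligned blocks separated by a 50 bp source gap and a 40 bp
# destination gap; source [0,100) -> dest [100,200), source [150,300) ->
# dest [240,390)
TWO_BLOCK_CHAIN = "chain 90 chr1 1000 + 0 300 chrA 900 + 100 390 2\n100\t50\t40\n150\n"

# minus-strand destination: source chr2[0,100) -> chrB plus [900,1000) reversed
MINUS_CHAIN = "chain 80 chr2 500 + 0 100 chrB 1000 - 0 100 3\n100\n"


@pytest.fixture(scope="session")
def identity_index():
    return build_index(parse_chain_text(IDENTITY_CHAIN))


@pytest.fixture(scope="session")
def two_block_index():
    return build_index(parse_chain_text(TWO_BLOCK_CHAIN))


@pytest.fixture(scope="session")
def minus_index():
    return build_index(parse_chain_text(MINUS_CHAIN))


def write_lines(path, lines):
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


@pytest.fixture
def seg_file(tmp_path):
    """Factory writing a segment table from (sample, chrom, start, end, *payload) rows."""

    def make(rows, name="input.seg", header="sample\tchrom\tstart\tend\tprobes\tlog2"):
        lines = [header] + ["\t".join(str(c) for c in row) for row in rows]
        return write_lines(tmp_path / name, lines)

    return make


@pytest.fixture
def probe_file(tmp_path):
    def make(rows, name="input.probes", header="probe_id\tchrom\tpos\tlog2"):
        lines = [header] + ["\t".join(str(c) for c in row) for row in rows]
        return write_lines(tmp_path / name, lines)

    return make
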