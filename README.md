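# seglift

Continuity-preserving conversion of copy-number segments and probe
positions between genome assemblies.

## The problem

Genomic studies accumulate data mapped to different releases of a
reference genome (hg19, hg38, ...), and integrative analyses need all
coordinates in one system. Generic liftover tools convert single
positions well, but when a *segment* — a contiguous interval carrying a
copy-number value — is no longer contiguous in the target assembly,
they split it into sub-segments mapped to scattered locations. For
copy-number variation (CNV) data the quantitative span of the region
matters more than base-level fidelity, so splitting amounts to data
loss.

seglift instead converts only the segment's **endpoints** through UCSC
chain files (parsed and indexed natively; no external liftOver binary),
rescues endpoints that have no direct image by a bounded neighbourhood
search, and then applies quality control so that every emitted segment
is still one meaningful interval. A converted segment must satisfy four
criteria:

1. `position_new_start ≠ ∅` — the start has an image;
2. `position_new_end ≠ ∅` — the end has an image;
3. `chromosome_new_start = chromosome_new_end`;
4. `1/β < length(old_segment)/length(new_segment) < β` (strict; default β = 2).

If criterion 1 or 2 fails directly, approximate conversion searches the
source positions `pos ± k·step_size` (for `k·step_size ≤ range`, nearest
first) for a liftable surrogate; if it still fails the segment is
**unconvertible**. If criterion 3 or 4 fails the segment is
**rejected**. Otherwise it is **directly** or **approximately
converted**. The four statuses partition every input file, and every
non-direct row is logged with a machine-readable reason.

Probe files (single positions) go through the same direct-then-
approximate conversion without the QC criteria.

## Worked example

```python
from seglift import (parse_chain_text, build_index, convert_segment,
                     Segment, QCParams, ApproxParams)

# one chain: source chr1[0,300) -> chrA, with a 50 bp source gap
chain = """chain 90 chr1 1000 + 0 300 chrA 900 + 100 390 2
100\t50\t40
150
"""
index = build_index(parse_chain_text(chain))

for seg in [Segment("S1", "chr1", 1, 90),
            Segment("S2", "chr1", 1, 121),
            Segment("S3", "chr1", 120, 130)]:
    res = convert_segment(seg, index, QCParams(beta=2.0),
                          ApproxParams(range=30, step_size=10))
    print(seg.sample_id, res.status.value,
          res.new_chrom, res.new_start, res.new_end,
          res.reason.value if res.reason else "-",
          res.approx_shift_start, res.approx_shift_end)
```

prints

```
S1 directly_converted chrA 101 190 - 0 0
S2 approximately_converted chrA 101 191 - 0 -30
S3 rejected None None None length_ratio_out_of_bounds -20 -30
```

S1 lies inside an aligned block and maps unchanged in length. S2 ends at
source base 121, inside the alignment gap `[101,150]`; the search finds
the nearest liftable position 30 bp to the left, so the segment is
approximately converted with a recorded end shift of −30. S3 has *both*
endpoints in the gap; both are rescued, but they collapse onto the same
target base, the old/new length ratio (11/1) exceeds β = 2, and QC
rejects the conversion.

## Batch use

```sh
seglift --input cohort/ --output cohort_hg38/ --chain hg19ToHg38.over.chain \
        --seg-pattern '*.seg' --probe-pattern '*.probes' \
        --beta 2 --range 10000 --step-size 100 [--resume]
```

seglift traverses the input tree (or a `--file-list`), converts every
file matching the patterns, and mirrors the directory structure under
the output root. Alongside each converted file it writes `.rejected`
and `.unconvertible` side files (original rows plus a reason column)
when non-empty. A run-level summary, a per-row failure log, and a
ledger are written at the output root; `--resume` restarts an
interrupted run, skipping completed files and refusing to reuse a
ledger written under a different chain file or parameter set. Exit
codes: 0 success, 1 any file-level error, 2 configuration error.

`seglift lift-point CHROM POS --chain FILE` maps a single 1-based
position for debugging.

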