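# beadmap

Tools for mapping single-cell images to physical plate positions in a
high-throughput imaging-flow-cytometry + robotic-dispensing workflow.

## The problem

An imaging flow cytometer records 3D images of cells at up to 1,000 cells/s;
the cells leaving the instrument are deposited by a robotic dispenser onto a
porous membrane filter in first-in-first-out (FIFO) order. In principle the
*i*-th imaged cell is the *i*-th cell on the plate, so every image has a
retrievable physical cell. In practice objects get trapped in the fluidics
(**deletion errors**) or locally scrambled by flow disruption
(**misplacement errors**), and a single uncaught error would shift every
subsequent assignment — errors propagate.

The method implemented here prevents that. Nonfluorescent marker beads of
three sizes — 10, 20 and 30 µm, written as the symbols **A**, **T**, **C** —
are premixed with the cells at a 2:1 cell:bead ratio, so the average number
of cells between adjacent beads is n̄ = 2. Both readouts (the cytometer and
the plate camera) then observe a bead-symbol sequence interleaved with
cells: the beads act like introns, the cells between them like exons. The
two symbol strings are globally aligned (Needleman–Wunsch, match +5 /
mismatch −4 / gap −8 by default), every discrepancy column of the consensus
map is classified as a deletion, insertion or misplacement and localized,
and each inter-marker gap is accepted only when both flanking beads match
cleanly *and* the imaged and plated cell counts in the gap agree. Cells in
accepted gaps are paired positionally; cells near detected errors are
dropped. The result is a mapping table — bead/cell, plate (x, y) in µm,
image reference, morphology features, cluster label — that trades a
15–20 % yield loss for near-zero misassignment.

The package is aimed at instrument builders and computational groups who
want to prototype, stress-test or extend this reconciliation scheme without
hardware: every input (event streams, error processes, plate images, cell
masks) can be generated synthetically with known ground truth.

## What's inside

| module | contents |
| --- | --- |
| `beadmap.stream_sim` | ground-truth FIFO streams; deletion / local-misplacement error processes with truth records |
| `beadmap.marker_codec` | event stream ⇄ marker-symbol sequence + per-gap cell partitions (JSON/FASTA export) |
| `beadmap.seq_align` | global alignment, consensus-map error classification, localization scoring against injected truth |
| `beadmap.cell_mapper` | drop rules, per-gap count verification, mapping table, retention/misassignment statistics |
| `beadmap.mc_experiments` | Monte Carlo detection-probability and retention curves |
| `beadmap.plate_vision` | synthetic plate images (pore background), pore removal, size-based detection, µm registration |
| `beadmap.morpho_cluster` | 2D/3D morphology features; from-scratch k-means (`MorphoKMeans`, sklearn-style fit/predict) |
| `beadmap.cli` | `beadmap` command: `simulate-stream`, `match`, `mc-curve`, `plate-detect`, `features`, `cluster` |

## Worked example

Simulate a run of 1,000 marker beads and 2,000 cells, corrupt the plate side
with 1 % deletions and 1 % local misplacements, then reconcile:

```python
from beadmap import (generate_stream, apply_deletion, apply_misplacement,
                     encode, global_align, classify_errors)
from beadmap import cell_mapper

stream = generate_stream(n_markers=1000, cell_marker_ratio=2.0, seed=42)
plate, td = apply_deletion(stream, 0.01, seed=43)
plate, tm = apply_misplacement(plate, 0.01, max_shift=5, seed=44)

ma, mb = encode(stream), encode(plate)
aln = global_align(ma.symbols, mb.symbols)
report = classify_errors(aln)

segs = cell_mapper.match_segments(ma, mb, aln, report)
pos = {e.uid: (e.source_index * 250.0, 0.0) for e in plate.events}
table = cell_mapper.build_mapping(segs, ma, mb, pos)
stats = cell_mapper.retention_stats(table, segs, ma,
                                    {e.uid: e.uid for e in stream.cells})
```

Output of this exact script:

```
events imaged: 3000  on plate: 2973  injected errors: 50
alignment score: 4891.0  reported errors: 8
error classes: {'deletion': 7, 'misplacement': 1}
retention: 0.886  misassignment: 0.0091
segments: {'matched': 929, 'dropped_count_mismatch': 53,
           'dropped_marker_error': 17, 'dropped_flanking': 2}
```

Reading it: 50 errors were injected across 3,000 events but only 8 touched
the 1,000 *marker beads* (the rest hit cells, where they surface as per-gap
count mismatches instead). The drop rules discard the 17 gaps adjacent to
bead errors, the 53 gaps whose cell counts disagree, and the two unverifiable
flanking gaps — keeping 88.6 % of the interior cells with a 0.9 %
misassignment rate, all of it from cells relocated *within* their own gap,
which count verification cannot see.

The same run from the shell:

```bash
beadmap simulate-stream --n-markers 1000 --deletion-rate 0.01 \
        --misplacement-rate 0.01 --seed 42 --out run
beadmap match run_truth.csv run_plate.csv --out run
```

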