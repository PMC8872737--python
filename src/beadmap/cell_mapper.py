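"""Map imaged cells to plate positions through verified inter-marker gaps.

After the two marker sequences are aligned and their discrepancies
classified, each inter-marker gap is accepted only when

* both flanking markers are cleanly matched columns of the alignment
  (same symbol, no gap), AND the matched markers are adjacent on *both*
  sequences (no error lies between them), AND
* the number of cells imaged in the gap equals the number of cells found
  on the plate in the gap.

Cells in accepted gaps are paired positionally (FIFO within the gap).
Cells adjacent to erroneous markers and cells whose gap counts disagree are
dropped, trading yield for accuracy: a wrong image-to-cell assignment is far
more damaging than a discarded cell.  Flanking gaps (before the first /
after the last marker) have no verifying marker pair and are always dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .marker_codec import MarkerSequence
from .seq_align import GAP, Alignment, ErrorReport

STATUS_MATCHED = "matched"
STATUS_COUNT = "dropped_count_mismatch"
STATUS_MARKER = "dropped_marker_error"
STATUS_FLANK = "dropped_flanking"


@dataclass
class Segment:
    """One inter-marker gap with its verification outcome.

    ``a_left``/``a_right`` are marker indices in the imaging-side sequence
    (None for flanking gaps); ``gap_a``/``gap_b`` index into the respective
    ``gap_counts`` arrays.
    """

    gap_a: int
    gap_b: int | None
    count_a: int
    count_b: int | None
    status: str
    a_left: int | None = None
    a_right: int | None = None
    b_left: int | None = None
    b_right: int | None = None


def match_segments(
    mseq_a: MarkerSequence,
    mseq_b: MarkerSequence,
    alignment: Alignment,
    report: ErrorReport,
) -> list[Segment]:
    """Apply the drop rules to every imaging-side gap.

    Returns one :class:`Segment` per gap of ``mseq_a`` (``len(symbols)+1``
    segments), so every imaged cell lands in exactly one segment.
    """
    if alignment.seq_a != mseq_a.symbols or alignment.seq_b != mseq_b.symbols:
        raise ValueError("alignment tracks do not match the marker sequences")

    # anchors: cleanly matched marker columns, as (index in a, index in b)
    map_a, map_b = alignment.index_maps()
    anchors: list[tuple[int, int]] = []
    for col, (a, b) in enumerate(zip(alignment.aligned_a, alignment.aligned_b)):
        if a != GAP and a == b:
            anchors.append((map_a[col], map_b[col]))

    n_a = len(mseq_a.symbols)
    segments: list[Segment] = []

    segments.append(
        Segment(gap_a=0, gap_b=None, count_a=mseq_a.gap_counts[0], count_b=None,
                status=STATUS_FLANK)
    )

    anchor_of_a = dict(anchors)
    for i in range(n_a - 1):  # gap between a-markers i and i+1 -> gap_counts[i+1]
        gap = i + 1
        count_a = mseq_a.gap_counts[gap]
        j_left = anchor_of_a.get(i)
        j_right = anchor_of_a.get(i + 1)
        if j_left is None or j_right is None or j_right != j_left + 1:
            # a flanking marker is erroneous, or an error sits between them
            segments.append(
                Segment(gap_a=gap, gap_b=None, count_a=count_a, count_b=None,
                        status=STATUS_MARKER, a_left=i, a_right=i + 1)
            )
            continue
        count_b = mseq_b.gap_counts[j_left + 1]
        status = STATUS_MATCHED if count_a == count_b else STATUS_COUNT
        segments.append(
            Segment(gap_a=gap, gap_b=j_left + 1, count_a=count_a, count_b=count_b,
                    status=status, a_left=i, a_right=i + 1, b_left=j_left,
                    b_right=j_right)
        )

    if n_a >= 1:
        segments.append(
            Segment(gap_a=n_a, gap_b=None, count_a=mseq_a.gap_counts[n_a],
                    count_b=None, status=STATUS_FLANK)
        )
    return segments


def build_mapping(
    segments: list[Segment],
    mseq_a: MarkerSequence,
    mseq_b: MarkerSequence,
    plate_positions: dict[int, tuple[float, float]],
    oof_uids: set[int] | None = None,
) -> pd.DataFrame:
    """Pair imaged cells with plate cells inside every matched segment.

    ``plate_positions`` maps plate-side uids to (x, y) in µm.  Within a
    matched segment the i-th imaged cell pairs with the i-th plate cell (the
    FIFO order both instruments preserve).  Out-of-focus cells are retained
    in the table with ``usable=False``: their position is known even though
    their image is too blurred to analyse.

    Returns a mapping table with one row per mapped entity (markers of
    matched segments included).
    """
    oof_uids = oof_uids or set()
    rows = []
    seen_markers: set[int] = set()
    for seg in segments:
        if seg.status != STATUS_MATCHED:
            continue
        for side, m_a, m_b in ((0, seg.a_left, seg.b_left), (1, seg.a_right, seg.b_right)):
            if m_a is not None and m_a not in seen_markers:
                seen_markers.add(m_a)
                rows.append(
                    {
                        "entity": "marker",
                        "symbol": mseq_a.symbols[m_a],
                        "image_uid": None,
                        "plate_uid": None,
                        "marker_index_a": m_a,
                        "marker_index_b": m_b,
                        "segment": seg.gap_a,
                        "usable": True,
                    }
                )
        members_a = mseq_a.gap_members[seg.gap_a]
        members_b = mseq_b.gap_members[seg.gap_b]
        if len(members_a) != len(members_b):  # matched implies equal counts
            raise ValueError("matched segment with unequal member lists")
        for uid_a, uid_b in zip(members_a, members_b):
            if uid_b not in plate_positions:
                raise ValueError(f"no plate position for plate cell uid {uid_b}")
            x, y = plate_positions[uid_b]
            if not (np.isfinite(x) and np.isfinite(y)):
                raise ValueError(f"non-finite plate position for uid {uid_b}")
            rows.append(
                {
                    "entity": "cell",
                    "symbol": "",
                    "image_uid": uid_a,
                    "plate_uid": uid_b,
                    "marker_index_a": None,
                    "marker_index_b": None,
                    "segment": seg.gap_a,
                    "usable": uid_a not in oof_uids,
                    "x_um": x,
                    "y_um": y,
                }
            )
    columns = [
        "entity", "symbol", "image_uid", "plate_uid", "marker_index_a",
        "marker_index_b", "segment", "x_um", "y_um", "usable",
    ]
    return pd.DataFrame(rows, columns=columns)


def retention_stats(
    table: pd.DataFrame,
    segments: list[Segment],
    mseq_a: MarkerSequence,
    truth_pairs: dict[int, int] | None = None,
) -> dict:
    """Yield/accuracy summary of a mapping run.

    ``truth_pairs`` maps imaged-cell uid -> true plate uid (available in
    simulations; identity when both streams carry the source uids).

    * ``retention_fraction``: mapped cells / imaged cells in interior
      (verifiable) gaps.
    * ``retention_fraction_total``: mapped cells / all imaged cells,
      flanking gaps included.
    * ``misassignment_rate``: wrongly paired / mapped (requires truth).
    * ``usable_fraction``: mapped cells with a usable (in-focus) image.
    """
    cells = table[table["entity"] == "cell"]
    n_mapped = len(cells)
    n_interior = sum(mseq_a.interior_gap_counts)
    n_total = mseq_a.n_cells

    mapped_uids = set(cells["image_uid"].astype(int)) if n_mapped else set()
    interior_uids = {u for g in mseq_a.gap_members[1:-1] for u in g}
    if truth_pairs is not None and not mapped_uids <= set(truth_pairs):
        raise ValueError("mapping table contains uids absent from ground truth")
    if not mapped_uids <= interior_uids:
        raise ValueError("mapping table contains non-interior cells")

    stats = {
        "n_imaged_cells": n_total,
        "n_interior_cells": n_interior,
        "n_mapped": n_mapped,
        "retention_fraction": (n_mapped / n_interior) if n_interior else 1.0,
        "retention_fraction_total": (n_mapped / n_total) if n_total else 1.0,
        "usable_fraction": (float(cells["usable"].mean()) if n_mapped else 1.0),
        "segment_statuses": {
            s: int(sum(1 for seg in segments if seg.status == s))
            for s in (STATUS_MATCHED, STATUS_COUNT, STATUS_MARKER, STATUS_FLANK)
        },
    }
    if truth_pairs is not None:
        wrong = sum(
            1
            for uid_a, uid_b in zip(cells["image_uid"], cells["plate_uid"])
            if truth_pairs[int(uid_a)] != int(uid_b)
        )
        stats["misassignment_rate"] = (wrong / n_mapped) if n_mapped else 0.0
    return stats
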