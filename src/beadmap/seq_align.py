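"""Global alignment of marker-bead sequences and error classification.

The imaging readout and the plate readout each yield a string over {A, T, C}
(10/20/30 µm beads).  The two strings are globally aligned (Needleman-Wunsch
with linear gap penalties), and every discrepancy column of the consensus map
is classified:

* a bead present in the imaging track but missing on the plate -> deletion
  (the bead was trapped somewhere between imaging and dispensing);
* a bead on the plate with no imaging counterpart -> insertion;
* a deletion and an insertion of the same symbol close to each other, or a
  complementary adjacent mismatch pair (x,y)(y,x), or a residual isolated
  mismatch -> misplacement (a FIFO-order violation moved the bead locally).

`match_truth` scores a classified report against injected ground truth: an
injected error counts as located when some reported error lands within a
positional tolerance of its true site.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .stream_sim import ALPHABET, ErrorTruth

GAP = "-"

#: Columns within which a deletion/insertion pair of the same symbol is
#: interpreted as one locally misplaced bead.
DEFAULT_PAIR_WINDOW = 10
#: Positions of slack when deciding whether a reported error localizes a
#: true one; absorbs placement ambiguity inside homopolymer runs.
DEFAULT_TOLERANCE = 2


@dataclass(frozen=True)
class ScoringScheme:
    """Match/mismatch/linear-gap scores.

    Defaults (+5/−4/−8) mirror the NUC44 substitution values and default gap
    penalty of the MATLAB bioinformatics-toolbox aligner commonly used for
    this kind of bead-sequence matching.
    """

    match: float = 5.0
    mismatch: float = -4.0
    gap: float = -8.0

    def __post_init__(self):
        if not self.match > self.mismatch:
            raise ValueError("match score must exceed mismatch score")
        if not self.gap < 0:
            raise ValueError("gap penalty must be negative")


@dataclass
class Alignment:
    """A global alignment stored as two equal-length gapped strings."""

    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self):
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped tracks differ in length")
        if any(a == GAP and b == GAP for a, b in zip(self.aligned_a, self.aligned_b)):
            raise ValueError("alignment contains a gap-gap column")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.aligned_a, self.aligned_b))

    @property
    def seq_a(self) -> str:
        return self.aligned_a.replace(GAP, "")

    @property
    def seq_b(self) -> str:
        return self.aligned_b.replace(GAP, "")

    def index_maps(self) -> tuple[list[int], list[int]]:
        """Per-column indices into seq_a and seq_b.

        A gap column carries the index of the next real symbol on that track
        (i.e. the boundary position where the missing symbol would sit).
        """
        ia = ib = 0
        map_a, map_b = [], []
        for a, b in zip(self.aligned_a, self.aligned_b):
            map_a.append(ia)
            map_b.append(ib)
            if a != GAP:
                ia += 1
            if b != GAP:
                ib += 1
        return map_a, map_b

    def pretty(self, width: int = 60) -> str:
        """Three-line consensus rendering (a / bars / b)."""
        bars = "".join(
            "|" if a == b else " " for a, b in zip(self.aligned_a, self.aligned_b)
        )
        chunks = []
        for i in range(0, len(self.aligned_a), width):
            chunks.append(
                "\n".join(
                    (
                        self.aligned_a[i : i + width],
                        bars[i : i + width],
                        self.aligned_b[i : i + width],
                    )
                )
            )
        return "\n\n".join(chunks)

    def to_dict(self) -> dict:
        return {"aligned_a": self.aligned_a, "aligned_b": self.aligned_b, "score": self.score}


@dataclass(frozen=True)
class AlignmentError:
    """One classified discrepancy in the consensus map.

    ``pos_a``/``pos_b`` are 0-based indices into the ungapped imaging/plate
    sequences (for gap columns: the boundary index on the gapped track).
    """

    error_class: str  # "deletion" | "insertion" | "misplacement"
    symbol: str
    pos_a: int | None = None
    pos_b: int | None = None
    column: int | None = None
    #: Localization spans: the maximal run of identical symbols containing the
    #: site, on each sequence.  A symbol deleted from inside such a run could
    #: have come from any position in it — all placements give the same
    #: alignment — so the error is located as the whole run.
    span_a: tuple[int, int] | None = None
    span_b: tuple[int, int] | None = None

    def to_dict(self) -> dict:
        return {
            "error_class": self.error_class,
            "symbol": self.symbol,
            "pos_a": self.pos_a,
            "pos_b": self.pos_b,
            # 1-based for human-readable output, matching how consensus-map
            # positions are conventionally counted
            "position_1based": (self.pos_a if self.pos_a is not None else self.pos_b) + 1,
        }


@dataclass
class ErrorReport:
    errors: list[AlignmentError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.errors)

    def by_class(self, error_class: str) -> list[AlignmentError]:
        return [e for e in self.errors if e.error_class == error_class]

    def to_dicts(self) -> list[dict]:
        return [e.to_dict() for e in self.errors]


def _validate_sequence(seq: str, name: str) -> None:
    bad = set(seq) - set(ALPHABET)
    if bad:
        raise ValueError(f"{name} contains symbols outside {ALPHABET}: {sorted(bad)}")


def _make_aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap
    aligner.extend_gap_score = scoring.gap
    return aligner


def global_align(
    seq_a: str, seq_b: str, scoring: ScoringScheme | None = None
) -> Alignment:
    """Maximum-score global alignment of two marker sequences.

    Needleman-Wunsch with linear gap penalties; among co-optimal alignments
    the first traceback is returned, so output is deterministic for fixed
    inputs and scoring.
    """
    scoring = scoring or ScoringScheme()
    _validate_sequence(seq_a, "seq_a")
    _validate_sequence(seq_b, "seq_b")
    if not seq_a and not seq_b:
        return Alignment("", "", 0.0)
    if not seq_a:
        return Alignment(GAP * len(seq_b), seq_b, scoring.gap * len(seq_b))
    if not seq_b:
        return Alignment(seq_a, GAP * len(seq_a), scoring.gap * len(seq_a))

    aln = _make_aligner(scoring).align(seq_a, seq_b)[0]
    return Alignment(str(aln[0]), str(aln[1]), float(aln.score))


def classify_errors(
    alignment: Alignment, pair_window: int = DEFAULT_PAIR_WINDOW
) -> ErrorReport:
    """Classify every discrepancy column of an alignment.

    Candidate deletions (symbol over gap) and insertions (gap over symbol)
    of the same symbol within ``pair_window`` columns merge into one
    misplacement; adjacent complementary mismatch columns (x,y)(y,x) — the
    signature of a swapped neighbour pair — merge likewise; remaining
    isolated mismatches are misplacements; leftover unpaired candidates keep
    their deletion/insertion class.
    """
    pair_window = int(pair_window)
    if pair_window < 1:
        raise ValueError("pair_window must be >= 1")
    map_a, map_b = alignment.index_maps()
    seq_a, seq_b = alignment.seq_a, alignment.seq_b

    def run_span(seq: str, pos: int, symbol: str) -> tuple[int, int]:
        # maximal run of `symbol` in `seq` containing/abutting index `pos`
        pos = min(max(pos, 0), max(len(seq) - 1, 0))
        if not seq:
            return (pos, pos)
        lo = hi = pos
        if seq[pos] != symbol:
            return (pos, pos)
        while lo > 0 and seq[lo - 1] == symbol:
            lo -= 1
        while hi < len(seq) - 1 and seq[hi + 1] == symbol:
            hi += 1
        return (lo, hi)

    deletions: list[tuple[int, str, int, int]] = []  # (column, symbol, pos_a, pos_b)
    insertions: list[tuple[int, str, int, int]] = []
    mismatches: list[tuple[int, str, str, int, int]] = []
    for col, (a, b) in enumerate(zip(alignment.aligned_a, alignment.aligned_b)):
        if a == b:
            continue
        if b == GAP:
            deletions.append((col, a, map_a[col], map_b[col]))
        elif a == GAP:
            insertions.append((col, b, map_a[col], map_b[col]))
        else:
            mismatches.append((col, a, b, map_a[col], map_b[col]))

    errors: list[AlignmentError] = []

    # complementary adjacent mismatch pairs -> one misplacement
    used = [False] * len(mismatches)
    for i in range(len(mismatches) - 1):
        if used[i] or used[i + 1]:
            continue
        c1, a1, b1, pa1, pb1 = mismatches[i]
        c2, a2, b2, pa2, pb2 = mismatches[i + 1]
        if c2 == c1 + 1 and a1 == b2 and a2 == b1:
            used[i] = used[i + 1] = True
            errors.append(
                AlignmentError(
                    "misplacement",
                    symbol=a1,
                    pos_a=pa1,
                    pos_b=pb2,
                    column=c1,
                    span_a=(pa1, pa2),
                    span_b=(pb1, pb2),
                )
            )

    # deletion/insertion pairs of the same symbol within the window
    ins_free = [True] * len(insertions)
    for col_d, sym_d, pa_d, _pb_d in deletions:
        best = None
        for j, (col_i, sym_i, _pa_i, pb_i) in enumerate(insertions):
            if not ins_free[j] or sym_i != sym_d:
                continue
            dist = abs(col_i - col_d)
            if dist <= pair_window and (best is None or dist < best[0]):
                best = (dist, j, pb_i)
        if best is not None:
            _, j, pb_i = best
            ins_free[j] = False
            errors.append(
                AlignmentError(
                    "misplacement",
                    symbol=sym_d,
                    pos_a=pa_d,
                    pos_b=pb_i,
                    column=col_d,
                    span_a=run_span(seq_a, pa_d, sym_d),
                    span_b=run_span(seq_b, pb_i, sym_d),
                )
            )
        else:
            errors.append(
                AlignmentError(
                    "deletion",
                    symbol=sym_d,
                    pos_a=pa_d,
                    pos_b=None,
                    column=col_d,
                    span_a=run_span(seq_a, pa_d, sym_d),
                )
            )

    for j, (col_i, sym_i, pa_i, pb_i) in enumerate(insertions):
        if ins_free[j]:
            errors.append(
                AlignmentError(
                    "insertion",
                    symbol=sym_i,
                    pos_a=None,
                    pos_b=pb_i,
                    column=col_i,
                    span_b=run_span(seq_b, pb_i, sym_i),
                )
            )

    # residual isolated mismatches: a bead is simultaneously "missing" here
    # and "extra" there — report as misplacement at this site
    for i, (col, a, b, pa, pb) in enumerate(mismatches):
        if not used[i]:
            errors.append(
                AlignmentError(
                    "misplacement",
                    symbol=a,
                    pos_a=pa,
                    pos_b=pb,
                    column=col,
                    span_a=(pa, pa),
                    span_b=(pb, pb),
                )
            )

    errors.sort(key=lambda e: e.column)
    return ErrorReport(errors)


@dataclass
class DetectionOutcome:
    """Per-true-error detection flags and the summary probability."""

    detected: list[bool]
    detection_probability: float
    tolerance: int


def match_truth(
    truth: list[ErrorTruth],
    report: ErrorReport,
    tolerance: int = DEFAULT_TOLERANCE,
) -> DetectionOutcome:
    """Score a classified error report against injected ground truth.

    A true error is *located* when any reported error lies within
    ``tolerance`` positions of it: deletions are compared on the imaging
    (template) coordinate; misplacements on either the removal site
    (template coordinate) or the re-insertion site (plate coordinate).
    With no injected errors the probability is 1.0 by convention.
    """
    tolerance = int(tolerance)
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")

    def spans(side: str) -> np.ndarray:
        out = []
        for e in report.errors:
            pos = e.pos_a if side == "a" else e.pos_b
            span = e.span_a if side == "a" else e.span_b
            if span is not None:
                out.append(span)
            elif pos is not None:
                out.append((pos, pos))
        if not out:
            return np.empty((0, 2), dtype=int)
        arr = np.array(out, dtype=int)
        return arr[np.argsort(arr[:, 0])]

    spans_a, spans_b = spans("a"), spans("b")

    def near(sorted_spans: np.ndarray, x: int) -> bool:
        # distance from x to interval [lo, hi] <= tolerance, for any span
        if sorted_spans.size == 0:
            return False
        lo, hi = sorted_spans[:, 0], sorted_spans[:, 1]
        i = int(np.searchsorted(lo, x, side="right"))
        j0, j1 = max(0, i - 64), min(len(lo), i + 64)
        d = np.maximum(lo[j0:j1] - x, x - hi[j0:j1])
        return bool(np.any(d <= tolerance))

    detected = []
    for t in truth:
        if t.error_type == "deletion":
            hit = near(spans_a, t.from_index)
        else:
            hit = near(spans_a, t.from_index) or near(spans_b, t.to_index)
        detected.append(hit)
    prob = float(np.mean(detected)) if detected else 1.0
    return DetectionOutcome(detected=detected, detection_probability=prob, tolerance=tolerance)
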