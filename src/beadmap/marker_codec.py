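"""Encode a FIFO event stream as a marker-symbol sequence with per-gap counts.

The marker beads play the role of introns: a stream of cells and beads is
summarised as the string of bead symbols over {A, T, C} plus, for every gap
(before the first bead, between each adjacent pair, after the last bead), the
ordered cells that fell in it.  The symbol strings from the imaging readout
and the plate readout are what the alignment stage compares; the gap counts
are what the mapping stage verifies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .stream_sim import ALPHABET, Event, EventStream


@dataclass
class MarkerSequence:
    """Marker symbols plus the partition of cells into inter-marker gaps.

    ``gap_counts`` has length ``len(symbols) + 1``; entries 0 and -1 are the
    flanking gaps, which no marker pair brackets and which the mapping stage
    therefore always drops.
    """

    symbols: str
    gap_counts: list[int]
    gap_members: list[list[int]]  # per-gap ordered cell uids
    gap_oof_counts: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.gap_oof_counts:
            self.gap_oof_counts = [0] * len(self.gap_counts)
        self.validate()

    def validate(self) -> None:
        bad = set(self.symbols) - set(ALPHABET)
        if bad:
            raise ValueError(f"symbols outside alphabet {ALPHABET}: {sorted(bad)}")
        n_gaps = len(self.symbols) + 1
        if len(self.gap_counts) != n_gaps:
            raise ValueError(
                f"gap_counts must have length {n_gaps}, got {len(self.gap_counts)}"
            )
        if len(self.gap_members) != n_gaps or len(self.gap_oof_counts) != n_gaps:
            raise ValueError("gap_members/gap_oof_counts length mismatch")
        for c, members, oof in zip(self.gap_counts, self.gap_members, self.gap_oof_counts):
            if c < 0 or len(members) != c:
                raise ValueError("gap_counts inconsistent with gap_members")
            if not 0 <= oof <= c:
                raise ValueError("gap_oof_counts out of range")

    @property
    def n_cells(self) -> int:
        return sum(self.gap_counts)

    @property
    def interior_gap_counts(self) -> list[int]:
        """Counts of gaps bracketed by a marker pair (verifiable gaps)."""
        return self.gap_counts[1:-1]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "symbols": self.symbols,
                    "gap_counts": self.gap_counts,
                    "gap_members": self.gap_members,
                    "gap_oof_counts": self.gap_oof_counts,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "MarkerSequence":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_fasta(self, path, record_id: str = "markers") -> None:
        """Write the symbol string as a single FASTA record.

        Lets third-party alignment tools be used as external cross-checks.
        """
        with open(path, "w") as fh:
            fh.write(f">{record_id}\n")
            for i in range(0, len(self.symbols), 70):
                fh.write(self.symbols[i : i + 70] + "\n")


def encode(stream: EventStream) -> MarkerSequence:
    """Extract the marker-symbol sequence and per-gap cell partition."""
    symbols: list[str] = []
    gap_members: list[list[int]] = [[]]
    gap_oof: list[int] = [0]
    for e in stream.events:
        if e.kind == "marker":
            if e.symbol not in ALPHABET:  # defensive: Event enforces this too
                raise ValueError(f"marker event {e.uid} has no valid symbol")
            symbols.append(e.symbol)
            gap_members.append([])
            gap_oof.append(0)
        else:
            gap_members[-1].append(e.uid)
            if e.out_of_focus:
                gap_oof[-1] += 1
    return MarkerSequence(
        symbols="".join(symbols),
        gap_counts=[len(g) for g in gap_members],
        gap_members=gap_members,
        gap_oof_counts=gap_oof,
    )


def decode(mseq: MarkerSequence, oof_uids: set[int] | None = None) -> EventStream:
    """Reconstruct an event stream whose :func:`encode` equals ``mseq``.

    Marker uids are synthesised above the largest cell uid.  Out-of-focus
    flags are restored from ``oof_uids`` when given, otherwise assigned to
    the first ``gap_oof_counts[i]`` cells of each gap.
    """
    mseq.validate()
    all_cells = [u for g in mseq.gap_members for u in g]
    next_uid = (max(all_cells) + 1) if all_cells else 0

    events: list[Event] = []
    idx = 0

    def emit_gap(g: int) -> None:
        nonlocal idx
        for k, uid in enumerate(mseq.gap_members[g]):
            oof = uid in oof_uids if oof_uids is not None else k < mseq.gap_oof_counts[g]
            events.append(Event(uid=uid, kind="cell", source_index=idx, out_of_focus=oof))
            idx += 1

    emit_gap(0)
    for i, sym in enumerate(mseq.symbols):
        events.append(Event(uid=next_uid, kind="marker", source_index=idx, symbol=sym))
        next_uid += 1
        idx += 1
        emit_gap(i + 1)
    stream = EventStream(events, metadata={"decoded": True})
    stream.validate()
    return stream
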