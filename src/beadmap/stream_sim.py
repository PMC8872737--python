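"""Simulate FIFO event streams of cells and marker beads.

A 3D imaging flow cytometer records objects in the order they pass the
interrogation area; a robotic dispenser then deposits the same objects onto a
porous filter plate in first-in-first-out order.  Interleaved marker beads of
10/20/30 µm (symbols A/T/C) anchor the two readouts to each other.  This
module generates ground-truth streams and corrupts them with the two error
processes the instrument exhibits: *deletion* (an object trapped in tubing,
present in one readout and missing from the other) and *misplacement* (a
local violation of FIFO order caused by disrupted laminar flow).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ALPHABET = ("A", "T", "C")

#: Default local misplacement range, in stream positions.  Order scrambling
#: in laminar flow is local: a bead overtakes or falls behind a handful of
#: neighbours, it does not teleport across the run.
DEFAULT_MAX_SHIFT = 5


@dataclass(frozen=True)
class Event:
    """One object in the FIFO stream: either a cell or a marker bead."""

    uid: int
    kind: str  # "cell" | "marker"
    source_index: int
    symbol: str | None = None  # A/T/C, markers only
    out_of_focus: bool = False  # cells only; image unusable, order intact

    def __post_init__(self):
        if self.kind not in ("cell", "marker"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "marker":
            if self.symbol not in ALPHABET:
                raise ValueError(
                    f"marker event requires a symbol in {ALPHABET}, got {self.symbol!r}"
                )
        elif self.symbol is not None:
            raise ValueError("cell events carry no symbol")


@dataclass
class EventStream:
    """Ordered FIFO record of events plus the parameters that generated it."""

    events: list[Event]
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, EventStream) and self.events == other.events

    def validate(self) -> None:
        uids = [e.uid for e in self.events]
        if len(set(uids)) != len(uids):
            raise ValueError("event uids are not unique")
        idx = [e.source_index for e in self.events]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("source_index must be strictly increasing")

    @property
    def markers(self) -> list[Event]:
        return [e for e in self.events if e.kind == "marker"]

    @property
    def cells(self) -> list[Event]:
        return [e for e in self.events if e.kind == "cell"]

    def symbols(self) -> str:
        """Marker symbols in stream order."""
        return "".join(e.symbol for e in self.markers)

    # -- serialization ----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "source_index": [e.source_index for e in self.events],
                "uid": [e.uid for e in self.events],
                "kind": [e.kind for e in self.events],
                "symbol": [e.symbol if e.symbol is not None else "" for e in self.events],
                "out_of_focus": [e.out_of_focus for e in self.events],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metadata: dict | None = None) -> "EventStream":
        required = {"source_index", "uid", "kind", "symbol", "out_of_focus"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"event-stream table missing columns: {sorted(missing)}")
        events = []
        for row in df.itertuples(index=False):
            symbol = row.symbol if isinstance(row.symbol, str) and row.symbol else None
            events.append(
                Event(
                    uid=int(row.uid),
                    kind=str(row.kind),
                    source_index=int(row.source_index),
                    symbol=symbol,
                    out_of_focus=bool(row.out_of_focus),
                )
            )
        stream = cls(events, metadata or {})
        stream.validate()
        return stream

    @classmethod
    def from_csv(cls, path) -> "EventStream":
        return cls.from_frame(pd.read_csv(path, keep_default_na=False))

    def to_json(self, path) -> None:
        payload = {"metadata": self.metadata, "events": self.to_frame().to_dict("records")}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "EventStream":
        with open(path) as fh:
            payload = json.load(fh)
        return cls.from_frame(pd.DataFrame(payload["events"]), payload.get("metadata"))


@dataclass(frozen=True)
class ErrorTruth:
    """Ground-truth record of one injected error."""

    error_type: str  # "deletion" | "misplacement"
    uid: int
    from_index: int
    to_index: int | None = None  # misplacement only

    def __post_init__(self):
        if self.error_type not in ("deletion", "misplacement"):
            raise ValueError(f"unknown error type {self.error_type!r}")
        if self.error_type == "misplacement":
            if self.to_index is None:
                raise ValueError("misplacement requires to_index")
            if self.to_index == self.from_index:
                raise ValueError("misplacement must change position")
        elif self.to_index is not None:
            raise ValueError("deletion has no to_index")


def truth_to_jsonl(truth: Sequence[ErrorTruth], path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(
                json.dumps(
                    {
                        "error_type": t.error_type,
                        "uid": t.uid,
                        "from_index": t.from_index,
                        "to_index": t.to_index,
                    }
                )
                + "\n"
            )


def truth_from_jsonl(path) -> list[ErrorTruth]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(ErrorTruth(**d))
    return out


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must be a probability in [0, 1], got {value}")
    return value


def generate_stream(
    n_markers: int,
    cell_marker_ratio: float = 2.0,
    symbol_weights: Iterable[float] = (1 / 3, 1 / 3, 1 / 3),
    p_out_of_focus: float = 0.0,
    seed: int | None = None,
) -> EventStream:
    """Generate a ground-truth FIFO stream of markers interleaved with cells.

    ``round(cell_marker_ratio * n_markers)`` cells are placed uniformly at
    random among ``n_markers`` marker beads (all orderings of the mixed queue
    equally likely).  Marker symbols are drawn i.i.d. from
    ``symbol_weights`` over (A, T, C).  The default 2:1 cell:marker ratio
    keeps the average number of cells between adjacent markers at 2, small
    enough to verify each inter-marker gap by a simple count comparison.
    """
    n_markers = int(n_markers)
    if n_markers < 1:
        raise ValueError("n_markers must be >= 1")
    ratio = float(cell_marker_ratio)
    if not np.isfinite(ratio) or ratio < 0:
        raise ValueError("cell_marker_ratio must be finite and non-negative")
    weights = np.asarray(list(symbol_weights), dtype=float)
    if weights.shape != (3,) or not np.all(np.isfinite(weights)) or np.any(weights < 0):
        raise ValueError("symbol_weights must be 3 non-negative finite values")
    if not np.isclose(weights.sum(), 1.0):
        raise ValueError("symbol_weights must sum to 1")
    p_oof = _check_prob(p_out_of_focus, "p_out_of_focus")

    rng = np.random.default_rng(seed)
    n_cells = int(round(ratio * n_markers))
    n_total = n_markers + n_cells

    marker_positions = set(rng.choice(n_total, size=n_markers, replace=False).tolist())
    symbols = rng.choice(ALPHABET, size=n_markers, p=weights)
    oof = rng.random(n_cells) < p_oof

    events: list[Event] = []
    im = ic = 0
    for pos in range(n_total):
        if pos in marker_positions:
            events.append(Event(uid=pos, kind="marker", source_index=pos, symbol=str(symbols[im])))
            im += 1
        else:
            events.append(
                Event(uid=pos, kind="cell", source_index=pos, out_of_focus=bool(oof[ic]))
            )
            ic += 1
    return EventStream(
        events,
        metadata={
            "n_markers": n_markers,
            "cell_marker_ratio": ratio,
            "symbol_weights": weights.tolist(),
            "p_out_of_focus": p_oof,
            "seed": seed,
        },
    )


def _renumber(events: list[Event]) -> list[Event]:
    return [
        Event(
            uid=e.uid,
            kind=e.kind,
            source_index=i,
            symbol=e.symbol,
            out_of_focus=e.out_of_focus,
        )
        for i, e in enumerate(events)
    ]


def apply_deletion(
    stream: EventStream, rate: float, seed: int | None = None
) -> tuple[EventStream, list[ErrorTruth]]:
    """Remove each event independently with probability ``rate``.

    Models objects trapped inside the fluidics between imaging and
    dispensing.  Surviving events keep their relative order;
    ``from_index`` in each truth record is the event's position in the
    input stream.
    """
    rate = _check_prob(rate, "rate")
    rng = np.random.default_rng(seed)
    drop = rng.random(len(stream.events)) < rate

    kept: list[Event] = []
    truth: list[ErrorTruth] = []
    for i, e in enumerate(stream.events):
        if drop[i]:
            truth.append(ErrorTruth(error_type="deletion", uid=e.uid, from_index=i))
        else:
            kept.append(e)
    out = EventStream(_renumber(kept), metadata={**stream.metadata, "deletion_rate": rate})
    return out, truth


def apply_misplacement(
    stream: EventStream,
    rate: float,
    max_shift: int = DEFAULT_MAX_SHIFT,
    seed: int | None = None,
) -> tuple[EventStream, list[ErrorTruth]]:
    """Locally relocate each event independently with probability ``rate``.

    A selected event is removed and re-inserted at a uniformly random
    nonzero offset within ``[-max_shift, +max_shift]`` (clamped to the
    stream bounds), modelling a bead overtaking or falling behind its
    neighbours.  No event is lost.  Moves are applied sequentially in
    stream order; each truth record stores the position at removal time
    and the position after re-insertion.
    """
    rate = _check_prob(rate, "rate")
    max_shift = int(max_shift)
    if max_shift < 1:
        raise ValueError("max_shift must be >= 1")
    rng = np.random.default_rng(seed)
    move = rng.random(len(stream.events)) < rate

    work = list(stream.events)
    selected_uids = [e.uid for i, e in enumerate(stream.events) if move[i]]
    truth: list[ErrorTruth] = []
    n = len(work)
    if n < 2:
        selected_uids = []
    pos_of = {e.uid: i for i, e in enumerate(work)}
    for uid in selected_uids:
        pos = pos_of[uid]
        offsets = [
            d
            for d in range(-max_shift, max_shift + 1)
            if d != 0 and min(max(pos + d, 0), n - 1) != pos
        ]
        if not offsets:
            continue
        d = int(rng.choice(offsets))
        target = min(max(pos + d, 0), n - 1)
        elem = work.pop(pos)
        work.insert(target, elem)
        truth.append(
            ErrorTruth(error_type="misplacement", uid=uid, from_index=pos, to_index=target)
        )
        lo, hi = (target, pos) if target < pos else (pos, target)
        for j in range(lo, hi + 1):
            pos_of[work[j].uid] = j
    out = EventStream(
        _renumber(work),
        metadata={**stream.metadata, "misplacement_rate": rate, "max_shift": max_shift},
    )
    return out, truth
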