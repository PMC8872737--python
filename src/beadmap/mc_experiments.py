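"""Monte Carlo studies: error-detection probability and cell retention.

Reproduces the simulation design behind the detection-probability-versus-
error-rate curves: a template sequence of 10,000 symbols over {A, T, C} is
corrupted at a given per-symbol error rate, the corrupted copy is globally
aligned back to the template, discrepancies are classified, and an injected
error counts as located when a reported error falls within a positional
tolerance of its true site.  The retention study runs the full pipeline
(stream simulation -> encoding -> alignment -> drop rules -> mapping) and
summarises the yield/accuracy trade-off of the drop rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cell_mapper, marker_codec, stream_sim
from .seq_align import (
    DEFAULT_PAIR_WINDOW,
    DEFAULT_TOLERANCE,
    ScoringScheme,
    classify_errors,
    global_align,
    match_truth,
)

ERROR_KINDS = ("deletion", "misplacement", "both")


@dataclass
class DetectionCurve:
    """Detection probability versus error rate (mean over replicates)."""

    error_kind: str
    rates: list[float]
    detection_probability: list[float]
    std_error: list[float]
    n_symbols: int
    replicates: int
    tolerance: int
    seed: int | None
    max_shift: int = stream_sim.DEFAULT_MAX_SHIFT
    per_replicate: list[list[float]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.rates) != len(self.detection_probability):
            raise ValueError("rates and probabilities differ in length")
        if any(not 0.0 <= p <= 1.0 for p in self.detection_probability):
            raise ValueError("detection probabilities must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rate": self.rates,
                "detection_probability": self.detection_probability,
                "std_error": self.std_error,
                "replicates": self.replicates,
                "error_kind": self.error_kind,
                "n_symbols": self.n_symbols,
                "tolerance": self.tolerance,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _corrupt(stream, error_kind, rate, max_shift, rng):
    truth: list[stream_sim.ErrorTruth] = []
    out = stream
    if error_kind in ("deletion", "both"):
        out, t = stream_sim.apply_deletion(out, rate, seed=int(rng.integers(2**31)))
        truth.extend(t)
    if error_kind in ("misplacement", "both"):
        out, t = stream_sim.apply_misplacement(
            out, rate, max_shift=max_shift, seed=int(rng.integers(2**31))
        )
        truth.extend(t)
    return out, truth


def detection_curve(
    error_kind: str,
    rates: list[float],
    n_symbols: int = 10_000,
    replicates: int = 20,
    scoring: ScoringScheme | None = None,
    tolerance: int = DEFAULT_TOLERANCE,
    pair_window: int = DEFAULT_PAIR_WINDOW,
    max_shift: int = stream_sim.DEFAULT_MAX_SHIFT,
    seed: int | None = None,
) -> DetectionCurve:
    """Simulate error-detection probability at each error rate.

    Per replicate: draw a template of ``n_symbols`` i.i.d. symbols, corrupt
    it with the chosen error process, align corrupted vs. template, classify
    the discrepancies and score localization against the injected truth.
    With no injected errors in a replicate the probability is 1.0 by
    convention.
    """
    if error_kind not in ERROR_KINDS:
        raise ValueError(f"error_kind must be one of {ERROR_KINDS}")
    rates = [stream_sim._check_prob(r, "rate") for r in rates]
    replicates = int(replicates)
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    scoring = scoring or ScoringScheme()

    root = np.random.default_rng(seed)
    means, stderrs, per_rep = [], [], []
    for rate in rates:
        probs = []
        for _ in range(replicates):
            rng = np.random.default_rng(root.integers(2**31))
            template = stream_sim.generate_stream(
                n_symbols, cell_marker_ratio=0.0, seed=int(rng.integers(2**31))
            )
            corrupted, truth = _corrupt(template, error_kind, rate, max_shift, rng)
            aln = global_align(template.symbols(), corrupted.symbols(), scoring)
            report = classify_errors(aln, pair_window=pair_window)
            outcome = match_truth(truth, report, tolerance=tolerance)
            probs.append(outcome.detection_probability)
        probs_arr = np.asarray(probs)
        means.append(float(probs_arr.mean()))
        stderrs.append(float(probs_arr.std(ddof=1) / np.sqrt(replicates)) if replicates > 1 else 0.0)
        per_rep.append(probs)
    return DetectionCurve(
        error_kind=error_kind,
        rates=list(rates),
        detection_probability=means,
        std_error=stderrs,
        n_symbols=int(n_symbols),
        replicates=replicates,
        tolerance=int(tolerance),
        seed=seed,
        max_shift=int(max_shift),
        per_replicate=per_rep,
    )


def run_pipeline_once(
    n_markers: int,
    cell_marker_ratio: float,
    deletion_rate: float,
    misplacement_rate: float,
    max_shift: int = stream_sim.DEFAULT_MAX_SHIFT,
    p_out_of_focus: float = 0.0,
    scoring: ScoringScheme | None = None,
    pair_window: int = DEFAULT_PAIR_WINDOW,
    cell_spacing_um: float = 250.0,
    seed: int | None = None,
) -> dict:
    """One full simulate -> encode -> align -> map run; returns its stats.

    The imaging side observes the ground-truth stream; the plate side is the
    same stream corrupted by deletion then misplacement.  Plate positions
    are synthesised along a dispensing line at ``cell_spacing_um``.
    """
    rng = np.random.default_rng(seed)
    truth_stream = stream_sim.generate_stream(
        n_markers,
        cell_marker_ratio=cell_marker_ratio,
        p_out_of_focus=p_out_of_focus,
        seed=int(rng.integers(2**31)),
    )
    plate_stream, _ = stream_sim.apply_deletion(
        truth_stream, deletion_rate, seed=int(rng.integers(2**31))
    )
    plate_stream, _ = stream_sim.apply_misplacement(
        plate_stream, misplacement_rate, max_shift=max_shift, seed=int(rng.integers(2**31))
    )

    mseq_a = marker_codec.encode(truth_stream)
    mseq_b = marker_codec.encode(plate_stream)
    aln = global_align(mseq_a.symbols, mseq_b.symbols, scoring)
    report = classify_errors(aln, pair_window=pair_window)
    segments = cell_mapper.match_segments(mseq_a, mseq_b, aln, report)

    plate_positions = {
        e.uid: (e.source_index * cell_spacing_um, 0.0) for e in plate_stream.events
    }
    oof_uids = {e.uid for e in truth_stream.cells if e.out_of_focus}
    table = cell_mapper.build_mapping(segments, mseq_a, mseq_b, plate_positions, oof_uids)
    truth_pairs = {e.uid: e.uid for e in truth_stream.cells}
    return cell_mapper.retention_stats(table, segments, mseq_a, truth_pairs)


def retention_curve(
    deletion_rates: list[float] | float,
    misplacement_rates: list[float] | float,
    n_markers: int = 1000,
    cell_marker_ratio: float = 2.0,
    replicates: int = 20,
    max_shift: int = stream_sim.DEFAULT_MAX_SHIFT,
    seed: int | None = None,
) -> pd.DataFrame:
    """Average retention/misassignment over replicates per rate pair.

    Scalar rates broadcast against each other; list rates are paired by
    cartesian product.
    """
    dels = np.atleast_1d(np.asarray(deletion_rates, dtype=float))
    miss = np.atleast_1d(np.asarray(misplacement_rates, dtype=float))
    root = np.random.default_rng(seed)
    rows = []
    for dr in dels:
        for mr in miss:
            stats_list = [
                run_pipeline_once(
                    n_markers,
                    cell_marker_ratio,
                    float(dr),
                    float(mr),
                    max_shift=max_shift,
                    seed=int(root.integers(2**31)),
                )
                for _ in range(replicates)
            ]
            rows.append(
                {
                    "deletion_rate": float(dr),
                    "misplacement_rate": float(mr),
                    "retention_fraction": float(
                        np.mean([s["retention_fraction"] for s in stats_list])
                    ),
                    "retention_fraction_total": float(
                        np.mean([s["retention_fraction_total"] for s in stats_list])
                    ),
                    "misassignment_rate": float(
                        np.mean([s["misassignment_rate"] for s in stats_list])
                    ),
                    "usable_fraction": float(
                        np.mean([s["usable_fraction"] for s in stats_list])
                    ),
                    "replicates": replicates,
                    "n_markers": n_markers,
                    "cell_marker_ratio": cell_marker_ratio,
                }
            )
    return pd.DataFrame(rows)
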