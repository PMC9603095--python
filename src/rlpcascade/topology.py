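"""Signal-peptide and transmembrane-segment calls, plus the topology filters.

External annotations (SignalP/TMHMM/Phobius-style output re-expressed as
TSV) always take precedence; a Kyte-Doolittle hydropathy heuristic is the
built-in fallback so the cascade runs with no external binaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .seqio import Interval, SequenceRecord, TopologyAnnotation

#: Kyte-Doolittle hydropathy scale (Kyte & Doolittle 1982).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    # unknown residue: neutral
    "X": 0.0,
}


@dataclass(frozen=True)
class TopologyConfig:
    """Hydropathy-heuristic knobs (window/threshold tuned for single-pass helices)."""

    window: int = 19
    threshold: float = 1.6
    min_tm_len: int = 15
    merge_gap: int = 5


def hydropathy_profile(residues: str, window: int) -> np.ndarray:
    """Sliding-window mean Kyte-Doolittle hydropathy.

    Entry ``i`` is the mean over the window starting at 0-based position
    ``i``; length is ``len(residues) - window + 1`` (empty for short input).
    """
    values = np.array([KYTE_DOOLITTLE[r] for r in residues], dtype=float)
    if len(values) < window:
        return np.empty(0)
    kernel = np.ones(window) / window
    return np.convolve(values, kernel, mode="valid")


def predict_tm_heuristic(
    record: SequenceRecord,
    window: int = 19,
    threshold: float = 1.6,
    min_tm_len: int = 15,
    merge_gap: int = 5,
) -> list[Interval]:
    """Predict TM segments as runs of high mean hydropathy.

    A position belongs to a candidate segment when some window covering it
    has mean hydropathy above ``threshold``.  Maximal runs closer than
    ``merge_gap`` residues are merged, and runs shorter than ``min_tm_len``
    are discarded.  Sequences shorter than the window yield no segments.
    """
    profile = hydropathy_profile(record.residues, window)
    if profile.size == 0:
        return []
    # windows above threshold -> mark every residue covered by such a window
    covered = np.zeros(len(record.residues), dtype=bool)
    for i in np.flatnonzero(profile > threshold):
        covered[i : i + window] = True
    # maximal runs of covered residues (as 1-based inclusive intervals)
    runs: list[list[int]] = []
    for pos in np.flatnonzero(covered) + 1:
        if runs and pos == runs[-1][1] + 1:
            runs[-1][1] = pos
        else:
            runs.append([pos, pos])
    merged: list[list[int]] = []
    for start, end in runs:
        if merged and start - merged[-1][1] - 1 < merge_gap:
            merged[-1][1] = end
        else:
            merged.append([start, end])
    return [
        Interval(s, e) for s, e in merged if e - s + 1 >= min_tm_len
    ]


_SMALL_RESIDUES = {"A", "G", "S"}

#: The h-region search is confined to the N-terminal export-signal window.
_SP_SEARCH_END = 30
_SP_MAX_H_END = 35
_SP_MIN_H_LEN = 8


def predict_sp_heuristic(
    record: SequenceRecord, threshold: float = 1.6
) -> tuple[bool, Optional[int]]:
    """Detect a signal peptide as an N-terminal hydrophobic h-region.

    Returns ``(present, cleavage_index)``.  Present iff the first 30
    residues contain >= 8 contiguous residues whose mean hydropathy exceeds
    ``threshold`` and the run ends before position 35 (otherwise it is the
    first TM helix, not an export signal).  The cleavage index is the first
    small residue (A/G/S) after the h-region, 1-based, if any.
    """
    residues = record.residues
    values = np.array([KYTE_DOOLITTLE[r] for r in residues], dtype=float)
    n = len(values)
    best_end = None
    for start in range(min(n, _SP_SEARCH_END)):
        # extend the run from `start` while the running mean stays high
        end = start + _SP_MIN_H_LEN
        if end > n:
            break
        if values[start:end].mean() <= threshold:
            continue
        # extend over further hydrophobic residues while the mean stays high
        while (
            end < n
            and values[end] > 0
            and values[start : end + 1].mean() > threshold
        ):
            end += 1
        if end < _SP_MAX_H_END:  # 0-based exclusive end; 1-based end < 35
            best_end = end
        break  # a run reaching position 35 is the first TM, not a signal
    if best_end is None:
        return False, None
    for i in range(best_end, len(residues)):
        if residues[i] in _SMALL_RESIDUES:
            return True, i + 1
    return True, None


def resolve_topology(
    record: SequenceRecord,
    external: Optional[TopologyAnnotation] = None,
    config: TopologyConfig = TopologyConfig(),
) -> TopologyAnnotation:
    """External annotation wins when supplied; otherwise run the heuristics.

    An external annotation with no TM segments is returned as-is: absence
    of a segment in tool output is information, not a gap to fill.
    """
    if external is not None:
        return external
    sp, cleavage = predict_sp_heuristic(record, threshold=config.threshold)
    tm = predict_tm_heuristic(
        record,
        window=config.window,
        threshold=config.threshold,
        min_tm_len=config.min_tm_len,
        merge_gap=config.merge_gap,
    )
    if sp and tm and cleavage is not None and cleavage >= tm[0].start:
        cleavage = None
    return TopologyAnnotation(
        sp=sp,
        sp_cleavage=cleavage,
        tm_segments=tm,
        kinase_domain=None,
        source="heuristic",
    )


def passes_rlk_dataset_filter(ann: TopologyAnnotation) -> bool:
    """Training-positive filter: signal peptide plus exactly one TM segment."""
    return ann.sp and len(ann.tm_segments) == 1
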