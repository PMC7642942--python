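"""Convert depth-of-coverage anomalies into zero-length virtual gaps.

Gapless (typically long-read) assemblies give the splitting machinery
nothing to cut at.  Regions of anomalous read depth are likely misassembly
points, so each scaffold is tiled with fixed windows (default 5 kbp), window
mean depths are scored in standard deviations from the scaffold mean (both
computed over window means), and any window at or beyond the threshold
(default 3 sd) receives a virtual gap at its 5' end.  Virtual gaps not
consumed by a split are stripped — and their contig pieces re-merged —
before any output is written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import Scaffold
from .io_formats import DepthProfile

DEFAULT_WINDOW_SIZE = 5_000
DEFAULT_STEP = 1_000
DEFAULT_THRESHOLD_SD = 3.0


@dataclass
class WindowStat:
    scaffold_id: str
    beg: int
    end: int
    mean_depth: float
    z: float


def window_depth(
    profile: DepthProfile,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> list[WindowStat]:
    """Slide a window along the scaffold and z-score each position.

    The step defaults to a fifth of the window so that candidate breakpoints
    (window 5' ends) are placed finely enough to land between markers that
    closely bracket a misassembly junction.  A scaffold shorter than one
    window yields a single window; a zero standard deviation (perfectly
    uniform depth) yields z = 0 everywhere.
    """
    depths = profile.depths
    length = len(depths)
    if length <= window_size:
        starts = np.array([0])
        window_size = length
    else:
        starts = np.arange(0, length - window_size + 1, step)
        if starts[-1] != length - window_size:
            starts = np.append(starts, length - window_size)
    csum = np.concatenate(([0], np.cumsum(depths, dtype=np.float64)))
    means = (csum[starts + window_size] - csum[starts]) / window_size
    sd = float(means.std())
    center = float(means.mean())
    zs = (means - center) / sd if sd > 0 else np.zeros_like(means)
    return [
        WindowStat(profile.scaffold_id, int(b), int(b) + window_size, float(m), float(z))
        for b, m, z in zip(starts, means, zs)
    ]


def insert_virtual_gaps(
    scaffold: Scaffold,
    window_stats: list[WindowStat],
    threshold: float = DEFAULT_THRESHOLD_SD,
    profile: DepthProfile | None = None,
) -> int:
    """Insert one virtual gap per maximal block of |z| >= threshold windows.

    Overlapping flagged windows describe one anomalous region.  The
    breakpoint estimate is the |depth - mean|-weighted centroid of the
    per-base depth over the block when the profile is supplied (a symmetric
    anomaly's centroid pins the breakpoint to within tens of bases, far
    below window granularity); otherwise the block center is used.
    Positions inside or abutting a real gap are skipped; scaffold length is
    unchanged (virtual gaps have zero length).  Returns the number inserted.
    """
    flagged = [s for s in window_stats if abs(s.z) >= threshold]
    inserted = 0
    block: list[WindowStat] = []

    def flush() -> int:
        if not block:
            return 0
        beg, end = block[0].beg, block[-1].end
        center = (beg + end) // 2
        if profile is not None:
            depths = profile.depths[beg:end].astype(float)
            weights = np.abs(depths - float(profile.depths.mean()))
            total = weights.sum()
            if total > 0:
                center = beg + int(round(float((weights * np.arange(len(weights))).sum() / total)))
        return 1 if scaffold.insert_virtual_gap(center) else 0

    for stat in flagged:
        if block and stat.beg <= block[-1].end:
            block.append(stat)
        else:
            inserted += flush()
            block = [stat]
    inserted += flush()
    return inserted


def strip_unused_virtual_gaps(scaffolds: dict[str, Scaffold]) -> dict[str, Scaffold]:
    """Remove every remaining virtual gap, re-merging split contig pieces."""
    return {sid: s.strip_virtual_gaps() for sid, s in scaffolds.items()}
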