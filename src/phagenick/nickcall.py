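"""Detection of single-strand nick sites from strand-specific coverage.

A nick on one strand means no sequenced molecule from that strand spans the
break, so native read depth on that strand falls abruptly to (near) zero
while the opposite strand and the amplified (WGA) control stay at normal
depth. This module finds such one-strand coverage-drop intervals and pairs
them with degenerate-motif occurrences to produce nick calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .motif import MotifHit, MotifStrandStats
from .sequence_io import StrandCoverage

END_EXCLUSION = 200  # bp; linear-genome termini produce coverage cliffs too


@dataclass(frozen=True)
class DropParams:
    """Thresholds operationalizing an "abrupt fall to zero (or near-zero)".

    A position on strand s is drop-marked when native depth_s <=
    max(tau_abs, tau_rel * median_s) while the other native strand retains
    at least ``min_other_strand`` of its median and the control retains at
    least ``min_control`` of its own same-strand median. Marked positions
    within ``merge_gap`` bp merge into one interval.
    """

    tau_abs: int = 2
    tau_rel: float = 0.05
    min_other_strand: float = 0.5
    min_control: float = 0.5
    merge_gap: int = 5
    min_callable_median: float = 10.0

    def __post_init__(self):
        if self.tau_abs < 0:
            raise ValueError("tau_abs must be >= 0")
        for name in ("tau_rel", "min_other_strand", "min_control"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class DropInterval:
    """A contiguous run of drop-marked positions on one (depleted) strand."""

    genome_id: str
    strand: str
    start: int
    end: int
    min_depth: int
    flank_depth: float

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError("empty drop interval")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class NickCall:
    interval: DropInterval
    motif_hit: Optional[MotifHit] = None
    distance: Optional[float] = None
    motif_associated: bool = False


def detect_drops(native: StrandCoverage, control: StrandCoverage,
                 params: DropParams = DropParams()) -> list:
    """One-strand coverage-drop intervals in native vs WGA control coverage.

    Both strands are tested symmetrically (assembly orientation is
    arbitrary); intervals touching the first or last 200 bp are excluded as
    physical-terminus artifacts. Raises when per-strand native median depth
    is below ``min_callable_median``.
    """
    if native.genome_id != control.genome_id:
        raise ValueError("native and control cover different genomes")
    L = len(native.depth_fwd)
    if len(control.depth_fwd) != L:
        raise ValueError("native and control lengths differ")

    medians = {s: float(np.median(native.depth(s))) for s in "+-"}
    for s, med in medians.items():
        if med < params.min_callable_median:
            raise ValueError(
                f"insufficient coverage: median depth {med:.1f} on strand {s} "
                f"< {params.min_callable_median}"
            )

    intervals = []
    for s in "+-":
        other = "-" if s == "+" else "+"
        dep = native.depth(s)
        dep_other = native.depth(other)
        ctrl = control.depth(s)
        ctrl_med = float(np.median(ctrl))
        thr = max(params.tau_abs, params.tau_rel * medians[s])
        mark = (
            (dep <= thr)
            & (dep_other >= params.min_other_strand * medians[other])
            & (ctrl >= params.min_control * ctrl_med)
        )
        for start, end in _merge_runs(np.flatnonzero(mark), params.merge_gap):
            if start < END_EXCLUSION or end > L - END_EXCLUSION:
                continue
            lo = max(0, start - 100)
            hi = min(L, end + 100)
            flank = np.concatenate([dep[lo:start], dep[end:hi]])
            intervals.append(DropInterval(
                genome_id=native.genome_id, strand=s, start=int(start), end=int(end),
                min_depth=int(dep[start:end].min()),
                flank_depth=float(np.median(flank)) if flank.size else 0.0,
            ))
    intervals.sort(key=lambda iv: (iv.start, iv.strand))
    return intervals


def _merge_runs(positions: np.ndarray, merge_gap: int):
    """Merge sorted marked positions separated by <= merge_gap into
    half-open intervals."""
    if positions.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > merge_gap + 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [positions.size - 1]])
    return [(int(positions[i]), int(positions[j]) + 1) for i, j in zip(starts, ends)]


def associate_motif_hits(intervals: Sequence[DropInterval],
                         hits: Sequence[MotifHit],
                         window: float = 50) -> list:
    """Pair each drop interval with its nearest motif hit within ``window`` bp.

    Greedy matching by ascending midpoint distance; each hit is used at most
    once; ties broken by interval then hit coordinate. Intervals with no hit
    in range yield calls with ``motif_associated=False``.
    """
    candidates = []
    for i, iv in enumerate(intervals):
        for j, h in enumerate(hits):
            d = abs(iv.midpoint - (h.start + h.k / 2))
            if d <= window:
                candidates.append((d, iv.start, h.start, i, j))
    candidates.sort()
    hit_used = set()
    assigned = {}
    for d, _, _, i, j in candidates:
        if i in assigned or j in hit_used:
            continue
        assigned[i] = (j, d)
        hit_used.add(j)
    calls = []
    for i, iv in enumerate(intervals):
        if i in assigned:
            j, d = assigned[i]
            calls.append(NickCall(interval=iv, motif_hit=hits[j], distance=d,
                                  motif_associated=True))
        else:
            calls.append(NickCall(interval=iv))
    return calls


def nick_report(calls: Sequence[NickCall],
                stats: Optional[MotifStrandStats] = None,
                n_hits: Optional[int] = None) -> dict:
    """Summary counts for a set of nick calls.

    Fractions are ``None`` (serialized as not-applicable) when their
    denominator is zero. ``n_hits`` defaults to the motif-hit total from
    ``stats`` when given.
    """
    n = len(calls)
    by_strand = {s: sum(1 for c in calls if c.interval.strand == s) for s in "+-"}
    n_assoc = sum(1 for c in calls if c.motif_associated)
    if n_hits is None and stats is not None:
        n_hits = stats.n_fwd + stats.n_rev
    report = {
        "n_intervals": n,
        "n_intervals_fwd": by_strand["+"],
        "n_intervals_rev": by_strand["-"],
        "n_motif_associated": n_assoc,
        "fraction_intervals_associated": (n_assoc / n) if n else None,
        "fraction_hits_with_drop": (n_assoc / n_hits) if n_hits else None,
        "n_motif_hits": n_hits,
    }
    if stats is not None:
        report.update({
            "genome_id": stats.genome_id,
            "n_fwd": stats.n_fwd,
            "n_rev": stats.n_rev,
            "net": stats.net,
            "expected_per_strand": stats.expected_per_strand,
        })
    return report
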