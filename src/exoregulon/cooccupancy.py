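"""RNAP / sigma-70 promoter co-occupancy typing of TF binding sites.

A regulatory binding site is typed by which transcription-machinery peaks
cover its target gene's promoter region: RNAP_RPOD when both core RNA
polymerase and the housekeeping sigma factor RpoD bind the promoter,
RNAP_ONLY when core RNAP binds without RpoD (an alternative sigma factor
may serve that promoter), and OTHERS for everything else — every
intragenic site and any regulatory site whose promoter neither factor
occupies.  Sites in the first two classes are the ones most likely to
modulate transcription initiation at a nearby promoter.
"""

from __future__ import annotations

import warnings
from bisect import bisect_right
from dataclasses import dataclass

import pandas as pd

from .annotate import TargetAssignment
from .synth import tss

RNAP_RPOD = "RNAP_RPOD"
RNAP_ONLY = "RNAP_ONLY"
OTHERS = "OTHERS"
_RANK = {RNAP_RPOD: 2, RNAP_ONLY: 1, OTHERS: 0}


def merge_intervals(intervals) -> list[tuple[int, int]]:
    """Sort and merge overlapping/adjacent half-open intervals."""
    out: list[list[int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [(s, e) for s, e in out]


@dataclass
class OccupancyPeakSet:
    factor: str  # "RNAP" or "RpoD"
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        self.intervals = merge_intervals(self.intervals)
        self._starts = [s for s, _ in self.intervals]

    def overlaps(self, start: int, end: int, min_overlap: int = 1) -> bool:
        """True when [start, end) intersects any peak by >= min_overlap bases."""
        i = bisect_right(self._starts, end - 1)
        for s, e in self.intervals[max(0, i - 2): i]:
            if min(e, end) - max(s, start) >= min_overlap:
                return True
        return False


@dataclass
class CoOccupancyCall:
    site: TargetAssignment
    type: str
    promoter_interval: tuple[int, int] | None = None


def promoter_interval(
    gene: pd.Series, upstream: int = 300, downstream: int = 50,
    genome_length: int | None = None,
) -> tuple[int, int]:
    """Window around a gene's transcription start, strand-aware and clipped."""
    if upstream < 0 or downstream < 0:
        raise ValueError("promoter extents must be >= 0")
    s = tss(gene)
    if gene.strand == "+":
        lo, hi = s - upstream, s + downstream
    else:
        lo, hi = s - downstream + 1, s + upstream + 1
    lo = max(0, lo)
    if genome_length is not None:
        hi = min(hi, genome_length)
    return lo, hi


def classify_cooccupancy(
    assignment: TargetAssignment,
    rnap: OccupancyPeakSet,
    rpod: OccupancyPeakSet,
    genes: pd.DataFrame,
    upstream: int = 300,
    downstream: int = 50,
    genome_length: int | None = None,
    mode: str = "promoter",
    min_overlap: int = 1,
) -> CoOccupancyCall:
    """Type one binding site by machinery occupancy.

    In "promoter" mode (default) the overlap is tested against the target
    gene's promoter interval; "site" mode tests the binding interval
    itself.  For a two-target (divergent) site the most-occupied class
    across targets wins.
    """
    if assignment.location_class != "regulatory" or not assignment.target_genes:
        return CoOccupancyCall(site=assignment, type=OTHERS)
    gene_ix = genes.set_index("gene_id")
    best = CoOccupancyCall(site=assignment, type=OTHERS)
    for gid in assignment.target_genes:
        if mode == "site":
            iv = (assignment.peak.fwd_border, assignment.peak.rev_border + 1)
        else:
            iv = promoter_interval(gene_ix.loc[gid], upstream, downstream, genome_length)
        has_rnap = rnap.overlaps(*iv, min_overlap)
        has_rpod = rpod.overlaps(*iv, min_overlap)
        if has_rpod and not has_rnap:
            warnings.warn(
                f"promoter of {gid} has RpoD without RNAP; classified as others",
                stacklevel=2,
            )
        t = RNAP_RPOD if (has_rnap and has_rpod) else (RNAP_ONLY if has_rnap else OTHERS)
        if _RANK[t] > _RANK[best.type]:
            best = CoOccupancyCall(site=assignment, type=t, promoter_interval=iv)
    return best


def summarize_counts(n_i: int, n_ii: int, n_others: int) -> dict:
    """Arithmetic of the three-class summary from raw class counts."""
    total = n_i + n_ii + n_others
    overlap = n_i + n_ii
    return {
        "n_rnap_rpod": n_i,
        "n_rnap_only": n_ii,
        "n_others": n_others,
        "overlap_total": overlap,
        "total": total,
        "overlap_percent": round(100 * overlap / total) if total else None,
    }


def summarize_cooccupancy(calls) -> dict:
    """Tally co-occupancy calls across all TFs into the three-class summary."""
    n_i = sum(1 for c in calls if c.type == RNAP_RPOD)
    n_ii = sum(1 for c in calls if c.type == RNAP_ONLY)
    n_o = sum(1 for c in calls if c.type == OTHERS)
    return summarize_counts(n_i, n_ii, n_o)
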