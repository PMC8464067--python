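"""ChIP-exo peak calling from strand-specific 5'-end coverage.

A genuine ChIP-exo binding event leaves a bimodal signature: exonuclease
digestion stops at the protein-DNA crosslink, so read 5' ends pile up in a
forward-strand border upstream of the protected region and a reverse-strand
border downstream of it.  Candidate peaks are therefore called as paired
borders; false positives are then removed with two filters: peaks whose
signal-to-noise ratio falls below 1.5 are discarded, and peaks must be
reproduced in every biological replicate after sequencing-depth
normalization.  The noise reference is either a mock (input) track built
from sheared chromatin, in which case S/N is the IP/Mock window ratio, or a
noise floor set at the top 5% of signals over genomic positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from math import ceil
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StrandCoverage",
    "BorderCall",
    "ExoPeak",
    "build_strand_coverage",
    "normalize_depth",
    "noise_floor",
    "detect_borders",
    "pair_borders",
    "score_snr",
    "call_candidates",
    "filter_and_combine",
    "peaks_to_frame",
]


@dataclass
class StrandCoverage:
    """Per-position 5'-end counts for one strand of one sample."""

    sample_id: str
    strand: str  # "+" or "-"
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if (self.values < 0).any():
            raise ValueError("coverage values must be non-negative")

    @property
    def library_size(self) -> float:
        return float(self.values.sum())

    def scaled(self, factor: float) -> "StrandCoverage":
        return replace(self, values=self.values * factor)


@dataclass(frozen=True)
class BorderCall:
    strand: str
    position: int
    height: float


@dataclass
class ExoPeak:
    """A paired forward/reverse border call."""

    fwd_border: int
    rev_border: int
    snr: float = float("nan")
    replicate_support: frozenset = field(default_factory=frozenset)
    passed_filters: bool = False

    def __post_init__(self) -> None:
        if self.fwd_border >= self.rev_border:
            raise ValueError("forward border must lie strictly left of reverse border")

    @property
    def center(self) -> int:
        return (self.fwd_border + self.rev_border) // 2

    @property
    def width(self) -> int:
        return self.rev_border - self.fwd_border


def build_strand_coverage(
    intervals: Iterable[tuple[int, int, float]],
    genome_length: int,
    sample_id: str = "sample",
    strand: str = "+",
) -> StrandCoverage:
    """Densify (start, end, value) records into a per-position track.

    Records are 0-based half-open; overlapping records are rejected by the
    last-writer-wins rule of the bedGraph reader, so callers should pass
    disjoint intervals.
    """
    values = np.zeros(genome_length, dtype=float)
    for i, (s, e, v) in enumerate(intervals):
        if s < 0 or e > genome_length or e < s:
            raise ValueError(f"record {i}: interval [{s},{e}) outside genome of {genome_length}")
        if v < 0:
            raise ValueError(f"record {i}: negative value {v}")
        values[s:e] = v
    return StrandCoverage(sample_id=sample_id, strand=strand, values=values)


def normalize_depth(tracks: Sequence[StrandCoverage], target_depth: float) -> list[StrandCoverage]:
    """Scale each sample so its total 5'-end count equals `target_depth`.

    Library size is pooled over the two strand tracks of a sample, so the
    forward/reverse balance within a sample is preserved.  Samples with an
    empty library pass through unchanged.
    """
    by_sample: dict[str, float] = {}
    for t in tracks:
        by_sample[t.sample_id] = by_sample.get(t.sample_id, 0.0) + t.library_size
    out = []
    for t in tracks:
        lib = by_sample[t.sample_id]
        out.append(t if lib <= 0 else t.scaled(target_depth / lib))
    return out


def noise_floor(values: np.ndarray, top_fraction: float = 0.05) -> float:
    """Noise level defined by the top `top_fraction` of signals.

    Over the M nonzero genomic positions, returns the smallest value among
    the top ceil(top_fraction * M) signals, so at most that fraction of
    nonzero positions strictly exceed the returned threshold.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    values = np.asarray(values, dtype=float)
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("noise floor undefined on an all-zero track")
    k = ceil(top_fraction * nonzero.size)
    return float(np.partition(nonzero, -k)[-k])


def smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return np.asarray(values, dtype=float)
    kernel = np.full(window, 1.0 / window)
    return np.convolve(values, kernel, mode="same")


def detect_borders(
    track: StrandCoverage,
    smoothing_window: int = 5,
    min_height: float | None = None,
    min_separation: int = 10,
) -> list[BorderCall]:
    """Call candidate borders as local maxima of the smoothed track.

    A plateau of equal smoothed values counts as one maximum reported at its
    leftmost position.  `min_height` defaults to the track's own noise
    floor, so isolated background reads do not seed candidates.  Maxima
    closer than `min_separation` bases are reduced to the highest one
    (leftmost on equal height), so sampling noise inside one exonuclease
    border does not split it into several calls.
    """
    sm = smooth(track.values, smoothing_window)
    if min_height is None:
        if not (track.values > 0).any():
            return []
        min_height = noise_floor(track.values)
    # run-length encode so plateaus resolve to their leftmost position
    change = np.flatnonzero(np.diff(sm) != 0) + 1
    starts = np.concatenate([[0], change])
    run_vals = sm[starts]
    left = np.concatenate([[-np.inf], run_vals[:-1]])
    right = np.concatenate([run_vals[1:], [-np.inf]])
    is_max = (run_vals > left) & (run_vals > right) & (run_vals >= min_height)
    positions = starts[is_max]
    heights = run_vals[is_max]
    if min_separation > 1 and positions.size:
        order = np.lexsort((positions, -heights))  # by height desc, then leftmost
        kept_pos: list[int] = []
        kept = []
        for idx in order:
            p = positions[idx]
            if all(abs(p - q) >= min_separation for q in kept_pos):
                kept_pos.append(p)
                kept.append(idx)
        keep_mask = np.zeros(positions.size, dtype=bool)
        keep_mask[kept] = True
        positions, heights = positions[keep_mask], heights[keep_mask]
    return [
        BorderCall(strand=track.strand, position=int(p), height=float(h))
        for p, h in zip(positions, heights)
    ]


def pair_borders(
    fwd: Sequence[BorderCall],
    rev: Sequence[BorderCall],
    d_min: int = 5,
    d_max: int = 100,
) -> list[ExoPeak]:
    """Pair forward borders with reverse borders into bimodal candidates.

    Scanning forward borders left to right, each is greedily matched to the
    nearest unused reverse border lying d_min..d_max bases to its right.
    For this interval-compatibility structure the greedy choice attains the
    maximum number of pairs; unpaired borders (no bimodal partner) drop out.
    """
    fwd_pos = sorted(b.position for b in fwd)
    rev_pos = sorted(b.position for b in rev)
    used = np.zeros(len(rev_pos), dtype=bool)
    peaks = []
    for f in fwd_pos:
        lo, hi = f + d_min, f + d_max
        k = np.searchsorted(rev_pos, lo, side="left")
        while k < len(rev_pos) and (used[k] or rev_pos[k] < lo):
            k += 1
        if k < len(rev_pos) and lo <= rev_pos[k] <= hi:
            used[k] = True
            peaks.append(ExoPeak(fwd_border=f, rev_border=rev_pos[k]))
    return peaks


def score_snr(
    peak: ExoPeak,
    ip_tracks: Sequence[StrandCoverage],
    reference: Sequence[StrandCoverage] | float,
    pad: int = 0,
    pseudocount: float = 1.0,
    border_halfwidth: int = 2,
) -> float:
    """Signal-to-noise ratio of one candidate peak.

    Mock mode (`reference` is a pair of mock tracks): the IP 5'-end signal
    summed over [fwd - pad, rev + pad] (both strands) divided by the mock
    sum over the same window plus `pseudocount`.  Floor mode (`reference`
    is a number): a ChIP-exo peak's signal is concentrated at its two
    exonuclease borders rather than spread over the protected span, so the
    peak signal is the mean per-position 5'-end count over the two border
    neighborhoods (half-width `border_halfwidth`), divided by the
    noise-floor value.  Depth normalization must already have been applied.
    """
    if isinstance(reference, (int, float, np.floating)):
        floor = float(reference)
        if floor <= 0:
            raise ValueError("noise floor must be positive")
        w = border_halfwidth
        n_pos = 0
        total = 0.0
        for b in (peak.fwd_border, peak.rev_border):
            lo, hi = max(0, b - w), b + w + 1
            n_pos += hi - lo
            total += float(sum(t.values[lo:hi].sum() for t in ip_tracks))
        return (total / n_pos) / floor
    lo = max(0, peak.fwd_border - pad)
    hi = peak.rev_border + pad + 1  # inclusive of the reverse border
    ip_sum = float(sum(t.values[lo:hi].sum() for t in ip_tracks))
    mock_sum = float(sum(t.values[lo:hi].sum() for t in reference))
    denom = mock_sum + pseudocount
    if denom <= 0:
        raise ValueError("nonpositive S/N denominator; increase pseudocount")
    return ip_sum / denom


def call_candidates(
    fwd_track: StrandCoverage,
    rev_track: StrandCoverage,
    reference: Sequence[StrandCoverage] | float | None = None,
    smoothing_window: int = 5,
    min_height: float | None = None,
    d_min: int = 5,
    d_max: int = 100,
    pad: int = 0,
    pseudocount: float = 1.0,
) -> list[ExoPeak]:
    """Borders -> pairing -> S/N for one sample; no filtering yet.

    With `reference=None` the pooled noise floor of the sample's own tracks
    is used as the S/N reference.
    """
    if reference is None:
        pooled = fwd_track.values + rev_track.values
        reference = noise_floor(pooled)
    fwd = detect_borders(fwd_track, smoothing_window, min_height)
    rev = detect_borders(rev_track, smoothing_window, min_height)
    peaks = pair_borders(fwd, rev, d_min=d_min, d_max=d_max)
    for p in peaks:
        p.snr = score_snr(p, [fwd_track, rev_track], reference, pad=pad, pseudocount=pseudocount)
        p.replicate_support = frozenset([fwd_track.sample_id])
    return peaks


def filter_and_combine(
    candidates: dict[str, Sequence[ExoPeak]],
    snr_min: float = 1.5,
    match_tolerance: int = 20,
) -> list[ExoPeak]:
    """Apply the S/N and replicate-reproducibility filters.

    A peak survives only if every replicate contains a matching candidate
    (centers within `match_tolerance`) and the S/N is at least `snr_min` in
    each of them — removal is strict "< snr_min", so a peak at exactly the
    threshold is retained.  Merged coordinates are the rounded mean of the
    replicate borders; the reported S/N is the minimum across replicates.
    """
    if not candidates:
        return []
    samples = sorted(candidates)
    anchor = samples[0]
    others = samples[1:]
    used: dict[str, set[int]] = {s: set() for s in others}
    final = []
    for cand in sorted(candidates[anchor], key=lambda p: p.center):
        if cand.snr < snr_min:
            continue
        group = [cand]
        ok = True
        for s in others:
            best_i, best_d = None, match_tolerance + 1
            for i, other in enumerate(candidates[s]):
                if i in used[s]:
                    continue
                d = abs(other.center - cand.center)
                if d < best_d:
                    best_i, best_d = i, d
            if best_i is None or candidates[s][best_i].snr < snr_min:
                ok = False
                break
            used[s].add(best_i)
            group.append(candidates[s][best_i])
        if not ok:
            continue
        fwd = int(round(np.mean([p.fwd_border for p in group])))
        rev = int(round(np.mean([p.rev_border for p in group])))
        final.append(
            ExoPeak(
                fwd_border=fwd,
                rev_border=rev,
                snr=min(p.snr for p in group),
                replicate_support=frozenset(samples),
                passed_filters=True,
            )
        )
    return final


def peaks_to_frame(peaks: Sequence[ExoPeak], tf: str = "TF") -> pd.DataFrame:
    """Tabular view of peak calls (one row per peak, BED-compatible columns)."""
    rows = [
        {
            "name": f"{tf}:{i}",
            "fwd_border": p.fwd_border,
            "rev_border": p.rev_border,
            "center": p.center,
            "width": p.width,
            "snr": p.snr,
            "n_replicates": len(p.replicate_support),
            "passed_filters": p.passed_filters,
        }
        for i, p in enumerate(peaks)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "name",
            "fwd_border",
            "rev_border",
            "center",
            "width",
            "snr",
            "n_replicates",
            "passed_filters",
        ],
    )
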