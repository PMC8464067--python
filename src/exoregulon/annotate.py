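"""Target-gene assignment and sequence extraction for called binding sites.

Each peak is anchored at its center and classified by genomic position: a
center inside a gene body is intragenic and targets that gene; an
intergenic center is regulatory and targets the nearest downstream gene
start on each strand within a configurable upstream window (a site between
two divergently transcribed genes therefore targets both, but still counts
as one binding site).  A regulatory site upstream of an operon's lead gene
lists the remaining operon members as secondary targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaks import ExoPeak
from .synth import IUPAC, tss

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A",
              "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
              "B": "V", "V": "B", "D": "H", "H": "D", "N": "N"}


@dataclass
class TargetAssignment:
    peak: ExoPeak
    location_class: str  # "regulatory" or "intragenic"
    target_genes: list[str] = field(default_factory=list)
    secondary_targets: list[str] = field(default_factory=list)  # operon members
    distance_to_start: int | None = None  # signed; negative = upstream
    orphan: bool = False  # regulatory but no gene start within the window


def assign_target(
    peak: ExoPeak, genes: pd.DataFrame, upstream_max: int = 300
) -> TargetAssignment:
    """Assign a peak to its target gene(s) by genomic position.

    The annotation must be sorted by start with non-overlapping genes.
    Distances to a gene start are measured to the transcription start (the
    strand-aware 5' end of the gene); `distance_to_start` reports the
    signed offset of the peak center from the primary target's start,
    negative when upstream.
    """
    c = peak.center
    inside = genes[(genes["start"] <= c) & (c < genes["end"])]
    if len(inside):
        g = inside.iloc[0]
        return TargetAssignment(
            peak=peak,
            location_class="intragenic",
            target_genes=[g.gene_id],
            distance_to_start=_signed_distance(c, g),
        )
    targets = []
    for strand in "+-":
        sub = genes[genes["strand"] == strand]
        if not len(sub):
            continue
        starts = sub.apply(tss, axis=1).to_numpy()
        order = starts.argsort()
        starts = starts[order]
        if strand == "+":
            # smallest start strictly right of the center
            i = int(np.searchsorted(starts, c, side="right"))
            if i < len(starts) and 0 < starts[i] - c <= upstream_max:
                targets.append((int(starts[i] - c), sub.iloc[order[i]]))
        else:
            # largest start strictly left of the center
            i = int(np.searchsorted(starts, c, side="left")) - 1
            if i >= 0 and 0 < c - starts[i] <= upstream_max:
                targets.append((int(c - starts[i]), sub.iloc[order[i]]))
    targets.sort(key=lambda t: t[0])
    assignment = TargetAssignment(peak=peak, location_class="regulatory")
    if not targets:
        assignment.orphan = True
        return assignment
    assignment.target_genes = [g.gene_id for _, g in targets]
    assignment.distance_to_start = _signed_distance(c, targets[0][1])
    # operon expansion: members downstream of a targeted lead gene
    if "operon_id" in genes.columns:
        for _, g in targets:
            if not g.operon_id:
                continue
            members = genes[genes["operon_id"] == g.operon_id]
            if len(members) < 2:
                continue
            lead = members.iloc[0] if g.strand == "+" else members.iloc[-1]
            if lead.gene_id == g.gene_id:
                assignment.secondary_targets.extend(
                    m for m in members["gene_id"] if m not in assignment.target_genes
                )
    return assignment


def _signed_distance(center: int, gene: pd.Series) -> int:
    s = tss(gene)
    return center - s if gene.strand == "+" else s - center


def summarize_locations(assignments) -> dict:
    """Counts and rounded percentages of the regulatory/intragenic split.

    Accepts a sequence of TargetAssignment or a (n_regulatory,
    n_intragenic) pair.  Percentages are None when there are no sites.
    """
    if isinstance(assignments, tuple):
        n_reg, n_intra = assignments
    else:
        n_reg = sum(1 for a in assignments if a.location_class == "regulatory")
        n_intra = sum(1 for a in assignments if a.location_class == "intragenic")
    total = n_reg + n_intra
    pct = lambda n: round(100 * n / total) if total else None
    return {
        "n_regulatory": n_reg,
        "n_intragenic": n_intra,
        "total": total,
        "pct_regulatory": pct(n_reg),
        "pct_intragenic": pct(n_intra),
    }


def extract_site_sequences(
    peaks, genome: str, flank: int = 0, tf: str = "TF"
) -> list[dict]:
    """Pull binding-region sequences for external motif discovery.

    Each record covers [fwd_border - flank, rev_border + flank) in
    forward-strand genome orientation, clipped (and flagged) at contig
    edges; header-style ids carry TF, index and coordinates.
    """
    records = []
    for i, p in enumerate(peaks):
        lo, hi = p.fwd_border - flank, p.rev_border + flank
        clipped = lo < 0 or hi > len(genome)
        lo, hi = max(0, lo), min(len(genome), hi)
        records.append(
            {
                "id": f"{tf}:{i}:{lo}-{hi}",
                "sequence": genome[lo:hi].upper(),
                "clipped": clipped,
            }
        )
    return records


def write_motif_fasta(path, records) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(f">{r['id']}\n{r['sequence']}\n")


def palindromicity(consensus: str) -> float:
    """Fraction of positions compatible with the reverse complement.

    Position i scores when its IUPAC set intersects the complement of the
    set at the mirrored position; 1.0 means the consensus can read as a
    perfect palindrome (inverted repeat), as for TTC...GAA half-sites.
    """
    s = consensus.upper()
    if not s:
        raise ValueError("empty consensus")
    bad = set(s) - set(IUPAC)
    if bad:
        raise ValueError(f"non-IUPAC letters in consensus: {sorted(bad)}")
    n = len(s)
    hits = 0
    for i in range(n):
        mirrored = s[n - 1 - i]
        comp_set = {COMPLEMENT[b] for b in IUPAC[mirrored]}
        if set(IUPAC[s[i]]) & comp_set:
            hits += 1
    return hits / n
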