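"""Assign peaks to target genes and type them by RNAP/RpoD co-occupancy.

Each peak center is classified as intragenic (inside a gene body) or
regulatory (intergenic, within 300 bases upstream of a gene start), then
typed by which transcription-machinery peaks cover the target promoter.
"""

from exoregulon import synth
from exoregulon.annotate import assign_target, summarize_locations
from exoregulon.cooccupancy import (
    OccupancyPeakSet,
    classify_cooccupancy,
    summarize_cooccupancy,
)
from exoregulon.peaks import ExoPeak

ds = synth.simulate_dataset(
    genome_spec=synth.GenomeSpec(length=200_000, n_genes=160),
    read_model=synth.ReadModel(background_rate=0.03),
    n_sites=20,
    seed=11,
)
peaks = [ExoPeak(int(c) - 20, int(c) + 20) for c in ds.sites["center"]]
assignments = [assign_target(p, ds.genes, upstream_max=300) for p in peaks]
loc = summarize_locations(assignments)
print(f"location split : {loc['n_regulatory']} regulatory "
      f"({loc['pct_regulatory']}%) / {loc['n_intragenic']} intragenic "
      f"({loc['pct_intragenic']}%)")

rnap = OccupancyPeakSet("RNAP", ds.rnap)
rpod = OccupancyPeakSet("RpoD", ds.rpod)
calls = [classify_cooccupancy(a, rnap, rpod, ds.genes) for a in assignments]
co = summarize_cooccupancy(calls)
print(f"co-occupancy   : {co['n_rnap_rpod']} RNAP+RpoD, {co['n_rnap_only']} "
      f"RNAP only, {co['n_others']} others")
print(f"overlap        : {co['overlap_total']}/{co['total']} "
      f"({co['overlap_percent']}%) of sites sit at an RNAP-engaged promoter")
# Sites in the first two classes are positioned to modulate transcription
# initiation; "others" covers intragenic sites and unoccupied promoters.
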