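"""Simulate a ChIP-exo study and call filtered bimodal peaks.

Generates a 200 kb genome with 20 planted TF binding sites and two IP
replicates, then runs border detection, bimodal pairing, S/N filtering and
replicate reconciliation, and compares the calls with the planted truth.
"""

import numpy as np

from exoregulon import synth
from exoregulon.pipeline import call_peaks_from_tracks, make_config

ds = synth.simulate_dataset(
    genome_spec=synth.GenomeSpec(length=200_000, n_genes=160),
    read_model=synth.ReadModel(background_rate=0.03),
    n_sites=20,
    regulatory_fraction=0.6,
    seed=11,
)
cfg = make_config({})["peaks"]
final = call_peaks_from_tracks(ds.tracks, cfg)

truth = ds.sites["center"].to_numpy()
called = np.array([p.center for p in final])
recovered = sum(np.min(np.abs(called - c)) <= 20 for c in truth)

print(f"planted sites : {len(truth)}")
print(f"called peaks  : {len(final)}  (S/N >= {cfg['snr_min']}, both replicates)")
print(f"recovered     : {recovered} within +-20 bases of a planted center")
print(f"median width  : {np.median([p.width for p in final]):.0f} bases "
      "(distance between the paired exonuclease borders)")
# Every call survived the bimodal-shape, S/N and duplicate filters; the
# width reflects the protected footprint of roughly twice the border offset.
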