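"""Reproduce genome-scale summary arithmetic from published-style counts.

The summary operations are pure count arithmetic, so they can be driven
directly with printed per-TF tallies: 208 + 75 of 588 sites at
RNAP-engaged promoters, a 118-site regulator with 91 intragenic sites,
and a 50-site regulator with 20 DE-bound genes of which 16 are repressed.
"""

import pandas as pd

from exoregulon.annotate import summarize_locations
from exoregulon.cooccupancy import summarize_counts
from exoregulon.regulon import classify_regulator, direct_regulon

co = summarize_counts(208, 75, 588 - 283)
print(f"RNAP overlap      : {co['overlap_total']}/{co['total']} = "
      f"{co['overlap_percent']}%")

loc = summarize_locations((27, 91))
print(f"118-site regulator: {loc['pct_intragenic']}% intragenic / "
      f"{loc['pct_regulatory']}% regulatory -> class "
      f"{classify_regulator(118)}")

bound = [f"g{i}" for i in range(50)]
de = pd.DataFrame(
    [{"gene_id": g, "is_de": i < 20, "direction": "up" if i < 16 else "down"}
     for i, g in enumerate(bound)]
)
out = direct_regulon(bound, de)
print(f"50-site regulator : {out['pct_direct']}% direct regulon, "
      f"{out['pct_repressed']}% repressed -> class {classify_regulator(50)}")
# These are the per-TF summary numbers a genome-scale screen reports:
# promoter engagement, location split, direct-regulon rate and mode.
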