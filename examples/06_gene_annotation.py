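"""Convert a marker's genetic neighbourhood to a physical interval and
list the gene models inside it.

A 1 cM half-window at a local ratio of 2 Mb/cM yields a 4 Mb interval;
a synthetic GFF3 annotation supplies the gene models.
"""

import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

import qtlome as q
from qtlome.types import MarkerMap

consensus = MarkerMap(pd.DataFrame({
    "marker": ["gwm100", "wPt-1140", "gwm200"],
    "chromosome": ["2B"] * 3,
    "position_cM": [125.0, 133.4, 140.0],
}))
physical = {"gwm100": 585_100_000, "wPt-1140": 601_900_000, "gwm200": 615_100_000}

ratio, extrapolated = q.genetic_to_physical_ratio("wPt-1140", consensus, physical)
interval = q.marker_interval("wPt-1140", consensus, physical, window_cM=1.0)
print(f"local ratio {ratio:.1f} Mb/cM -> interval "
      f"{interval.chromosome}:{interval.start_bp:,}-{interval.end_bp:,} "
      f"({interval.width_bp / 1e6:.1f} Mb)")

rng = np.random.default_rng(0)
starts = np.sort(rng.integers(interval.start_bp, interval.end_bp - 5000, 24))
lines = ["##gff-version 3"] + [
    f"2B\tsim\tgene\t{s}\t{s + 4000}\t.\t+\t.\tID=TraesSim2B{i:03d}"
    for i, s in enumerate(starts)
]
with tempfile.TemporaryDirectory() as tmp:
    gff = Path(tmp) / "genes.gff3"
    gff.write_text("\n".join(lines) + "\n")
    genes = q.genes_in_interval(interval, gff)
print(f"{len(genes)} gene models in the interval; first three:")
print(genes.head(3).to_string(index=False))
# In a real analysis the GFF3 is the genome annotation and candidate
# genes are read off this list for the markers with the strongest and
# most stable associations.
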