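"""Build the deprivation index for the synthetic city and map its septiles.

The index is the first principal component of the five standardized census
indicators, oriented so higher = more deprived and normalized to mean 0 /
sd 1.  Reports the variance explained (the real-city analyses report > 75%
for this construction) and the 5th/95th percentile exposure contrast used by
the regression stage.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from fertimap.deprivation import compute_index
from fertimap.graph import TractSet
from fertimap.io import grid_polygons, read_gal, read_indicators, write_choropleth, write_index

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"
CITY = BASE / "city"

indicators = read_indicators(CITY / "indicators.csv")
index = compute_index(indicators)
write_index(BASE / "deprivation_index.csv", index)

ids, _ = read_gal(CITY / "adjacency.gal")
n = len(ids)
rows, cols = divmod(__import__("numpy").arange(n), 15)
tracts = TractSet(tract_id=tuple(ids), rows=rows, cols=cols)
write_choropleth(
    dict(zip(index.tract_id, index.x)),
    grid_polygons(tracts),
    "septile",
    BASE / "deprivation_septiles.geojson",
)

print(f"first principal component explains {100 * index.variance_explained:.1f}% "
      f"of indicator variance (expect > 75% with one dominant latent factor)")
print(f"index normalized: mean {index.x.mean():+.2e}, sd {index.x.std():.6f}")
print(f"exposure contrast q95 - q5 = {index.q95:.3f} - ({index.q5:.3f}) = {index.span:.3f}")
print(f"septile sizes: {__import__('numpy').bincount(index.septile)[1:].tolist()} (7 = most deprived)")
print(f"wrote {BASE / 'deprivation_index.csv'} and the septile choropleth")
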