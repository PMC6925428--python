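"""Crude fertility rates per 1,000 women by period, age group and nationality.

City-level rates (births and woman-years pooled over tracts) in the wide
period x age x nationality layout used for descriptive tables, plus the
tract-level rates the smoothing stage starts from.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import pandas as pd

from fertimap.io import read_counts
from fertimap.rates import crude_rate

BASE = Path(__file__).resolve().parents[1] / "results" / "analysis"

counts = read_counts(BASE / "city" / "counts.csv")
tract_rates = crude_rate(counts)
tract_rates.to_csv(BASE / "crude_rates_tract.csv", index=False, float_format="%.10g")

city_cells = counts.groupby(["period", "age_group", "nationality"], as_index=False)[
    ["births", "women"]
].sum()
city_cells["rate"] = 1000.0 * city_cells.births / city_cells.women
wide = city_cells.pivot_table(
    index="age_group", columns=["period", "nationality"], values="rate"
).round(2)
wide.to_csv(BASE / "crude_rates_city.csv")

print("city-level fertility rates (births per 1,000 women):")
print(wide.to_string())
n_undef = int(tract_rates["undefined"].sum())
print(f"\ntract-level cells: {len(tract_rates)}, undefined (no woman-years): {n_undef}")
print(f"wrote {BASE / 'crude_rates_city.csv'} and crude_rates_tract.csv")
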