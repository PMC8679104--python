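#!/usr/bin/env python
"""Generate the reference synthetic inputs and write them as CSVs.

Produces the frozen 46-country fixture ("reference-46"): the country x
{urban, rural} quantity table, the raw price datapoints in heterogeneous
currencies and years, and the deflator/PPP/exchange-rate series.  The CSVs
under results/inputs/ are what the CLI subcommands consume; later analysis
steps regenerate the same fixture in memory from its frozen seed.
"""

from pathlib import Path

from hhcost.prices import economic_factors_frame, price_points_frame
from hhcost.quantities import aggregate_unserved, country_table_frame
from hhcost.synthetic import reference_fixture

OUT = Path(__file__).resolve().parent.parent / "results" / "inputs"


def main() -> None:
    table, points, factors = reference_fixture()
    OUT.mkdir(parents=True, exist_ok=True)
    country_table_frame(table).to_csv(OUT / "country_table.csv", index=False)
    price_points_frame(points).to_csv(OUT / "price_points.csv", index=False)
    economic_factors_frame(factors).to_csv(OUT / "economic_factors.csv", index=False)

    unserved = aggregate_unserved(table, table.base_year)
    pop = sum(r.population[table.base_year] for r in table)
    print(f"reference-46 fixture: {len(table)} strata across {len(table.countries)} countries")
    print(f"  population {pop/1e9:.2f} billion; "
          f"households with no handwashing facility: {unserved/1e6:.1f} million")
    print(f"  {len(points)} raw price datapoints across "
          f"{len({p.category for p in points})} categories")
    print(f"wrote country_table.csv, price_points.csv, economic_factors.csv to {OUT}")


if __name__ == "__main__":
    main()
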