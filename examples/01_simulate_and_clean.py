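"""Generate a county vaccination panel and apply the cleaning rules.

Builds a synthetic county-level panel (counties nested in states, heavy-tailed
populations, 5% missing cells), then applies the three cleaning rules: the
65,000-population filter, MMR-for-overall proxy substitution, and
impute-or-exclude for missing outcome cells.
"""

from vaxpolicy import SimConfig, apply_county_filters, handle_missing, simulate_county_panel

config = SimConfig(n_states=10, counties_per_state=(5, 15), seed=11, missing_rate=0.05)
panel = simulate_county_panel(config)
print(f"raw panel: {len(panel.units)} counties x {len(panel.years)} years, "
      f"{int(panel.data[panel.outcomes].isna().sum().sum())} missing cells")

panel, pop_report = apply_county_filters(panel, min_population=65_000)
print(f"population filter: excluded {len(pop_report.excluded_units)} counties "
      f"below 65,000; proxied {len(pop_report.proxied_units)} counties from MMR")

panel, miss_report = handle_missing(panel, "overall", max_missing_fraction=0.2)
print(f"impute-or-exclude: imputed {len(miss_report.imputed_cells)} cells, "
      f"excluded {len(miss_report.excluded_units)} counties with >20% missing")
print(f"cleaned panel: {len(panel.units)} counties, "
      f"{int(panel.data['overall'].isna().sum())} missing overall-coverage cells remain")
# Every number above is also recorded in the CleaningReport objects, so a
# subanalysis can later drop exactly the proxied or imputed units.
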