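"""Per-season injury proportions for the bundled pilot cohort table.

The 14-athlete table reproduces the study marginals: 10/14 injured in
the season before consultation (71%) and 4/12 with follow-up data
injured in the season after (33%).  Percentages are computed over
athletes with known status only.
"""

from sportsrisk import cohort_injury_summary, table1_cohort

table = table1_cohort()
summary = cohort_injury_summary(table)

print(table.to_string(index=False))
print()
for season in ("season1", "season2"):
    s = summary[season]
    print(f"{season}: {s['n_injured']}/{s['n_known']} injured "
          f"({s['pct_injured']}%, displayed as {s['pct_display']}%)")
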