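"""Load the bundled injury-SNP panel and summarize its composition.

The panel holds 124 SNPs across six injury/trait categories.  The
summary prints per-category counts, the 63-SNP combined-score subset,
and how many SNPs are new to sports genetics (113, i.e. 91%).
"""

from sportsrisk import load_fixture_panel, panel_summary

panel = load_fixture_panel()
summary = panel_summary(panel)

print(f"panel: {summary['total']} SNPs, build {panel.build}")
for category, n in summary["category_counts"].items():
    print(f"  {category}: {n}")
print(f"combined-score subset (bone mineral density): {summary['n_combined_score']}")
print(f"new to sports genetics: {summary['n_not_previously_used']} "
      f"({summary['pct_not_previously_used']}%)")
# The vitamin/mineral sub-labels overlap (two folate-pathway SNPs carry
# both b_vitamins and homocysteine), so sub-counts sum above 39.
print(f"vitamin/mineral sub-labels: {summary['subcategory_counts']}")
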