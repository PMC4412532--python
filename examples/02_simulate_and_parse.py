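"""Simulate a small genotype cohort and round-trip one raw file.

Genotypes are drawn under Hardy-Weinberg equilibrium at the panel's
allele frequencies and written in the 4-column direct-to-consumer
dialect (rsid, chromosome, position, genotype), then parsed back.
"""

import tempfile
from pathlib import Path

from sportsrisk import (
    CohortSpec,
    load_fixture_panel,
    parse_raw_genotypes,
    simulate_profiles,
    write_cohort,
)

panel = load_fixture_panel()
spec = CohortSpec(n_individuals=3, seed=42)
profiles = simulate_profiles(panel, spec)

with tempfile.TemporaryDirectory() as tmp:
    paths = write_cohort(profiles, tmp)
    print(f"wrote {len(paths)} genotype files, e.g. {paths[0].name}:")
    print("".join(Path(paths[0]).read_text().splitlines(keepends=True)[:6]), end="")
    again = parse_raw_genotypes(paths[0], profiles[0].individual_id)
    assert again.calls == profiles[0].calls
    print(f"... ({len(again)} calls; parsed file equals the simulated profile)")
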