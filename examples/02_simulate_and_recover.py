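"""Generate a synthetic cohort with planted ground truth and recover it.

The generator places 50 lncRNA/gene cassettes (10 per orientation) on
synthetic chromosomes, plants an anti:co:null = 0.2:0.4:0.4 regulation
mixture for each named subpopulation comparison, and emits GFF3 + DE
tables. Running the pipeline back over those files must recover the planted
structure exactly.
"""

from collections import Counter

from lncpair import (
    GeneratorConfig, call_regulation, count_calls, find_pairs, generate,
)

config = GeneratorConfig(seed=1)  # defaults: 10 pairs/orientation, 10 comparisons
dataset = generate(config)
print(f"generated {len(dataset.features)} features "
      f"({len(dataset.truth.pairs)} planted pairs incl. "
      f"{int(dataset.truth.pairs['decoy'].sum())} beyond-window decoys)")

pairs = find_pairs(dataset.features)
print("recovered orientations:", dict(Counter(p.orientation for p in pairs)))
print("planted orientations:  ", dataset.truth.planted_orientation_counts())

comparison = "U15/L15"
regulated = call_regulation(pairs, dataset.de_tables[comparison], comparison)
print(f"\ncalls for {comparison} (upper vs lower cells, 15-day colony):")
print(count_calls(regulated).to_string())
print("planted:", dataset.truth.planted_call_counts(comparison))
print("\nEvery planted count is recovered exactly because effects are drawn")
print("clear of the significance gates; decoys never enter the pair list.")
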