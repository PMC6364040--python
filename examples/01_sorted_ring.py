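"""Generate a small synthetic admixture dataset and inspect the automatic
plotting order: populations bucketed by representative ancestry, then sorted
by that ancestry's mean proportion, descending."""

from admixring import SynthConfig, generate_dataset, resolve_order

dataset = generate_dataset(
    SynthConfig(n_populations=6, individuals_per_population=(3, 8), k=4, seed=42)
)
order = resolve_order(dataset)

print(f"{dataset.n_individuals} individuals, "
      f"{order.n_populations} populations, K={dataset.n_ancestries}\n")
print(f"{'population':<12}{'rep. ancestry':>14}{'mean prop.':>12}{'members':>9}")
for s in order.population_sequence:
    print(f"{s.label:<12}{s.representative_ancestry + 1:>14}"
          f"{s.representative_proportion:>12.3f}{s.n_members:>9}")

# Each line is one population in ring order.  "rep. ancestry" is the
# 1-based ancestry column with the largest mean proportion in that
# population; within a block sharing the same representative ancestry the
# mean proportion column is non-increasing.
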