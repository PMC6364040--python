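"""Compute the polar geometry of the circular plot: equal angular spans per
population and the center pie for a highlighted target."""

from admixring import (
    SynthConfig,
    compute_center_pie,
    compute_layout,
    generate_dataset,
    resolve_order,
)

dataset = generate_dataset(
    SynthConfig(n_populations=5, individuals_per_population=(2, 6), k=3, seed=7)
)
order = resolve_order(dataset)
target = order.population_sequence[0].label
layout = compute_layout(order, dataset.matrix, target=target)

print(f"{order.n_populations} populations -> each span "
      f"{layout.populations[0].width:.1f} deg (360/P, independent of size)\n")
for span in layout.populations:
    print(f"  {span.label}: [{span.start_angle:8.2f}, {span.end_angle:8.2f}] deg")

print(f"\ncenter pie for {target} (slice = 360 x mean ancestry proportion):")
for s in compute_center_pie(dataset, target):
    print(f"  ancestry {s.ancestry + 1}: {s.width:7.2f} deg")

# Every population gets the same span whatever its sample size; the pie
# angles sum to 360 and are exactly proportional to the target's mean
# ancestry vector.
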