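"""Full pipeline to files: synthetic inputs -> sorted ring -> SVG figure plus
the deterministic PlotSpec, color scheme, and sorted proportion table."""

from pathlib import Path

from admixring import (
    RenderOptions,
    SynthConfig,
    compute_layout,
    default_palette,
    generate,
    load_dataset,
    render_figure,
    resolve_order,
    write_color_scheme,
    write_sorted_table,
)

out = Path("scratch")
out.mkdir(exist_ok=True)

config = SynthConfig(n_populations=12, individuals_per_population=(4, 12), k=5, seed=3)
generate(config, out / "demo.Q", out / "demo.ind")

dataset = load_dataset(out / "demo.Q", out / "demo.ind")
order = resolve_order(dataset)
layout = compute_layout(order, dataset.matrix, target="Pop005")
scheme = default_palette(dataset.n_ancestries)

spec = render_figure(layout, scheme, out / "demo.svg", RenderOptions(format="svg"))
spec.write(out / "demo.plotspec.txt")
write_color_scheme(scheme, out / "demo.colors.txt")
write_sorted_table(dataset, order, out / "demo.sorted.tsv")

print(f"individuals: {dataset.n_individuals}, populations: {order.n_populations}, "
      f"K={dataset.n_ancestries}")
print(f"primitives drawn: {spec.count('sector')} sectors, {spec.count('line')} "
      f"separators, {spec.count('text')} labels, {spec.count('pie')} pie slices")
print(f"outputs under {out}/: demo.svg, demo.plotspec.txt, demo.colors.txt, "
      f"demo.sorted.tsv")

# The PlotSpec lists every drawn primitive with 6-decimal coordinates; two
# runs on the same inputs produce byte-identical text, which is what the
# determinism tests compare.
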