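"""Synthetic admixture datasets.

Emulates the output of a model-based ancestry inference run: each population
gets a random center on the K-simplex (flat Dirichlet), and its individuals
are drawn from a Dirichlet concentrated around that center.  Higher
``concentration`` means tighter populations; at very large values every
individual collapses onto the population center.  Rows are renormalized in
float arithmetic so each sums to one essentially exactly, and files are
written in the exact dialects the readers accept.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .qio import AncestryMatrix, Dataset, IndividualRecord

__all__ = ["SynthConfig", "generate_dataset", "generate"]


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic-data generator.

    ``individuals_per_population`` is an inclusive (low, high) range sampled
    per population, unless ``total_individuals`` pins the overall count, in
    which case the total is spread as evenly as possible across populations.
    """

    n_populations: int = 10
    individuals_per_population: tuple[int, int] = (5, 15)
    k: int = 5
    concentration: float = 30.0
    seed: int = 0
    total_individuals: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n_populations < 1:
            raise ValidationError("need at least one population")
        if self.k < 2:
            raise ValidationError("need K >= 2")
        lo, hi = self.individuals_per_population
        if not (1 <= lo <= hi):
            raise ValidationError("individuals_per_population must be 1 <= low <= high")
        if self.concentration <= 0:
            raise ValidationError("concentration must be positive")
        if self.total_individuals is not None and self.total_individuals < self.n_populations:
            raise ValidationError("total_individuals must allow >= 1 per population")


def _population_sizes(config: SynthConfig, rng: np.random.Generator) -> list[int]:
    p = config.n_populations
    if config.total_individuals is not None:
        base, extra = divmod(config.total_individuals, p)
        return [base + 1 if i < extra else base for i in range(p)]
    lo, hi = config.individuals_per_population
    return [int(s) for s in rng.integers(lo, hi + 1, size=p)]


def generate_dataset(config: SynthConfig) -> Dataset:
    """Draw a synthetic dataset in memory.

    Deterministic in (seed, config).  Population labels are "Pop001",
    "Pop002", ...; individual IDs are "<label>_ind<j>".
    """
    rng = np.random.default_rng(config.seed)
    sizes = _population_sizes(config, rng)
    width = max(3, len(str(config.n_populations)))

    rows: list[np.ndarray] = []
    records: list[IndividualRecord] = []
    row = 0
    for i, n in enumerate(sizes):
        label = f"Pop{i + 1:0{width}d}"
        center = rng.dirichlet(np.ones(config.k))
        draws = rng.dirichlet(config.concentration * center + 1e-9, size=n)
        for j in range(n):
            x = np.asarray(draws[j], dtype=float)
            x = x / x.sum()
            # Pin the largest entry so the float row sum is 1 to the last ulp;
            # the largest component always has headroom, so it stays in [0, 1].
            top = int(np.argmax(x))
            x[top] = 0.0
            x[top] = 1.0 - float(np.add.reduce(x))
            rows.append(x)
            records.append(IndividualRecord(f"{label}_ind{j + 1:03d}", label, row))
            row += 1

    matrix = AncestryMatrix(np.vstack(rows))
    return Dataset(matrix, tuple(records))


def generate(config: SynthConfig, q_path: str | Path, ind_path: str | Path) -> Dataset:
    """Write a synthetic dataset to disk as a .Q file and an .ind file.

    Proportions are written with shortest round-trip float formatting, so the
    files reparse to the in-memory values exactly and rows sum to one within
    float rounding.  Identical config and seed give byte-identical files.
    """
    dataset = generate_dataset(config)
    with open(q_path, "w", encoding="utf-8") as fh:
        for r in range(dataset.n_individuals):
            fh.write(" ".join(repr(float(v)) for v in dataset.matrix.values[r]) + "\n")
    with open(ind_path, "w", encoding="utf-8") as fh:
        for rec in dataset.individuals:
            fh.write(f"{rec.individual_id}\t{rec.group_label}\n")
    return dataset
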