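"""Representative-ancestry sorting.

The display order is derived from the data itself: each population's
*representative ancestry* is the ancestry component with the largest mean
proportion among its members.  Populations are bucketed into K groups by
representative ancestry (groups arranged in ascending ancestry-column order),
populations within a group are sorted by their representative proportion in
descending order, and individuals within a population are sorted by their own
proportion of the population's representative ancestry, also descending.

All tie-breaks are deterministic: argmax ties resolve to the lowest ancestry
index, equal population proportions resolve by label (lexicographic), and
equal individual proportions preserve original file order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import UnknownLabelError, ValidationError
from .qio import AncestryMatrix, Dataset

__all__ = [
    "PopulationSummary",
    "PlotOrder",
    "summarize_population",
    "group_by_representative",
    "sort_populations",
    "sort_individuals",
    "resolve_order",
]


@dataclass(frozen=True)
class PopulationSummary:
    """Per-population aggregate used for sorting and the center pie."""

    label: str
    member_rows: tuple[int, ...]
    mean_proportions: np.ndarray
    representative_ancestry: int

    @property
    def n_members(self) -> int:
        return len(self.member_rows)

    @property
    def representative_proportion(self) -> float:
        return float(self.mean_proportions[self.representative_ancestry])


@dataclass(frozen=True)
class PlotOrder:
    """Resolved plotting order: populations, and individuals within them."""

    population_sequence: tuple[PopulationSummary, ...]
    #: Per-population sorted member rows, aligned with population_sequence.
    members_by_population: tuple[tuple[int, ...], ...]

    @property
    def individual_sequence(self) -> tuple[int, ...]:
        return tuple(r for members in self.members_by_population for r in members)

    @property
    def n_populations(self) -> int:
        return len(self.population_sequence)


def summarize_population(dataset: Dataset, label: str) -> PopulationSummary:
    """Mean proportion vector and representative ancestry for one population.

    The representative ancestry is the argmax of the mean vector; ties go to
    the lowest ancestry index (numpy argmax convention).
    """
    rows = dataset.members_of(label)
    mean = dataset.matrix.values[rows].mean(axis=0)
    rep = int(np.argmax(mean))
    return PopulationSummary(label, tuple(rows), mean, rep)


def group_by_representative(
    summaries: Iterable[PopulationSummary],
) -> list[list[PopulationSummary]]:
    """Bucket populations into K groups by representative ancestry.

    Groups are returned in ascending ancestry index; a group may be empty when
    no population has that ancestry as its maximum.
    """
    summaries = list(summaries)
    if not summaries:
        return []
    k = len(summaries[0].mean_proportions)
    for s in summaries:
        if len(s.mean_proportions) != k:
            raise ValidationError("population summaries disagree on K")
    groups: list[list[PopulationSummary]] = [[] for _ in range(k)]
    for s in summaries:
        groups[s.representative_ancestry].append(s)
    return groups


def sort_populations(group: Sequence[PopulationSummary]) -> list[PopulationSummary]:
    """Sort one group by representative proportion, descending.

    Equal proportions fall back to ascending label order so the result is a
    pure function of the data.
    """
    group = list(group)
    reps = {s.representative_ancestry for s in group}
    if len(reps) > 1:
        raise ValidationError(
            f"sort_populations got mixed representative ancestries: {sorted(reps)}"
        )
    return sorted(group, key=lambda s: (-s.representative_proportion, s.label))


def sort_individuals(
    population: PopulationSummary, matrix: AncestryMatrix
) -> tuple[int, ...]:
    """Sort one population's members by the population's representative column.

    Descending in that proportion; ties keep original row order.
    """
    col = population.representative_ancestry
    return tuple(
        sorted(population.member_rows, key=lambda r: (-matrix.values[r, col], r))
    )


def resolve_order(
    dataset: Dataset,
    custom_order: Optional[Sequence[str]] = None,
    exclude: Optional[Iterable[str]] = None,
) -> PlotOrder:
    """Produce the final plotting order for a dataset.

    Without overrides: bucket populations by representative ancestry, walk the
    groups in ascending ancestry index, sort within each group by
    representative proportion descending.  A ``custom_order`` replaces the
    population sequence outright (individuals are still sorted within each
    population); ``exclude`` drops populations from the plot entirely.
    """
    labels = dataset.population_labels()
    label_set = set(labels)

    excluded: set[str] = set()
    if exclude:
        for lab in exclude:
            if lab not in label_set:
                raise UnknownLabelError(f"unknown population in exclude list: {lab!r}")
            excluded.add(lab)

    if custom_order is not None:
        seen: set[str] = set()
        sequence_labels: list[str] = []
        for lab in custom_order:
            if lab not in label_set:
                raise UnknownLabelError(f"unknown population in order file: {lab!r}")
            if lab in seen:
                raise ValidationError(f"population listed twice in order file: {lab!r}")
            seen.add(lab)
            if lab not in excluded:
                sequence_labels.append(lab)
        summaries = [summarize_population(dataset, lab) for lab in sequence_labels]
    else:
        kept = [lab for lab in labels if lab not in excluded]
        groups = group_by_representative(
            summarize_population(dataset, lab) for lab in kept
        )
        summaries = [s for group in groups for s in sort_populations(group)]

    if not summaries:
        raise ValidationError("no populations left to plot after exclusions")

    members = tuple(sort_individuals(s, dataset.matrix) for s in summaries)
    return PlotOrder(tuple(summaries), members)
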