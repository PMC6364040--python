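"""Shared test utilities: random dataset construction and an independent
brute-force reference for the ordering pipeline."""

from __future__ import annotations

import numpy as np

from admixring.qio import AncestryMatrix, Dataset, IndividualRecord


def make_dataset(rows, labels) -> Dataset:
    """Build a Dataset from a list of proportion rows and group labels."""
    arr = np.asarray(rows, dtype=float)
    records = tuple(
        IndividualRecord(f"ind{i:04d}", lab, i) for i, lab in enumerate(labels)
    )
    return Dataset(AncestryMatrix(arr), records)


def random_dataset(rng: np.random.Generator, max_pops=10, max_n=50, max_k=6) -> Dataset:
    """Random admixture dataset: Dirichlet rows, random population partition."""
    k = int(rng.integers(2, max_k + 1))
    n_pops = int(rng.integers(1, max_pops + 1))
    sizes = rng.integers(1, max(2, max_n // n_pops) + 1, size=n_pops)
    labels = []
    for i, s in enumerate(sizes):
        labels.extend([f"P{i:02d}"] * int(s))
    # shuffle so input order exercises the sorting
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    rows = rng.dirichlet(np.full(k, 0.8), size=len(labels))
    return make_dataset(rows, labels)


def brute_force_order(dataset: Dataset):
    """Reference ordering, written as plain loops independent of the package:

    bucket populations by argmax of their mean vector (ties to the lowest
    ancestry index), walk buckets in ascending ancestry index, sort each
    bucket by representative proportion descending (label ascending on ties),
    and sort individuals by the population's representative column descending
    (row index ascending on ties).
    """
    vals = dataset.matrix.values
    k = vals.shape[1]
    labels = []
    for rec in dataset.individuals:
        if rec.group_label not in labels:
            labels.append(rec.group_label)
    info = {}
    for lab in labels:
        rows = [r.row_index for r in dataset.individuals if r.group_label == lab]
        mean = [sum(vals[r, a] for r in rows) / len(rows) for a in range(k)]
        rep = 0
        for a in range(1, k):
            if mean[a] > mean[rep]:
                rep = a
        info[lab] = (rows, mean, rep)
    pop_seq = []
    for a in range(k):
        bucket = [lab for lab in labels if info[lab][2] == a]
        bucket.sort(key=lambda lab: (-info[lab][1][a], lab))
        pop_seq.extend(bucket)
    ind_seq = []
    for lab in pop_seq:
        rows, _, rep = info[lab]
        ind_seq.extend(sorted(rows, key=lambda r: (-vals[r, rep], r)))
    return pop_seq, ind_seq
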