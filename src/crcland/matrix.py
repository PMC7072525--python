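"""Binary samples x gene-instance encoding of clonal mutation profiles.

A mutated gene scores 1 and a wild-type gene 0. Genes hit more than once
in some sample get duplicated instance columns (APC, APC_1, APC_2, ...):
the number of columns for a gene is the cohort-wide maximum per-sample
mutation count in that gene, and a sample with m hits sets the first m
instance columns to 1. Instance columns are filled by count, not by the
identity of the individual mutation, which makes the Hamming distance
between two rows equal the summed absolute difference of per-gene
mutation counts.

Only genes inside the shared panel gene set are encoded; samples with no
mutations in the shared set are dropped (and reported).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .records import VariantRecord

__all__ = ["BinaryMatrix", "encode_binary_matrix", "gene_counts_by_sample",
           "collapse_identical_profiles"]


@dataclass
class BinaryMatrix:
    """0/1 matrix with ordered samples (rows) and gene-instance columns."""

    data: pd.DataFrame  # index: sample ids; columns: gene-instance labels
    dropped_samples: list[str]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=int)

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")


def _instance_labels(gene: str, n: int) -> list[str]:
    return [gene if k == 0 else f"{gene}_{k}" for k in range(n)]


def gene_counts_by_sample(
    clonal_variants: Iterable[VariantRecord],
) -> dict[str, Counter]:
    """Per-sample multiset of mutated genes (clonal variants only expected)."""
    out: dict[str, Counter] = {}
    for rec in clonal_variants:
        out.setdefault(rec.sample_id, Counter())[rec.gene] += 1
    return out


def encode_binary_matrix(
    sample_gene_counts: Mapping[str, Mapping[str, int]],
    shared_gene_set: Iterable[str],
) -> BinaryMatrix:
    """Encode per-sample gene mutation counts as a binary instance matrix.

    Parameters
    ----------
    sample_gene_counts
        Mapping sample id -> {gene: clonal mutation count}. Build it from
        variant records with :func:`gene_counts_by_sample`.
    shared_gene_set
        Genes covered by both panels; counts outside it are ignored.

    Samples whose restricted count is empty are dropped and listed in
    ``dropped_samples``. Columns are ordered alphabetically by gene with
    instances ascending; rows keep the input sample order.
    """
    shared = set(shared_gene_set)
    if not shared:
        raise ValueError("shared_gene_set must be non-empty")

    restricted: dict[str, dict[str, int]] = {}
    dropped: list[str] = []
    for sample, counts in sample_gene_counts.items():
        r = {g: int(c) for g, c in counts.items() if g in shared and c > 0}
        if r:
            restricted[sample] = r
        else:
            dropped.append(sample)

    max_count: Counter = Counter()
    for counts in restricted.values():
        for gene, c in counts.items():
            if c > max_count[gene]:
                max_count[gene] = c

    columns: list[str] = []
    for gene in sorted(max_count):
        columns.extend(_instance_labels(gene, max_count[gene]))

    rows = np.zeros((len(restricted), len(columns)), dtype=int)
    col_index = {label: j for j, label in enumerate(columns)}
    for i, (sample, counts) in enumerate(restricted.items()):
        for gene, c in counts.items():
            for label in _instance_labels(gene, c):
                rows[i, col_index[label]] = 1

    data = pd.DataFrame(rows, index=list(restricted), columns=columns)
    return BinaryMatrix(data=data, dropped_samples=dropped)


def collapse_identical_profiles(
    matrix: BinaryMatrix | pd.DataFrame,
) -> tuple[list[tuple[int, ...]], list[int], list[list[str]]]:
    """Group samples sharing an identical binary profile.

    Returns ``(unique_vectors, multiplicities, members)`` where
    ``members[k]`` lists the sample ids carrying ``unique_vectors[k]``.
    Vectors appear in order of first occurrence.
    """
    df = matrix.data if isinstance(matrix, BinaryMatrix) else matrix
    order: list[tuple[int, ...]] = []
    groups: dict[tuple[int, ...], list[str]] = {}
    for sample, row in zip(df.index, df.to_numpy(dtype=int)):
        key = tuple(int(x) for x in row)
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(str(sample))
    return order, [len(groups[k]) for k in order], [groups[k] for k in order]
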