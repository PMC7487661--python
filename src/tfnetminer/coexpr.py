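"""Co-expression edge-list utilities shared by the target and network stages.

Each dataset is an edge list (gene_a, gene_b[, rho]); an unordered pair's
support is the number of datasets in which it appears at least once.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd


def _pairs(dataset) -> set[frozenset]:
    if isinstance(dataset, pd.DataFrame):
        it: Iterable = zip(dataset["gene_a"], dataset["gene_b"])
    else:
        it = ((a, b) for a, b, *_ in dataset)
    return {frozenset((a, b)) for a, b in it if a != b}


def pair_support(datasets: Sequence) -> dict[frozenset, int]:
    """Unordered pair -> number of datasets containing it."""
    support: dict[frozenset, int] = {}
    for ds in datasets:
        for pair in _pairs(ds):
            support[pair] = support.get(pair, 0) + 1
    return support


def supported_pairs(datasets: Sequence, min_datasets: int = 2) -> set[frozenset]:
    return {p for p, n in pair_support(datasets).items() if n >= min_datasets}


def partners(gene: str, datasets: Sequence, min_datasets: int = 2) -> set[str]:
    """Genes linked to ``gene`` in at least ``min_datasets`` datasets."""
    out = set()
    for pair, n in pair_support(datasets).items():
        if n >= min_datasets and gene in pair:
            out |= pair - {gene}
    return out
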