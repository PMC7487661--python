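"""Shared domain records.

Coordinates are 0-based, half-open throughout the package (BED convention);
a gene is described by its TSS only, with promoter/flank windows derived
on demand.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneModel:
    """One annotated gene: identity, biotype and TSS location."""

    gene_id: str
    symbol: str
    biotype: str  # "lncRNA" | "PCG"
    chrom: str
    strand: str  # "+" | "-"
    tss: int

    def __post_init__(self) -> None:
        if self.biotype not in ("lncRNA", "PCG"):
            raise ValueError(f"unknown biotype {self.biotype!r} for {self.gene_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"unknown strand {self.strand!r} for {self.gene_id}")
        if self.tss < 0:
            raise ValueError(f"negative TSS for {self.gene_id}")


@dataclass(frozen=True)
class Peak:
    """One ChIP-Seq peak interval with its signal and originating sample."""

    chrom: str
    start: int
    end: int
    sample: str
    signal: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty/inverted peak [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ChipProfile:
    """One TF ChIP-Seq profile: the set of genes it assigns as targets."""

    profile_id: str
    tf_name: str
    targets: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.targets = frozenset(self.targets)
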