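"""Peak-to-promoter target assignment and binding-region summaries.

Promoter windows are strand-aware intervals around each TSS (default
2000 bp upstream to 200 bp downstream).  A gene counts as bound in a
ChIP-Seq sample when at least one of that sample's peaks overlaps its
promoter window (half-open intervals, >= ``min_overlap`` bp); genes
bound in at least ``min_samples`` samples pass the reproducibility rule.
Targets are then the bound genes that are also in the consensus
differential lists, with lncRNA targets optionally refined by
co-expression support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from tfnetminer.coexpr import pair_support
from tfnetminer.models import GeneModel, Peak


@dataclass(frozen=True)
class PromoterWindow:
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str


@dataclass(frozen=True)
class BindingEvidence:
    gene_id: str
    samples_bound: frozenset[str]

    @property
    def n_samples_bound(self) -> int:
        return len(self.samples_bound)


@dataclass
class TargetSet:
    """Bound-and-differential genes, split by biotype and direction."""

    lncrna_targets: list[tuple[str, str]] = field(default_factory=list)
    pcg_targets: list[tuple[str, str]] = field(default_factory=list)
    lncrna_highconf: list[str] = field(default_factory=list)

    @property
    def lncrna_ids(self) -> set[str]:
        return {g for g, _ in self.lncrna_targets}

    @property
    def pcg_ids(self) -> set[str]:
        return {g for g, _ in self.pcg_targets}

    @property
    def all_ids(self) -> set[str]:
        return self.lncrna_ids | self.pcg_ids

    def directions(self) -> dict[str, str]:
        return dict(self.lncrna_targets + self.pcg_targets)


@dataclass
class PeakSummary:
    biotype: str
    n_peaks: int
    mean_length: float | None
    mean_signal: float | None


def promoter_windows(
    annotation: Sequence[GeneModel],
    upstream: int = 2000,
    downstream: int = 200,
) -> list[PromoterWindow]:
    """Strand-aware promoter windows, truncated at position 0.

    On "+": [TSS - upstream, TSS + downstream); on "-" the window is
    mirrored: [TSS - downstream, TSS + upstream).
    """
    seen: set[str] = set()
    windows = []
    for g in annotation:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene id {g.gene_id} in annotation")
        seen.add(g.gene_id)
        if g.strand == "+":
            start, end = g.tss - upstream, g.tss + downstream
        elif g.strand == "-":
            start, end = g.tss - downstream, g.tss + upstream
        else:  # pragma: no cover - GeneModel already validates
            raise ValueError(f"unknown strand {g.strand!r}")
        windows.append(PromoterWindow(g.gene_id, g.chrom, max(0, start), end, g.strand))
    return windows


def assign_binding(
    peaks_by_sample: Mapping[str, Sequence[Peak]],
    windows: Sequence[PromoterWindow],
    min_samples: int = 2,
    min_overlap: int = 1,
) -> list[BindingEvidence]:
    """Genes whose promoter window is hit in >= ``min_samples`` samples.

    Overlap is computed on half-open intervals; a hit requires at least
    ``min_overlap`` overlapping bases.  The result is independent of the
    ordering of samples and of peaks within samples.
    """
    if not peaks_by_sample:
        raise ValueError("no peak files given")
    trees: dict[str, IntervalTree] = {}
    for w in windows:
        trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w.gene_id)
    bound: dict[str, set[str]] = {}
    for sample, peaks in peaks_by_sample.items():
        for peak in peaks:
            tree = trees.get(peak.chrom)
            if tree is None:
                continue
            for iv in tree.overlap(peak.start, peak.end):
                if min(peak.end, iv.end) - max(peak.start, iv.begin) >= min_overlap:
                    bound.setdefault(iv.data, set()).add(sample)
    out = [
        BindingEvidence(gene, frozenset(samples))
        for gene, samples in bound.items()
        if len(samples) >= min_samples
    ]
    out.sort(key=lambda e: e.gene_id)
    return out


def select_targets(
    binding: Sequence[BindingEvidence],
    consensus_up: Sequence[str],
    consensus_down: Sequence[str],
    annotation: Sequence[GeneModel],
    coexpr_datasets: Sequence = (),
    min_datasets: int = 2,
    tf_gene: str | None = None,
) -> TargetSet:
    """Intersect binding evidence with the consensus DE lists.

    High-confidence lncRNA targets additionally require a co-expression
    link, supported by >= ``min_datasets`` of the given datasets, to at
    least one PCG target (or to ``tf_gene`` when provided).
    """
    biotypes = {g.gene_id: g.biotype for g in annotation}
    direction = {g: "up" for g in consensus_up}
    direction.update({g: "down" for g in consensus_down})
    bound_ids = {e.gene_id for e in binding}
    ts = TargetSet()
    for gene in sorted(bound_ids & set(direction)):
        bt = biotypes.get(gene)
        if bt is None:
            continue  # DE evidence for a gene missing from annotation
        (ts.lncrna_targets if bt == "lncRNA" else ts.pcg_targets).append(
            (gene, direction[gene])
        )
    if coexpr_datasets and ts.lncrna_targets:
        support = pair_support(coexpr_datasets)
        anchors = ts.pcg_ids | ({tf_gene} if tf_gene else set())
        for gene in sorted(ts.lncrna_ids):
            partners = {
                other
                for pair, n in support.items()
                if n >= min_datasets and gene in pair
                for other in pair - {gene}
            }
            if partners & anchors:
                ts.lncrna_highconf.append(gene)
    return ts


def peak_region_stats(
    peaks_by_sample: Mapping[str, Sequence[Peak]],
    target_set: TargetSet,
    annotation: Sequence[GeneModel],
    extension: int = 2000,
) -> dict:
    """Per-biotype summaries of peaks falling in target TSS +/- ``extension``.

    Peaks from all samples are pooled; a peak is attributed to every
    biotype class whose region it overlaps.  Lengths and signals of the
    two classes are compared by two-sided Welch t-tests (p is None when
    a class has fewer than two peaks).
    """
    regions: dict[str, IntervalTree] = {"lncRNA": IntervalTree(), "PCG": IntervalTree()}
    genes = {g.gene_id: g for g in annotation}
    for biotype, ids in (("lncRNA", target_set.lncrna_ids), ("PCG", target_set.pcg_ids)):
        for gid in ids:
            g = genes[gid]
            regions[biotype].addi(max(0, g.tss - extension), g.tss + extension, gid)
    lengths: dict[str, list[float]] = {"lncRNA": [], "PCG": []}
    signals: dict[str, list[float]] = {"lncRNA": [], "PCG": []}
    for peaks in peaks_by_sample.values():
        for peak in peaks:
            for biotype, tree in regions.items():
                if tree.overlap(peak.start, peak.end):
                    lengths[biotype].append(peak.length)
                    signals[biotype].append(peak.signal)
    summaries = {
        bt: PeakSummary(
            bt,
            len(lengths[bt]),
            float(np.mean(lengths[bt])) if lengths[bt] else None,
            float(np.mean(signals[bt])) if signals[bt] else None,
        )
        for bt in ("lncRNA", "PCG")
    }

    def _welch_p(a, b):
        if len(a) < 2 or len(b) < 2:
            return None
        if np.var(a) == 0 and np.var(b) == 0 and np.mean(a) == np.mean(b):
            return 1.0
        return float(stats.ttest_ind(a, b, equal_var=False).pvalue)

    return {
        "summaries": summaries,
        "length_ttest_p": _welch_p(lengths["lncRNA"], lengths["PCG"]),
        "signal_ttest_p": _welch_p(signals["lncRNA"], signals["PCG"]),
    }


def gc_fraction(sequence: str) -> float:
    """(G+C) / (A+C+G+T); ambiguous bases excluded from both counts."""
    seq = sequence.upper()
    gc = sum(seq.count(b) for b in "GC")
    acgt = gc + sum(seq.count(b) for b in "AT")
    if acgt == 0:
        raise ValueError("sequence has no unambiguous bases")
    return gc / acgt


def export_regions(
    peaks: Sequence[Peak],
    genome: Mapping[str, str],
) -> list[tuple[str, str, float]]:
    """Extract peak sequences; returns (name, sequence, GC fraction) rows.

    Record names follow ``chrom:start-end``.  A peak extending beyond its
    chromosome is an error.
    """
    rows = []
    for peak in peaks:
        seq = genome.get(peak.chrom)
        if seq is None:
            raise ValueError(f"chromosome {peak.chrom} absent from genome")
        if peak.end > len(seq):
            raise ValueError(
                f"peak [{peak.start}, {peak.end}) beyond end of {peak.chrom} ({len(seq)} bp)"
            )
        sub = seq[peak.start:peak.end]
        rows.append((f"{peak.chrom}:{peak.start}-{peak.end}", sub, gc_fraction(sub)))
    return rows
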