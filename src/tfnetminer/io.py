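"""Readers and writers for the plain-text formats the pipeline exchanges.

Formats: annotation TSV, BED6+signal peak files, expression TSV (genes x
samples, header cells ``sample:group``), GMT profile pools and gene-set
databases, edge-list TSVs, FASTA genomes and clinical qPCR TSVs.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from tfnetminer.models import ChipProfile, GeneModel, Peak

ANNOTATION_COLUMNS = ["gene_id", "symbol", "biotype", "chrom", "strand", "tss"]


# ---------------------------------------------------------------- annotation

def write_annotation(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(g.gene_id, g.symbol, g.biotype, g.chrom, g.strand, g.tss) for g in genes],
        columns=ANNOTATION_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | os.PathLike) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "symbol": str})
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"annotation {path} lacks columns {sorted(missing)}")
    dup = df["gene_id"][df["gene_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicated gene ids in annotation: {sorted(set(dup))}")
    return [
        GeneModel(r.gene_id, r.symbol, r.biotype, r.chrom, r.strand, int(r.tss))
        for r in df.itertuples(index=False)
    ]


# ----------------------------------------------------------------- BED peaks

def write_peaks_bed(peaks: Sequence[Peak], path: str | os.PathLike) -> None:
    """BED6 + one extra column: score = round(signal*10), col 7 = float signal."""
    with open(path, "w") as fh:
        for p in peaks:
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.sample}\t"
                f"{round(p.signal * 10)}\t.\t{p.signal:.4f}\n"
            )


def read_peaks_bed(path: str | os.PathLike, sample: str | None = None) -> list[Peak]:
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(f"{path}:{lineno}: malformed BED line (<4 fields)")
            try:
                chrom, start, end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
                signal = float(fields[6]) if len(fields) > 6 else float(fields[4]) / 10.0
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed BED line: {exc}") from exc
            if end <= start:
                raise ValueError(f"{path}:{lineno}: empty/inverted interval")
            peaks.append(Peak(chrom, start, end, sample or name, signal))
    return peaks


# --------------------------------------------------------------- expression

def write_expression(expr: pd.DataFrame, path: str | os.PathLike) -> None:
    """``expr``: genes x samples, columns named ``sample:group``."""
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def read_expression(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    bad = [c for c in df.columns if ":" not in c]
    if bad:
        raise ValueError(f"expression columns must be 'sample:group'; got {bad[:3]}")
    return df


def expression_groups(expr: pd.DataFrame) -> dict[str, list[str]]:
    """Map group label -> column names, from ``sample:group`` headers."""
    groups: dict[str, list[str]] = {}
    for col in expr.columns:
        groups.setdefault(col.rsplit(":", 1)[1], []).append(col)
    return groups


# ---------------------------------------------------------------------- GMT

def write_profile_pool(pool: Sequence[ChipProfile], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for prof in pool:
            genes = "\t".join(sorted(prof.targets))
            fh.write(f"{prof.profile_id}\t{prof.tf_name}\t{genes}\n")


def read_profile_pool(path: str | os.PathLike) -> list[ChipProfile]:
    pool = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: GMT line needs id and TF name")
            pool.append(ChipProfile(fields[0], fields[1], frozenset(fields[2:]) - {""}))
    return pool


def write_genesets(genesets: Mapping[str, tuple[str, Iterable[str]]], path) -> None:
    """``genesets``: term_id -> (description, member genes)."""
    with open(path, "w") as fh:
        for term, (desc, genes) in genesets.items():
            fh.write(term + "\t" + desc + "\t" + "\t".join(sorted(genes)) + "\n")


def read_genesets(path) -> dict[str, tuple[str, frozenset[str]]]:
    out: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs >=1 member gene")
            out[fields[0]] = (fields[1], frozenset(fields[2:]) - {""})
    return out


# -------------------------------------------------------------------- edges

def write_edges(edges: Iterable[tuple], path, header=("gene_a", "gene_b", "rho")) -> None:
    rows = list(edges)
    ncol = len(rows[0]) if rows else len(header)
    pd.DataFrame(rows, columns=list(header)[:ncol]).to_csv(path, sep="\t", index=False)


def read_edges(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError(f"edge list {path} lacks gene_a/gene_b columns")
    return df


# -------------------------------------------------------------------- FASTA

def write_genome(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="") for chrom, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_genome(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta_records(records: Sequence[tuple[str, str]], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(seq), id=name, description="") for name, seq in records],
        path,
        "fasta",
    )


# ----------------------------------------------------------------- clinical

def write_clinical(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "ct_target_tumor", "ct_reference_tumor",
                "ct_target_normal", "ct_reference_normal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"clinical table {path} lacks columns {sorted(missing)}")
    return df
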