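"""Synthetic inputs with known planted structure for every pipeline stage.

One synthetic chromosome ("chrS", 0-based half-open coordinates) carries
evenly spaced genes.  The generator plants: differentially expressed
genes (log2 shift of ``de_effect`` in both case groups), promoter-bound
TF targets (a peak overlapping the promoter window in >= 2 of the ChIP
samples, GC-enriched sequence under the peak), one co-factor TF whose
pool profiles overlap the planted targets heavily, clique modules
supported by >= 2 of 3 co-expression datasets plus within-module PPIs,
and a clinical qPCR table with configured per-covariate group sizes and
dCt shifts.  Truth objects are returned (and written) alongside the
data; fixing the seed makes every output byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from tfnetminer import io
from tfnetminer.models import ChipProfile, GeneModel, Peak
from tfnetminer.targets import promoter_windows

CHROM = "chrS"

#: Fake TF roster for background pool profiles.
TF_ROSTER = tuple(f"TF{i:03d}" for i in range(1, 81))

#: Clinical covariates: level -> (n, planted dCt shift).  Group sizes
#: mirror a 111-patient cohort; only invasion depth and distal
#: metastasis carry planted effects.
DEFAULT_CLINICAL_SPEC = {
    "age_group": [("ge60", 67, 0.0), ("lt60", 44, 0.0)],
    "gender": [("female", 45, 0.0), ("male", 66, 0.0)],
    "location": [("colon", 54, 0.0), ("rectal", 57, 0.0)],
    "diameter": [("gt5", 28, 0.0), ("le5", 83, 0.0)],
    "differentiation": [("moderate", 87, 0.0), ("poor", 20, 0.0), ("well", 4, 0.0)],
    "invasion": [("T1", 7, 1.5), ("T2", 23, 0.3), ("T3", 16, 0.6), ("T4", 65, -0.4)],
    "lymph": [("N0", 57, 0.0), ("N1", 31, 0.0), ("N2", 23, 0.0)],
    "metastasis": [("M0", 102, 0.0), ("M1", 9, -1.66)],
    "tnm": [("I", 21, 0.0), ("II", 36, 0.0), ("III", 44, 0.0), ("IV", 10, 0.0)],
}


@dataclass
class SynthConfig:
    seed: int = 0
    n_genes: int = 1000
    frac_lncrna: float = 0.2
    chrom_length: int = 6_000_000
    n_samples_per_group: int = 10
    de_effect: float = 2.0  # log2 fold change planted in both case groups
    noise_sd: float = 1.0  # expression noise SD, log2 scale
    n_planted_de: int = 120
    n_planted_targets: int = 40
    n_chip_samples: int = 5
    n_decoy_peaks: int = 150  # per ChIP sample, outside all promoters
    pool_size: int = 500
    planted_cofactor_tf: str = "COF1"
    n_cofactor_profiles: int = 6
    cofactor_target_frac: float = 0.7  # fraction of planted targets per co-factor profile
    gc_background: float = 0.40
    gc_peak: float = 0.65
    module_spec: list = field(default_factory=lambda: [(30, 1), (28, 1)])
    clinical_spec: dict = field(default_factory=lambda: {
        k: list(v) for k, v in DEFAULT_CLINICAL_SPEC.items()
    })
    tumor_shift: float = -1.0  # tumor-vs-normal dCt shift (negative = up-regulated)
    patient_sd: float = 1.4  # patient-level random effect, shared by the pair
    clinical_noise_sd: float = 1.4  # residual per-tissue noise
    baseline_dct: float = 6.3

    def __post_init__(self) -> None:
        if not 0 < self.frac_lncrna < 1:
            raise ValueError("frac_lncrna must lie strictly between 0 and 1")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


GROUPS = ("normal", "primary", "metastasis")


# --------------------------------------------------------------- annotation

def make_annotation(config: SynthConfig) -> list[GeneModel]:
    """Evenly spaced genes on one chromosome, jittered TSS, both strands."""
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    spacing = config.chrom_length // (config.n_genes + 1)
    if spacing < 2500:
        raise ValueError(
            f"chrom_length {config.chrom_length} too small for {config.n_genes} genes"
        )
    rng = config.rng(1)
    n_lnc = round(config.frac_lncrna * config.n_genes)
    biotypes = np.array(["lncRNA"] * n_lnc + ["PCG"] * (config.n_genes - n_lnc))
    rng.shuffle(biotypes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    if config.n_genes >= 2 and len(set(strands)) == 1:
        strands[0] = "+" if strands[0] == "-" else "-"
    jitter = rng.integers(-spacing // 8, spacing // 8 + 1, size=config.n_genes)
    genes = []
    n_l = n_p = 0
    for i in range(config.n_genes):
        tss = int((i + 1) * spacing + jitter[i])
        if biotypes[i] == "lncRNA":
            n_l += 1
            symbol = f"LNC{n_l:04d}"
        else:
            n_p += 1
            symbol = f"PCG{n_p:04d}"
        genes.append(GeneModel(f"g{i:05d}", symbol, biotypes[i], CHROM, strands[i], tss))
    return genes


# --------------------------------------------------------------- expression

def make_expression(
    config: SynthConfig, annotation: Sequence[GeneModel]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log2 expression for 3 groups + truth table of planted DE genes.

    Planted genes are shifted by +/- ``de_effect`` in BOTH case groups
    relative to normal; all other genes share their baseline mean across
    groups.  Truth columns: gene_id, direction.
    """
    if not annotation:
        raise ValueError("empty annotation")
    rng = config.rng(2)
    n = len(annotation)
    baseline = rng.uniform(4.0, 10.0, size=n)
    n_de = min(config.n_planted_de, n) if config.de_effect != 0 else 0
    de_idx = rng.choice(n, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([1.0, -1.0], size=n_de)
    shift = np.zeros(n)
    shift[de_idx] = signs * config.de_effect
    cols, data = [], []
    for group in GROUPS:
        eff = baseline if group == "normal" else baseline + shift
        for j in range(config.n_samples_per_group):
            cols.append(f"{group}{j + 1}:{group}")
            data.append(eff + rng.normal(0.0, config.noise_sd, size=n))
    expr = pd.DataFrame(
        np.column_stack(data), index=[g.gene_id for g in annotation], columns=cols
    )
    expr.index.name = "gene_id"
    truth = pd.DataFrame(
        {
            "gene_id": [annotation[i].gene_id for i in de_idx],
            "direction": np.where(signs > 0, "up", "down"),
        }
    ).sort_values("gene_id", ignore_index=True)
    return expr, truth


def make_evidence(
    config: SynthConfig, de_truth: pd.DataFrame, annotation: Sequence[GeneModel]
) -> pd.DataFrame:
    """External evidence list: all planted DE genes plus inert extras.

    The extras are non-DE genes given a random direction; they can never
    become consensus calls (not significant) and exercise the
    intersection logic.
    """
    rng = config.rng(3)
    planted = set(de_truth["gene_id"])
    others = [g.gene_id for g in annotation if g.gene_id not in planted]
    n_extra = min(len(others), max(10, len(planted) // 2))
    extras = sorted(rng.choice(others, size=n_extra, replace=False)) if n_extra else []
    frame = pd.concat(
        [
            de_truth[["gene_id", "direction"]],
            pd.DataFrame(
                {"gene_id": extras, "direction": rng.choice(["up", "down"], size=len(extras))}
            ),
        ],
        ignore_index=True,
    )
    return frame.sort_values("gene_id", ignore_index=True)


# ------------------------------------------------------------------ ChIP-Seq

def pick_planted_targets(
    config: SynthConfig, annotation: Sequence[GeneModel], de_truth: pd.DataFrame
) -> list[str]:
    """Planted TF targets: about half from the planted DE set, half not."""
    rng = config.rng(4)
    de_genes = list(de_truth["gene_id"])
    non_de = [g.gene_id for g in annotation if g.gene_id not in set(de_genes)]
    n_from_de = min(len(de_genes), config.n_planted_targets // 2)
    n_from_other = min(len(non_de), config.n_planted_targets - n_from_de)
    chosen = list(rng.choice(de_genes, size=n_from_de, replace=False)) if n_from_de else []
    chosen += list(rng.choice(non_de, size=n_from_other, replace=False))
    return sorted(chosen)


def make_profile_pool(
    config: SynthConfig,
    annotation: Sequence[GeneModel],
    planted_targets: Sequence[str],
) -> list[ChipProfile]:
    """The TF ChIP-Seq profile pool on its own (no peaks, no genome)."""
    ids = sorted(g.gene_id for g in annotation)
    missing = set(planted_targets) - set(ids)
    if missing:
        raise ValueError(f"planted targets absent from annotation: {sorted(missing)[:3]}")
    return _make_pool(config, ids, sorted(planted_targets), config.rng(9))


def make_chip_data(
    config: SynthConfig,
    annotation: Sequence[GeneModel],
    planted_targets: Sequence[str],
    with_genome: bool = True,
) -> tuple[dict[str, list[Peak]], list[ChipProfile], dict[str, str]]:
    """Per-sample peaks, the TF profile pool, and the genome sequence.

    Every planted target gets a promoter-overlapping peak in >= 2 of the
    ChIP samples; decoy peaks land strictly outside all promoter
    windows.  The pool holds ``n_cofactor_profiles`` profiles for the
    planted co-factor (target sets overlapping the planted targets
    heavily) plus background profiles with uniformly random target sets.
    Planted peak intervals are GC-enriched within an A/T-balanced
    genome.
    """
    ids = {g.gene_id for g in annotation}
    missing = set(planted_targets) - ids
    if missing:
        raise ValueError(f"planted targets absent from annotation: {sorted(missing)[:3]}")
    rng = config.rng(5)
    windows = {w.gene_id: w for w in promoter_windows(annotation)}
    samples = [f"chip{i + 1}" for i in range(config.n_chip_samples)]
    peaks: dict[str, list[Peak]] = {s: [] for s in samples}
    planted_intervals: list[tuple[int, int]] = []
    for gene in planted_targets:
        w = windows[gene]
        n_bound = int(rng.integers(2, config.n_chip_samples + 1))
        bound_in = rng.choice(samples, size=n_bound, replace=False)
        for sample in bound_in:
            length = int(np.clip(rng.normal(260, 40), 100, 600))
            lo = max(0, w.start - length + 1)
            start = int(rng.integers(lo, w.end - 1))
            peak = Peak(CHROM, start, start + length, sample, float(np.clip(rng.normal(13, 3), 0.5, None)))
            peaks[sample].append(peak)
            planted_intervals.append((peak.start, peak.end))
    # decoys: centred in inter-promoter gaps, never touching a window
    sorted_windows = sorted(windows.values(), key=lambda w: w.start)
    gaps = []
    prev_end = 0
    for w in sorted_windows:
        if w.start - prev_end > 1000:
            gaps.append((prev_end + 200, w.start - 200))
        prev_end = max(prev_end, w.end)
    if config.chrom_length - prev_end > 1000:
        gaps.append((prev_end + 200, config.chrom_length - 200))
    for sample in samples:
        for _ in range(config.n_decoy_peaks):
            g0, g1 = gaps[int(rng.integers(len(gaps)))]
            length = int(np.clip(rng.normal(260, 40), 100, min(600, g1 - g0)))
            start = int(rng.integers(g0, g1 - length + 1))
            peaks[sample].append(
                Peak(CHROM, start, start + length, sample, float(np.clip(rng.normal(12, 3), 0.5, None)))
            )
    for sample in samples:
        peaks[sample].sort(key=lambda p: (p.start, p.end))

    pool = make_profile_pool(config, annotation, planted_targets)
    genome = {CHROM: _make_genome(config, planted_intervals, rng)} if with_genome else {}
    return peaks, pool, genome


def _make_pool(config, universe, planted_targets, rng) -> list[ChipProfile]:
    n_univ = len(universe)
    # background profile sizes: 30-120 genes in a 1000-gene universe,
    # scaled down proportionally for smaller universes
    lo = max(2, min(30, n_univ // 10))
    hi = max(lo + 1, min(120, n_univ // 5))
    pool: list[ChipProfile] = []
    n_cof = min(config.n_cofactor_profiles, config.pool_size)
    for i in range(config.pool_size):
        pid = f"P{i + 1:04d}"
        if i < n_cof:
            n_from_planted = max(
                1, int(round(config.cofactor_target_frac * len(planted_targets)))
            )
            chosen = set(rng.choice(planted_targets, size=n_from_planted, replace=False))
            n_fill = int(rng.integers(lo, hi))
            chosen |= set(rng.choice(universe, size=n_fill, replace=False))
            pool.append(ChipProfile(pid, config.planted_cofactor_tf, frozenset(chosen)))
        else:
            tf = TF_ROSTER[int(rng.integers(len(TF_ROSTER)))]
            n_targets = int(rng.integers(lo, hi))
            chosen = set(rng.choice(universe, size=n_targets, replace=False))
            pool.append(ChipProfile(pid, tf, frozenset(chosen)))
    return pool


def _make_genome(config, planted_intervals, rng) -> str:
    p_gc = config.gc_background / 2.0
    p_at = (1.0 - config.gc_background) / 2.0
    bases = rng.choice(
        np.array(list("ACGT")), size=config.chrom_length, p=[p_at, p_gc, p_gc, p_at]
    )
    q_gc = config.gc_peak / 2.0
    q_at = (1.0 - config.gc_peak) / 2.0
    for start, end in planted_intervals:
        bases[start:end] = rng.choice(
            np.array(list("ACGT")), size=end - start, p=[q_at, q_gc, q_gc, q_at]
        )
    return "".join(bases)


# ------------------------------------------------------------------ network

def make_network_inputs(
    config: SynthConfig,
    annotation: Sequence[GeneModel],
    planted_targets: Sequence[str] = (),
) -> tuple[list[pd.DataFrame], pd.DataFrame, list[list[str]]]:
    """3 co-expression edge lists + PPI edge list + truth modules.

    Each planted module is a clique present in >= 2 of the 3 datasets;
    background edges are sparse and mostly single-dataset.  PPI edges
    concentrate within modules among PCGs.  When ``planted_targets`` is
    given, each planted lncRNA target additionally gets 2-dataset
    co-expression links to planted PCG targets (the high-confidence
    refinement signal).
    """
    rng = config.rng(6)
    by_type = {"lncRNA": [], "PCG": []}
    for g in annotation:
        by_type[g.biotype].append(g.gene_id)
    total = sum(size for size, _ in config.module_spec)
    for size, n_lnc in config.module_spec:
        if size > len(annotation):
            raise ValueError(f"module size {size} exceeds n_genes {len(annotation)}")
        if n_lnc > size:
            raise ValueError("module lncRNA count exceeds module size")
    if total > len(annotation):
        raise ValueError("module_spec exceeds the gene universe")
    lnc_free = [g for g in by_type["lncRNA"]]
    pcg_free = [g for g in by_type["PCG"]]
    rng.shuffle(lnc_free)
    rng.shuffle(pcg_free)
    modules: list[list[str]] = []
    for size, n_lnc in config.module_spec:
        members = [lnc_free.pop() for _ in range(n_lnc)]
        members += [pcg_free.pop() for _ in range(size - n_lnc)]
        modules.append(sorted(members))

    edges_by_ds: list[dict[frozenset, float]] = [{}, {}, {}]

    def add_edge(a, b, n_datasets, rho_lo, rho_hi):
        which = rng.choice(3, size=n_datasets, replace=False)
        for ds in which:
            edges_by_ds[ds][frozenset((a, b))] = float(rng.uniform(rho_lo, rho_hi))

    for members in modules:
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                add_edge(members[i], members[j], int(rng.choice([2, 3])), 0.6, 0.95)
    # sparse background: mostly 1-dataset, a touch of 2-dataset noise
    all_ids = [g.gene_id for g in annotation]
    n_background = 4 * len(annotation)
    for _ in range(n_background):
        a, b = rng.choice(all_ids, size=2, replace=False)
        if a == b:
            continue
        n_ds = 2 if rng.random() < 0.01 else 1
        add_edge(a, b, n_ds, 0.3, 0.6)
    # high-confidence refinement signal for planted lncRNA targets
    biotype = {g.gene_id: g.biotype for g in annotation}
    lnc_targets = [g for g in planted_targets if biotype.get(g) == "lncRNA"]
    pcg_targets = [g for g in planted_targets if biotype.get(g) == "PCG"]
    for lnc in lnc_targets:
        if not pcg_targets:
            break
        for partner in rng.choice(pcg_targets, size=min(2, len(pcg_targets)), replace=False):
            add_edge(lnc, partner, int(rng.choice([2, 3])), 0.6, 0.95)

    coexpr = []
    for d in edges_by_ds:
        rows = [(min(p), max(p), rho) for p, rho in d.items()]
        rows.sort()
        coexpr.append(pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho"]))
    ppi_rows = set()
    for members in modules:
        pcgs = [g for g in members if biotype[g] == "PCG"]
        for i in range(len(pcgs)):
            for j in range(i + 1, len(pcgs)):
                if rng.random() < 0.3:
                    ppi_rows.add((min(pcgs[i], pcgs[j]), max(pcgs[i], pcgs[j])))
    pcg_ids = by_type["PCG"]
    for _ in range(len(annotation) // 2):
        a, b = rng.choice(pcg_ids, size=2, replace=False)
        if a != b:
            ppi_rows.add((min(a, b), max(a, b)))
    ppi = pd.DataFrame(sorted(ppi_rows), columns=["gene_a", "gene_b"])
    return coexpr, ppi, modules


def make_genesets(
    config: SynthConfig,
    annotation: Sequence[GeneModel],
    modules: Sequence[Sequence[str]],
) -> dict[str, tuple[str, frozenset[str]]]:
    """GMT gene sets: one term covering each planted module + background."""
    rng = config.rng(7)
    all_ids = [g.gene_id for g in annotation]
    genesets: dict[str, tuple[str, frozenset[str]]] = {}
    for i, members in enumerate(modules):
        extra = set(rng.choice(all_ids, size=10, replace=False))
        genesets[f"MOD{i + 1}_PROCESS"] = (
            f"planted process covering module {i + 1}",
            frozenset(members) | extra,
        )
    for i in range(20):
        size = int(rng.integers(20, 80))
        genesets[f"BG{i + 1:02d}_PROCESS"] = (
            "background process",
            frozenset(rng.choice(all_ids, size=size, replace=False)),
        )
    return genesets


# ----------------------------------------------------------------- clinical

def make_clinical(config: SynthConfig) -> tuple[pd.DataFrame, dict]:
    """Paired tumor/normal qPCR table with planted covariate effects.

    Covariate group sizes are reproduced exactly; each covariate's level
    assignment is an independent permutation of the patients.  Tumor dCt
    = baseline + patient effect + tumor_shift + sum of covariate shifts
    + residual noise; the paired normal tissue shares the patient effect
    (dCt measurements within a patient are correlated, which is what
    makes the paired design informative).  Truth records the planted
    shifts.
    """
    spec = config.clinical_spec
    sizes = {cov: sum(n for _, n, _ in levels) for cov, levels in spec.items()}
    n_patients = next(iter(sizes.values()))
    if len(set(sizes.values())) != 1:
        raise ValueError(f"covariate group sizes disagree on cohort size: {sizes}")
    for cov, levels in spec.items():
        if min(n for _, n, _ in levels) < 1:
            raise ValueError(f"covariate {cov!r} has an empty level")
    rng = config.rng(8)
    table = pd.DataFrame({"sample_id": [f"pt{i + 1:03d}" for i in range(n_patients)]})
    shift_total = np.zeros(n_patients)
    for cov, levels in spec.items():
        assignment = np.concatenate([[lv] * n for lv, n, _ in levels])
        order = rng.permutation(n_patients)
        table[cov] = assignment[order]
        shift = np.concatenate([[s] * n for _, n, s in levels])
        shift_total += shift[order].astype(float)
    patient_effect = rng.normal(0.0, config.patient_sd, size=n_patients)
    dct_tumor = (
        config.baseline_dct
        + patient_effect
        + config.tumor_shift
        + shift_total
        + rng.normal(0.0, config.clinical_noise_sd, size=n_patients)
    )
    dct_normal = (
        config.baseline_dct
        + patient_effect
        + rng.normal(0.0, config.clinical_noise_sd, size=n_patients)
    )
    ct_ref_t = rng.normal(20.0, 0.5, size=n_patients)
    ct_ref_n = rng.normal(20.0, 0.5, size=n_patients)
    table["ct_target_tumor"] = np.round(ct_ref_t + dct_tumor, 4)
    table["ct_reference_tumor"] = np.round(ct_ref_t, 4)
    table["ct_target_normal"] = np.round(ct_ref_n + dct_normal, 4)
    table["ct_reference_normal"] = np.round(ct_ref_n, 4)
    truth = {
        "tumor_shift": config.tumor_shift,
        "covariate_shifts": {
            cov: {lv: s for lv, _, s in levels} for cov, levels in spec.items()
        },
    }
    return table, truth


# ------------------------------------------------------------------- driver

def generate_all(config: SynthConfig, outdir: str | Path) -> dict:
    """Generate and write every pipeline input; returns paths + truth."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = make_annotation(config)
    io.write_annotation(annotation, out / "annotation.tsv")
    expr, de_truth = make_expression(config, annotation)
    io.write_expression(expr, out / "expression.tsv")
    evidence = make_evidence(config, de_truth, annotation)
    evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
    planted_targets = pick_planted_targets(config, annotation, de_truth)
    peaks, pool, genome = make_chip_data(config, annotation, planted_targets)
    peak_paths = {}
    for sample, plist in peaks.items():
        path = out / f"peaks_{sample}.bed"
        io.write_peaks_bed(plist, path)
        peak_paths[sample] = str(path)
    io.write_profile_pool(pool, out / "pool.gmt")
    io.write_genome(genome, out / "genome.fa")
    coexpr, ppi, modules = make_network_inputs(config, annotation, planted_targets)
    coexpr_paths = []
    for i, df in enumerate(coexpr):
        path = out / f"coexpr_ds{i + 1}.tsv"
        df.to_csv(path, sep="\t", index=False)
        coexpr_paths.append(str(path))
    ppi.to_csv(out / "ppi.tsv", sep="\t", index=False)
    genesets = make_genesets(config, annotation, modules)
    io.write_genesets(genesets, out / "genesets.gmt")
    clinical, clin_truth = make_clinical(config)
    io.write_clinical(clinical, out / "clinical.tsv")
    truth = {
        "planted_de": de_truth.to_dict("list"),
        "planted_targets": planted_targets,
        "planted_cofactor_tf": config.planted_cofactor_tf,
        "modules": modules,
        "clinical": clin_truth,
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return {
        "annotation": str(out / "annotation.tsv"),
        "expression": str(out / "expression.tsv"),
        "evidence": str(out / "evidence.tsv"),
        "peaks": peak_paths,
        "pool": str(out / "pool.gmt"),
        "genome": str(out / "genome.fa"),
        "coexpr": coexpr_paths,
        "ppi": str(out / "ppi.tsv"),
        "genesets": str(out / "genesets.gmt"),
        "clinical": str(out / "clinical.tsv"),
        "truth": truth,
    }
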