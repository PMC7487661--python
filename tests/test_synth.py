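"""Generator contracts: planted structure, determinism, file round-trips."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tfnetminer import io, synth
from tfnetminer.targets import promoter_windows


class TestAnnotation:
    def test_biotype_proportions_and_bounds(self, small_config, small_annotation):
        n_lnc = sum(g.biotype == "lncRNA" for g in small_annotation)
        assert n_lnc == round(small_config.frac_lncrna * small_config.n_genes)
        assert len({g.gene_id for g in small_annotation}) == small_config.n_genes
        assert all(0 <= g.tss < small_config.chrom_length for g in small_annotation)
        assert {g.strand for g in small_annotation} == {"+", "-"}

    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            synth.make_annotation(synth.SynthConfig(n_genes=0))

    def test_overcrowded_chromosome_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            synth.make_annotation(synth.SynthConfig(n_genes=1000, chrom_length=100_000))

    def test_same_seed_identical_files(self, small_config, tmp_path):
        for d in ("a", "b"):
            io.write_annotation(synth.make_annotation(small_config), tmp_path / d)
        assert (tmp_path / "a").read_bytes() == (tmp_path / "b").read_bytes()


class TestExpression:
    def test_planted_shift_in_both_case_groups(self, small_config, small_annotation):
        cfg = synth.SynthConfig(seed=1, n_genes=50, chrom_length=400_000, noise_sd=0.0,
                                de_effect=2.0, n_planted_de=10)
        ann = synth.make_annotation(cfg)
        expr, truth = synth.make_expression(cfg, ann)
        groups = io.expression_groups(expr)
        for _, row in truth.iterrows():
            delta_p = (expr.loc[row.gene_id, groups["primary"]].mean()
                       - expr.loc[row.gene_id, groups["normal"]].mean())
            delta_m = (expr.loc[row.gene_id, groups["metastasis"]].mean()
                       - expr.loc[row.gene_id, groups["normal"]].mean())
            sign = 1 if row.direction == "up" else -1
            assert delta_p == pytest.approx(sign * 2.0)
            assert delta_m == pytest.approx(sign * 2.0)
        non_de = expr.drop(index=truth.gene_id)
        spread = non_de.max(axis=1) - non_de.min(axis=1)
        assert float(spread.max()) == 0.0  # noise-free: constant rows

    def test_zero_effect_means_empty_truth(self, small_config, small_annotation):
        cfg = synth.SynthConfig(de_effect=0.0, n_genes=40, chrom_length=200_000)
        ann = synth.make_annotation(cfg)
        _, truth = synth.make_expression(cfg, ann)
        assert truth.empty

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            synth.SynthConfig(n_samples_per_group=1)

    def test_planted_genes_detectable_by_ttest_oracle(self, small_annotation):
        """At de_effect=2, n=10/group, a plain two-sample t-test should
        reject the null for >90% of planted genes."""
        cfg = synth.SynthConfig(seed=11, n_genes=80, chrom_length=400_000,
                                n_samples_per_group=10, n_planted_de=30)
        ann = synth.make_annotation(cfg)
        expr, truth = synth.make_expression(cfg, ann)
        groups = io.expression_groups(expr)
        a = expr.loc[truth.gene_id, groups["normal"]].to_numpy()
        b = expr.loc[truth.gene_id, groups["primary"]].to_numpy()
        p = stats.ttest_ind(a, b, axis=1).pvalue
        assert (p < 0.05).mean() > 0.9


class TestChipData:
    def test_planted_targets_bound_in_two_samples_bruteforce(self, small_config,
                                                             small_annotation, small_chip):
        planted, peaks, _, _ = small_chip
        windows = {w.gene_id: w for w in promoter_windows(small_annotation)}
        for gene in planted:
            w = windows[gene]
            n_hit = sum(
                any(min(p.end, w.end) - max(p.start, w.start) >= 1 for p in plist)
                for plist in peaks.values()
            )
            assert n_hit >= 2

    def test_decoys_outside_all_promoters(self, small_config, small_annotation, small_chip):
        planted, peaks, _, _ = small_chip
        windows = promoter_windows(small_annotation)
        planted_set = set(planted)
        decoy_hits = 0
        for plist in peaks.values():
            for p in plist:
                for w in windows:
                    if w.gene_id not in planted_set:
                        assert min(p.end, w.end) - max(p.start, w.start) < 1, \
                            f"decoy touches {w.gene_id}"
        assert decoy_hits == 0

    def test_unknown_target_rejected(self, small_config, small_annotation):
        with pytest.raises(ValueError, match="absent"):
            synth.make_chip_data(small_config, small_annotation, ["nope"])

    def test_pool_composition(self, small_config, small_chip):
        _, _, pool, _ = small_chip
        assert len(pool) == small_config.pool_size
        n_cof = sum(p.tf_name == small_config.planted_cofactor_tf for p in pool)
        assert n_cof == small_config.n_cofactor_profiles

    def test_no_cofactor_when_disabled(self, small_config, small_annotation, small_expression):
        cfg = synth.SynthConfig(seed=2, n_genes=80, chrom_length=400_000,
                                pool_size=40, n_cofactor_profiles=0)
        ann = synth.make_annotation(cfg)
        _, truth = synth.make_expression(cfg, ann)
        planted = synth.pick_planted_targets(cfg, ann, truth)
        _, pool, _ = synth.make_chip_data(cfg, ann, planted)
        assert all(p.tf_name != cfg.planted_cofactor_tf for p in pool)

    def test_bed_bytes_deterministic(self, small_config, small_annotation,
                                     small_expression, tmp_path):
        _, de_truth = small_expression
        planted = synth.pick_planted_targets(small_config, small_annotation, de_truth)
        blobs = []
        for d in ("x", "y"):
            peaks, _, _ = synth.make_chip_data(small_config, small_annotation, planted)
            io.write_peaks_bed(peaks["chip1"], tmp_path / d)
            blobs.append((tmp_path / d).read_bytes())
        assert blobs[0] == blobs[1]

    def test_planted_peaks_gc_enriched(self, small_config, small_annotation, small_chip):
        planted, peaks, _, genome = small_chip
        seq = genome[synth.CHROM]
        windows = {w.gene_id: w for w in promoter_windows(small_annotation)}
        peak_gc, bg_gc = [], []
        planted_regions = []
        for gene in planted:
            w = windows[gene]
            for plist in peaks.values():
                for p in plist:
                    if min(p.end, w.end) - max(p.start, w.start) >= 1:
                        planted_regions.append(p)
        rng = np.random.default_rng(0)
        for p in planted_regions:
            sub = seq[p.start:p.end]
            peak_gc.append((sub.count("G") + sub.count("C")) / len(sub))
            start = int(rng.integers(0, len(seq) - 300))
            bg = seq[start:start + 300]
            bg_gc.append((bg.count("G") + bg.count("C")) / len(bg))
        res = stats.ttest_ind(peak_gc, bg_gc, alternative="greater")
        assert res.pvalue < 0.01


class TestNetworkInputs:
    def test_truth_module_sizes(self, small_config, small_annotation):
        _, _, modules = synth.make_network_inputs(small_config, small_annotation)
        assert sorted(len(m) for m in modules) == sorted(
            size for size, _ in small_config.module_spec
        )

    def test_within_module_edges_in_two_datasets(self, small_config, small_annotation):
        coexpr, _, modules = synth.make_network_inputs(small_config, small_annotation)
        pair_sets = [
            {frozenset((a, b)) for a, b in zip(ds.gene_a, ds.gene_b)} for ds in coexpr
        ]
        for module in modules:
            for i in range(len(module)):
                for j in range(i + 1, len(module)):
                    pair = frozenset((module[i], module[j]))
                    assert sum(pair in s for s in pair_sets) >= 2

    def test_background_sparser_than_modules(self, small_config, small_annotation):
        coexpr, _, modules = synth.make_network_inputs(small_config, small_annotation)
        from tfnetminer.coexpr import supported_pairs
        supported = supported_pairs(coexpr, 2)
        module_genes = {g for m in modules for g in m}
        n_mod_genes = len(module_genes)
        n_bg_genes = len(small_annotation) - n_mod_genes
        within = sum(1 for p in supported if p <= module_genes)
        outside = sum(1 for p in supported if not (p & module_genes))
        dens_within = within / (n_mod_genes * (n_mod_genes - 1) / 2)
        dens_bg = outside / (n_bg_genes * (n_bg_genes - 1) / 2)
        assert dens_bg < dens_within

    def test_oversized_module_rejected(self, small_config, small_annotation):
        cfg = synth.SynthConfig(n_genes=20, chrom_length=200_000, module_spec=[(30, 1)])
        ann = synth.make_annotation(cfg)
        with pytest.raises(ValueError, match="exceeds"):
            synth.make_network_inputs(cfg, ann)


class TestClinical:
    def test_group_sizes_exact(self, small_config):
        table, _ = synth.make_clinical(small_config)
        for cov, levels in small_config.clinical_spec.items():
            counts = table[cov].value_counts()
            for level, n, _ in levels:
                assert counts[level] == n

    def test_zero_shift_equal_means_in_expectation(self):
        spec = {"grp": [("a", 40, 0.0), ("b", 40, 0.0)]}
        diffs = []
        for seed in range(10):
            cfg = synth.SynthConfig(seed=seed, clinical_spec=spec)
            table, _ = synth.make_clinical(cfg)
            dct = table.ct_target_tumor - table.ct_reference_tumor
            diffs.append(dct[table.grp == "a"].mean() - dct[table.grp == "b"].mean())
        se = np.hypot(cfg.clinical_noise_sd, cfg.patient_sd) * np.sqrt(2 / 40) / np.sqrt(10)
        assert abs(np.mean(diffs)) < 3 * se

    def test_planted_metastasis_shift_recovered(self, small_config):
        table, truth = synth.make_clinical(small_config)
        dct = table.ct_target_tumor - table.ct_reference_tumor
        m0 = dct[table.metastasis == "M0"]
        m1 = dct[table.metastasis == "M1"]
        diff = m1.mean() - m0.mean()
        se = np.sqrt(m0.var(ddof=1) / len(m0) + m1.var(ddof=1) / len(m1))
        assert diff == pytest.approx(
            truth["covariate_shifts"]["metastasis"]["M1"], abs=2 * se
        )

    def test_inconsistent_cohort_size_rejected(self):
        spec = {"a": [("x", 10, 0.0)], "b": [("y", 11, 0.0)]}
        with pytest.raises(ValueError, match="disagree"):
            synth.make_clinical(synth.SynthConfig(clinical_spec=spec))


class TestRoundTrips:
    def test_all_outputs_roundtrip(self, small_config, tmp_path):
        paths = synth.generate_all(small_config, tmp_path)
        ann = io.read_annotation(paths["annotation"])
        assert len(ann) == small_config.n_genes
        expr = io.read_expression(paths["expression"])
        assert expr.shape[0] == small_config.n_genes
        assert set(io.expression_groups(expr)) == {"normal", "primary", "metastasis"}
        pool = io.read_profile_pool(paths["pool"])
        assert len(pool) == small_config.pool_size
        genome = io.read_genome(paths["genome"])
        assert len(genome[synth.CHROM]) == small_config.chrom_length
        for sample, path in paths["peaks"].items():
            peaks = io.read_peaks_bed(path, sample=sample)
            assert all(p.end > p.start for p in peaks)
        clin = io.read_clinical(paths["clinical"])
        assert len(clin) == 111
        genesets = io.read_genesets(paths["genesets"])
        assert all(members for _, (_, members) in genesets.items())

    def test_expression_values_preserved(self, small_config, small_annotation, tmp_path):
        expr, _ = synth.make_expression(small_config, small_annotation)
        io.write_expression(expr, tmp_path / "e.tsv")
        back = io.read_expression(tmp_path / "e.tsv")
        pd.testing.assert_frame_equal(expr.round(6), back, check_exact=False, atol=1e-6)
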