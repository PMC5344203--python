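import numpy as np
import pandas as pd
import pytest

from remodelscan import synthetic
from remodelscan.synthetic import SyntheticConfig


def small_config(**kw):
    base = dict(seed=7, n_chroms=2, chrom_length=200_000, n_genes=30, n_enhancers=10)
    base.update(kw)
    return SyntheticConfig(**base)


class TestAnnotation:
    def test_layout_contracts(self):
        cfg = small_config()
        genes, enh, sizes = synthetic.build_annotation(cfg)
        assert len(genes) == 30 and len(enh) == 10
        assert set(genes["strand"]) == {"+", "-"}
        # non-overlapping promoters per chromosome
        for _, sub in genes.groupby("chrom"):
            tss = np.sort(sub["tss"].to_numpy())
            assert (np.diff(tss) >= 2000).all()
        # enhancers at least 2 kb from every TSS
        for e in enh.itertuples():
            tss = genes.loc[genes["chrom"] == e.chrom, "tss"].to_numpy()
            mid = (e.start + e.end) // 2
            assert (np.abs(tss - mid) >= 2000).all()

    def test_zero_enhancers(self):
        _, enh, _ = synthetic.build_annotation(small_config(n_enhancers=0))
        assert len(enh) == 0

    def test_determinism(self):
        a = synthetic.build_annotation(small_config())
        b = synthetic.build_annotation(small_config())
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_capacity_error(self):
        with pytest.raises(synthetic.CapacityError):
            synthetic.build_annotation(small_config(chrom_length=20_000, n_genes=50))


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        {"dynamics_fractions": {"fixed": 0.5, "shift": 0.4, "loss": 0.05, "gain": 0.0}},
        {"shift_range": (0, 120)},
        {"shift_range": (1, 200)},
        {"coverage": 0.0},
        {"expression_coupling": -1.0},
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(synthetic.ConfigError):
            small_config(**kw).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config()
        cfg.to_yaml(tmp_path / "c.yaml")
        back = SyntheticConfig.from_yaml(tmp_path / "c.yaml")
        assert back == cfg


class TestNucleosomeTruth:
    def test_label_counts_match_fractions(self):
        cfg = small_config(ndr_dynamic_fraction=0.0, ndr_stable_max_weight=0.0,
                           n_enhancers=0)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        arr = truth.nucleosomes[truth.nucleosomes["origin"] == "array"]
        frac = arr["label"].value_counts(normalize=True)
        for lab, f in cfg.dynamics_fractions.items():
            # exact up to multinomial rounding plus boundary-squeeze relabels
            assert frac.get(lab, 0.0) == pytest.approx(f, abs=0.02)

    def test_all_fixed_gives_identical_maps(self):
        cfg = small_config(
            dynamics_fractions={"fixed": 1.0, "shift": 0.0, "loss": 0.0, "gain": 0.0},
            n_enhancers=0, ndr_dynamic_fraction=0.0, ndr_stable_max_weight=0.0,
        )
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        nucs = truth.nucleosomes
        assert (nucs["dyad_a"] == nucs["dyad_b"]).all()

    def test_labels_agree_with_dyad_maps(self):
        """Brute-force comparison of the two dyad maps reproduces the labels."""
        cfg = small_config()
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        nucs = truth.nucleosomes
        lo, hi = cfg.shift_range
        for row in nucs.itertuples():
            has_a, has_b = not pd.isna(row.dyad_a), not pd.isna(row.dyad_b)
            if row.label == "fixed":
                assert has_a and has_b and row.dyad_a == row.dyad_b
            elif row.label == "loss":
                assert has_a and not has_b
            elif row.label == "gain":
                assert has_b and not has_a
            elif row.label == "shift" and row.origin == "array":
                assert has_a and has_b and 1 <= abs(row.dyad_b - row.dyad_a) <= hi

    def test_state_b_min_separation(self):
        cfg = small_config()
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        for _, sub in truth.nucleosomes.dropna(subset=["dyad_b"]).groupby("chrom"):
            gaps = np.diff(np.sort(sub["dyad_b"].to_numpy()))
            assert (gaps >= 147).all()

    def test_truth_round_trip(self, tmp_path):
        cfg = small_config()
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        truth.write(tmp_path)
        back = synthetic.TruthRecord.read(tmp_path)
        pd.testing.assert_frame_equal(back.nucleosomes, truth.nucleosomes)
        assert back.chrom_sizes == truth.chrom_sizes


class TestMnaseSampling:
    def test_total_reads_near_poisson_mean(self, default_truth, default_config, default_tags):
        n_nucs = default_truth.nucleosomes["dyad_a"].notna().sum()
        w = default_truth.nucleosomes.loc[
            default_truth.nucleosomes["dyad_a"].notna(), "weight_a"].sum()
        expected = default_config.coverage * w
        assert abs(len(default_tags["A"]) - expected) < 4 * np.sqrt(expected)
        assert n_nucs > 2000

    def test_zero_fuzziness_reads_sit_on_dyads(self):
        cfg = small_config(fuzziness_bp=0.0, n_enhancers=0,
                           ndr_dynamic_fraction=0.0, ndr_stable_max_weight=0.0)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        tags = synthetic.sample_mnase_reads(truth, cfg, "A")
        plus = tags["strand"] == "+"
        dyads = np.where(plus, tags["pos5"] + 73, tags["pos5"] - 73)
        planted = set(truth.nucleosomes["dyad_a"].dropna().astype(int))
        assert set(dyads.tolist()) <= planted

    def test_read_dyad_sd_matches_planted_fuzziness(self):
        cfg = small_config(coverage=200.0, fuzziness_bp=20.0, n_enhancers=0,
                           ndr_dynamic_fraction=0.0, ndr_stable_max_weight=0.0,
                           dynamics_fractions={"fixed": 1.0, "shift": 0.0,
                                               "loss": 0.0, "gain": 0.0})
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        tags = synthetic.sample_mnase_reads(truth, cfg, "A")
        plus = tags["strand"] == "+"
        tags = tags.assign(dyad=np.where(plus, tags["pos5"] + 73, tags["pos5"] - 73))
        one = truth.nucleosomes.iloc[0]
        members = tags[(tags["chrom"] == one["chrom"])
                       & (tags["dyad"].sub(one["dyad_a"]).abs() <= 73)]
        assert np.std(members["dyad"]) == pytest.approx(20.0, abs=2.5)

    def test_determinism(self, default_truth, default_config):
        a = synthetic.sample_mnase_reads(default_truth, default_config, "A")
        b = synthetic.sample_mnase_reads(default_truth, default_config, "A")
        pd.testing.assert_frame_equal(a, b)


class TestHmSampling:
    def test_promoter_levels_bimodal(self, default_truth, default_config):
        synthetic.sample_hm_reads(default_truth, default_config, "H3K4me3", "A")
        levels = default_truth.genes["H3K4me3_level_a"].to_numpy()
        marked = default_truth.genes["H3K4me3_marked_a"].to_numpy()
        assert levels[marked].mean() > 3 * levels[~marked].mean()

    def test_empty_stream_without_elements_or_background(self):
        cfg = small_config(n_enhancers=0, chip_background_per_kb=0.0,
                           chip_reads_per_level=0.0)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        tags = synthetic.sample_hm_reads(truth, cfg, "H3K9ac", "A")
        assert len(tags) == 0

    def test_reads_within_chromosomes(self, default_truth, default_config):
        tags = synthetic.sample_hm_reads(default_truth, default_config, "H3K27ac", "B")
        sizes = tags["chrom"].map(default_truth.chrom_sizes)
        assert (tags["pos5"] >= 0).all() and (tags["pos5"] < sizes).all()


class TestExpression:
    def test_zero_coupling_zero_noise_constant_fpkm(self):
        cfg = small_config(expression_coupling=0.0, expression_noise_sd=0.0,
                           n_enhancers=0)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        expr = synthetic.sample_expression(truth, cfg)
        assert expr["fpkm_a"].nunique() == 1

    def test_coupling_sign_on_planted_truth(self):
        cfg = small_config(expression_coupling=1.0)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        from scipy.stats import spearmanr
        rho, _ = spearmanr(truth.genes["ndr_weight_a"], truth.genes["fpkm_a"])
        assert rho < -0.5

    def test_synergy_cases_follow_enhancer_direction(self):
        cfg = small_config(n_enhancers=10, mark_persistence=0.3)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        cases = truth.genes[truth.genes["synergy_case"]]
        assert len(cases) > 0
        gmap = truth.genes.set_index("gene_id")
        for e in truth.enhancers.itertuples():
            up = e.state_a != "active" and e.state_b == "active"
            down = e.state_a == "active" and e.state_b != "active"
            if not (up or down) or not e.planted_gene_id:
                continue
            g = gmap.loc[e.planted_gene_id]
            if not g["synergy_case"]:
                continue
            fc = np.log2((g["fpkm_b"] + 1) / (g["fpkm_a"] + 1))
            assert (fc > 0) == up
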