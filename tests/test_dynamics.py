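import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import adjusted_rand_score

from remodelscan import dynamics, synthetic
from remodelscan.dynamics import (
    UnsortedInputError,
    feature_enrichment,
    match_nucleosomes,
    tss_composite_profile,
    tss_difference_clusters,
    tss_matrix,
)


def calls(positions, chrom="chr1"):
    return pd.DataFrame({"chrom": chrom, "dyad": np.asarray(positions, dtype=np.int64)})


def oracle_matching(a, b, max_shift=127):
    """Exhaustive max-cardinality / min-total-distance matching."""
    best = (0, 0)
    for k in range(min(len(a), len(b)), -1, -1):
        found = None
        for asub in itertools.combinations(range(len(a)), k):
            for bsub in itertools.permutations(range(len(b)), k):
                if all(abs(a[i] - b[j]) <= max_shift for i, j in zip(asub, bsub)):
                    tot = sum(abs(a[i] - b[j]) for i, j in zip(asub, bsub))
                    if found is None or tot < found:
                        found = tot
        if found is not None:
            return k, found
    return best


class TestMatching:
    @pytest.mark.parametrize("a,b,expected_status,expected_shift", [
        ([1000], [1000], "fixed", 0),
        ([1000], [1100], "shift", 100),   # footprints overlap 47 bp
    ])
    def test_pairing_rules(self, a, b, expected_status, expected_shift):
        m, _ = match_nucleosomes(calls(a), calls(b))
        assert m.loc[0, "status"] == expected_status
        assert m.loc[0, "shift_bp"] == expected_shift

    def test_beyond_overlap_limit_is_loss_plus_gain(self):
        m, _ = match_nucleosomes(calls([1000]), calls([1140]))  # |d|=140 > 127
        assert sorted(m["status"]) == ["gain", "loss"]

    def test_three_node_instance_prefers_nearest(self):
        m, _ = match_nucleosomes(calls([1000]), calls([1010, 1120]))
        matched = m[m["status"] == "shift"]
        assert matched["dyad_b"].item() == 1010
        assert (m["status"] == "gain").sum() == 1

    def test_unsorted_input_rejected(self):
        bad = pd.DataFrame({"chrom": "chr1", "dyad": [500, 100]})
        with pytest.raises(UnsortedInputError):
            match_nucleosomes(bad, calls([100]))

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            na, nb = rng.integers(0, 9, size=2)
            a = np.sort(rng.choice(2000, size=na, replace=False))
            b = np.sort(rng.choice(2000, size=nb, replace=False))
            m, _ = match_nucleosomes(calls(a), calls(b))
            matched = m[m["status"].isin(["fixed", "shift"])]
            total = int((matched["dyad_b"] - matched["dyad_a"]).abs().sum())
            k_o, tot_o = oracle_matching(list(a), list(b))
            assert (len(matched), total) == (k_o, tot_o)

    @given(st.data())
    @settings(max_examples=50, deadline=None)
    def test_partition_and_symmetry(self, data):
        a = sorted(data.draw(st.sets(st.integers(0, 3000), max_size=10)))
        b = sorted(data.draw(st.sets(st.integers(0, 3000), max_size=10)))
        m, s = match_nucleosomes(calls(a), calls(b))
        c = s["counts"]
        assert c["fixed"] + c["shift"] + c["loss"] == len(a)
        assert c["fixed"] + c["shift"] + c["gain"] == len(b)
        m2, s2 = match_nucleosomes(calls(b), calls(a))
        assert s2["counts"]["loss"] == c["gain"]
        assert s2["counts"]["gain"] == c["loss"]
        shifts = np.sort(m.loc[m["status"] == "shift", "shift_bp"].to_numpy())
        shifts2 = np.sort(-m2.loc[m2["status"] == "shift", "shift_bp"].to_numpy())
        assert np.array_equal(shifts, shifts2)

    def test_planted_fraction_recovery_on_truth_maps(self):
        """Matching the planted dyad maps reproduces the planted dynamics
        fractions to within 3 percentage points."""
        cfg = synthetic.SyntheticConfig(seed=2, n_enhancers=0,
                                        ndr_dynamic_fraction=0.0,
                                        ndr_stable_max_weight=0.0)
        genes, enh, sizes = synthetic.build_annotation(cfg)
        truth = synthetic.plant_nucleosome_truth(genes, enh, sizes, cfg)
        ca = calls_from_truth(truth, "dyad_a")
        cb = calls_from_truth(truth, "dyad_b")
        _, s = match_nucleosomes(ca, cb)
        for lab, f in cfg.dynamics_fractions.items():
            assert abs(s["fractions_union"][lab] - f) <= 0.03


def calls_from_truth(truth, col):
    sub = truth.nucleosomes.dropna(subset=[col])
    return (sub.rename(columns={col: "dyad"})[["chrom", "dyad"]]
            .astype({"dyad": np.int64})
            .sort_values(["chrom", "dyad"], kind="stable").reset_index(drop=True))


class TestFeatureEnrichment:
    def genes(self):
        return pd.DataFrame({
            "gene_id": ["g1"], "chrom": ["chr1"], "strand": ["+"],
            "tss": [5000], "tes": [9000],
        })

    def test_density_formula(self):
        # 10 dyads inside the 2-kb promoter of a single gene
        result = feature_enrichment(calls([4500] * 10), self.genes(), {"chr1": 20_000})
        prom = result[result["feature"] == "promoter"].iloc[0]
        assert prom["length_bp"] == 2000
        assert prom["calls_per_kb"] == pytest.approx(5.0)

    def test_promoter_takes_precedence_over_genic(self):
        # dyad at 5500: inside both the promoter [4000,6000) and the body
        result = feature_enrichment(calls([5500]), self.genes(), {"chr1": 20_000})
        assert result.set_index("feature").loc["promoter", "n_calls"] == 1
        assert result.set_index("feature").loc["genic", "n_calls"] == 0

    def test_uniform_dyads_equal_density(self):
        rng = np.random.default_rng(5)
        d = calls(np.sort(rng.integers(0, 20_000, size=10_000)))
        result = feature_enrichment(d, self.genes(), {"chr1": 20_000})
        dens = result["calls_per_kb"].to_numpy()
        assert dens.max() / dens.min() < 1.10


class TestTssProfiles:
    def test_uniform_tags_give_flat_profile(self):
        rng = np.random.default_rng(6)
        n = 200_000
        tags = pd.DataFrame({
            "chrom": "chr1",
            "pos5": np.sort(rng.integers(0, 99_000, size=n)),
            "strand": rng.choice(["+", "-"], size=n),
        })
        genes = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(20)], "chrom": "chr1",
            "strand": ["+", "-"] * 10, "tss": np.arange(5000, 85_000, 4000),
        })
        prof = tss_composite_profile(genes, {"chr1": 100_000}, n, tags=tags,
                                     metric="occupancy")
        cv = prof["smoothed"].std() / prof["smoothed"].mean()
        assert cv < 0.05

    def test_ndr_minimum_and_plus_one_maximum(self, default_tags, default_truth):
        genes = default_truth.genes
        prof = tss_composite_profile(genes, default_truth.chrom_sizes,
                                     len(default_tags["A"]), tags=default_tags["A"],
                                     metric="occupancy")
        sm = prof.set_index("offset")["smoothed"]
        window = sm.loc[-400:400]
        assert -200 <= window.idxmin() <= 50
        assert 25 <= sm.loc[0:200].idxmax() <= 125

    def test_call_density_mode_counts_dyads(self, default_calls, default_truth,
                                            default_tags):
        prof = tss_composite_profile(default_truth.genes, default_truth.chrom_sizes,
                                     len(default_tags["A"]), calls=default_calls["A"],
                                     metric="call_density")
        assert len(prof) == 200  # 10-bp bins over +/-1 kb
        assert (prof["value"] >= 0).all()

    def test_invalid_bin_width_rejected(self, default_truth, default_tags):
        with pytest.raises(ValueError):
            tss_composite_profile(default_truth.genes, default_truth.chrom_sizes,
                                  100, tags=default_tags["A"], metric="occupancy",
                                  bin_bp=3)


class TestDifferenceClusters:
    def make_matrix(self, values, n_genes):
        idx = [f"g{i}" for i in range(n_genes)]
        return pd.DataFrame(values, index=idx)

    def test_identical_matrices_flagged_degenerate(self):
        m = self.make_matrix(np.ones((10, 8)), 10)
        res = tss_difference_clusters(m, m.copy(), k=5, seed=0)
        assert res.degenerate and res.labels.nunique() == 1

    def test_k1_single_label(self):
        a = self.make_matrix(np.zeros((10, 8)), 10)
        b = self.make_matrix(np.arange(80).reshape(10, 8), 10)
        res = tss_difference_clusters(a, b, k=1, seed=0)
        assert res.labels.nunique() == 1 and not res.degenerate

    def test_archetype_patterns_recovered(self):
        rng = np.random.default_rng(7)
        n_bins, per = 80, 500
        arch = np.zeros((5, n_bins))
        for i in range(5):
            arch[i, i * 16:(i + 1) * 16] = 10.0
        rows = np.repeat(np.arange(5), per)
        diff = arch[rows] + rng.normal(0, 1.0, size=(5 * per, n_bins))
        a = self.make_matrix(np.zeros_like(diff), 5 * per)
        b = self.make_matrix(diff, 5 * per)
        res = tss_difference_clusters(a, b, k=5, seed=0)
        assert adjusted_rand_score(rows, res.labels.to_numpy()) >= 0.9
        assert len(res.ordered_gene_ids) == 5 * per

    def test_mismatched_gene_sets_rejected(self):
        a = self.make_matrix(np.zeros((5, 4)), 5)
        b = self.make_matrix(np.zeros((6, 4)), 6)
        with pytest.raises(ValueError):
            tss_difference_clusters(a, b)


class TestTssMatrix:
    def test_shape_and_scale(self, default_tags, default_truth):
        mat = tss_matrix(default_tags["A"], default_truth.genes,
                         default_truth.chrom_sizes, len(default_tags["A"]),
                         bin_bp=5)
        assert mat.shape == (len(default_truth.genes), 400)
        assert (mat.to_numpy() >= 0).all()
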