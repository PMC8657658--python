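"""Size factors, NB Wald test, BH adjustment, direction labelling."""

import numpy as np
import pandas as pd
import pytest

from cystirep import synthdata as sd
from cystirep.dge import bh_adjust, deg_summary, label_degs, nb_wald_test, size_factors


def brute_force_bh(p):
    """Independent step-up oracle: literal textbook rule."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        df = pd.DataFrame({"A": [10, 100, 1], "B": [10, 100, 1]})
        assert np.allclose(size_factors(df), [1.0, 1.0])

    def test_scaling_equivariance(self, tiny_counts):
        f = size_factors(tiny_counts)
        assert f["B"] / f["A"] == pytest.approx(2.0)
        # multiply one sample by lambda -> its factor scales by lambda
        # relative to the others (factors are defined up to the
        # geometric-mean-one normalization)
        scaled = tiny_counts.assign(A=tiny_counts["A"] * 3)
        f2 = size_factors(scaled)
        assert (f2["A"] / f2["B"]) / (f["A"] / f["B"]) == pytest.approx(3.0, rel=1e-12)

    def test_median_of_ratios_by_hand(self, tiny_counts):
        # per-gene geometric means: sqrt(200), sqrt(20000), sqrt(2)
        # ratios for A: all 1/sqrt(2); for B: all sqrt(2)
        f = size_factors(tiny_counts)
        assert f["A"] == pytest.approx(1 / np.sqrt(2))
        assert f["B"] == pytest.approx(np.sqrt(2))

    def test_geometric_mean_close_to_one(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(200, 6)))
        f = size_factors(counts)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=0.05)

    def test_no_common_gene_raises(self):
        df = pd.DataFrame({"A": [5, 0], "B": [0, 5]})
        with pytest.raises(ValueError, match="pseudo-reference"):
            size_factors(df)

    def test_matches_independent_median_of_ratios_oracle(self, rng):
        """Cross-check against pydeseq2's size-factor fit on a small matrix."""
        anndata = pytest.importorskip("anndata")
        from pydeseq2.dds import DeseqDataSet

        counts = pd.DataFrame(
            rng.poisson(rng.uniform(5, 200, size=(30, 1)), size=(30, 6)),
            columns=[f"S{i}" for i in range(6)],
        )
        meta = pd.DataFrame({"condition": ["a"] * 3 + ["b"] * 3}, index=counts.columns)
        dds = DeseqDataSet(counts=counts.T, metadata=meta, design="~condition", quiet=True)
        dds.fit_size_factors()
        theirs = np.asarray(dds.obs["size_factors"], dtype=float)
        ours = size_factors(counts).to_numpy()
        assert np.allclose(ours, theirs, rtol=1e-8)


class TestNBWald:
    def test_equal_groups_give_zero_lfc(self):
        df = pd.DataFrame({"A": [100], "B": [100], "C": [100], "D": [100]},
                          index=pd.Index(["g1"], name="gene"))
        res = nb_wald_test(df, ["wt", "wt", "ko", "ko"], reference="wt",
                           factors=pd.Series(1.0, index=df.columns))
        assert res["log2fc"].iloc[0] == pytest.approx(0.0)

    def test_all_zero_gene_gets_p_one(self):
        df = pd.DataFrame(
            {"A": [0, 50], "B": [0, 60], "C": [0, 55], "D": [0, 52]},
            index=pd.Index(["dead", "alive"], name="gene"),
        )
        res = nb_wald_test(df, ["wt", "wt", "ko", "ko"], reference="wt",
                           factors=pd.Series(1.0, index=df.columns))
        dead = res.set_index("gene").loc["dead"]
        assert dead["p"] == 1.0 and dead["log2fc"] == 0.0

    def test_single_sample_group_rejected(self):
        df = pd.DataFrame({"A": [1], "B": [2], "C": [3]})
        with pytest.raises(ValueError, match="2 samples"):
            nb_wald_test(df, ["wt", "ko", "ko"], reference="wt")

    def test_lfc_estimate_recovered_at_n20(self):
        """Gene at means 100 vs 400 and tight dispersion: log2fc ~ 2 +- 0.1."""
        cfg = sd.CountsSimConfig(
            n_genes=50, n_per_group=20, baseline_mean=100.0, dispersion=0.01,
            planted_up=(("G00007", 2.0),), seed=21,
        )
        counts, _ = sd.simulate_counts(cfg)
        res = nb_wald_test(counts, ["wt"] * 20 + ["ko"] * 20, reference="wt")
        lfc = res.set_index("gene").loc["G00007", "log2fc"]
        assert lfc == pytest.approx(2.0, abs=0.1)

    def test_null_type_i_error_near_nominal(self):
        cfg = sd.CountsSimConfig(n_genes=10_000, n_per_group=3, baseline_mean=100.0,
                                 dispersion=0.02, seed=77)
        counts, _ = sd.simulate_counts(cfg)
        res = nb_wald_test(counts, ["wt"] * 3 + ["ko"] * 3, reference="wt")
        assert float((res["p"] < 0.05).mean()) == pytest.approx(0.05, abs=0.01)

    def test_permuting_sample_order_changes_nothing(self, rng):
        cfg = sd.CountsSimConfig(n_genes=100, n_per_group=3, baseline_mean=80.0,
                                 dispersion=0.05, planted_up=(("G00002", 1.5),), seed=4)
        counts, _ = sd.simulate_counts(cfg)
        groups = ["wt"] * 3 + ["ko"] * 3
        base = nb_wald_test(counts, groups, reference="wt")
        perm = rng.permutation(6)
        shuffled = nb_wald_test(
            counts.iloc[:, perm], [groups[i] for i in perm], reference="wt"
        )
        pd.testing.assert_frame_equal(base, shuffled)


class TestBH:
    def test_step_up_by_hand(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_identities(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)
        assert bh_adjust([0.03])[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_brute_force_oracle_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(0, 1, size=rng.integers(1, 40))
            assert np.allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestLabelling:
    @pytest.mark.parametrize(
        "fdr,lfc,expected",
        [
            (0.04, 1.2, "up"),
            (0.04, 1.0, "up"),      # fold cut boundary inclusive
            (0.04, -0.5, "ns"),     # significant but below the fold cut
            (0.05, 3.0, "ns"),      # FDR cut strict
            (0.01, -1.0, "down"),
        ],
    )
    def test_direction_rules(self, fdr, lfc, expected):
        table = pd.DataFrame({"gene": ["g"], "log2fc": [lfc], "p": [fdr], "fdr": [fdr]})
        assert label_degs(table)["direction"].iloc[0] == expected

    def test_partition_property(self, rng):
        table = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(500)],
                "log2fc": rng.normal(0, 1.5, 500),
                "p": rng.uniform(0, 0.2, 500),
            }
        )
        labelled = label_degs(table)
        s = deg_summary(labelled)
        assert s["total_significant"] == s["up"] + s["down"] + s["significant_below_fold_cut"]


def test_planted_deg_benchmark_sensitivity_and_fdr():
    """200 planted DEGs at |effect| >= 1, n=3/group: sensitivity >= 0.8, FDR <= 0.1."""
    rng = np.random.default_rng(99)
    genes = sd.gene_ids(5000)
    chosen = rng.choice(5000, size=200, replace=False)
    planted_up = tuple((genes[i], float(rng.uniform(1.0, 2.5))) for i in chosen[:100])
    planted_down = tuple((genes[i], -float(rng.uniform(1.0, 2.5))) for i in chosen[100:])
    cfg = sd.CountsSimConfig(
        n_genes=5000, n_per_group=3, baseline_mean=100.0, dispersion=0.02,
        planted_up=planted_up, planted_down=planted_down, seed=15,
    )
    counts, truth = sd.simulate_counts(cfg)
    res = label_degs(nb_wald_test(counts, ["wt"] * 3 + ["ko"] * 3, reference="wt"))
    merged = res.merge(truth, on="gene")
    true_dir = np.where(merged["log2_effect"] >= 1, "up",
                        np.where(merged["log2_effect"] <= -1, "down", "ns"))
    planted = true_dir != "ns"
    called = merged["direction"] != "ns"
    sensitivity = (planted & (merged["direction"] == true_dir)).sum() / planted.sum()
    fdr = (called & ~planted).sum() / max(called.sum(), 1)
    assert sensitivity >= 0.8
    assert fdr <= 0.1
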