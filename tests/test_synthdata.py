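"""Generator contracts: determinism, planted truth, distributional checks."""

import numpy as np
import pandas as pd
import pytest

from cystirep import synthdata as sd
from cystirep.cystine import call_cystine_hits, compound_activities
from cystirep.reversal import tails_to_signature, vote_reversal


class TestScreenSim:
    def test_control_well_counts(self, small_screen_cfg):
        plates, _ = sd.simulate_screen(small_screen_cfg)
        per_plate = plates.groupby("plate_id")["role"].value_counts().unstack()
        assert (per_plate["vehicle"] == 4).all()
        assert (per_plate["positive"] == 4).all()

    def test_zero_noise_effect_is_exact(self, small_screen_cfg):
        plates, _ = sd.simulate_screen(small_screen_cfg)
        act = compound_activities(plates).set_index("compound_id")["activity"]
        assert act["CPD0003"] == pytest.approx(20.0, abs=1e-12)
        assert (act.drop(["CPD0003", "CPD0017"]) == pytest.approx(100.0)) is not False

    def test_determinism(self, small_screen_cfg):
        a, ta = sd.simulate_screen(small_screen_cfg)
        b, tb = sd.simulate_screen(small_screen_cfg)
        pd.testing.assert_frame_equal(a, b)
        pd.testing.assert_frame_equal(ta, tb)

    def test_different_seeds_differ(self, small_screen_cfg):
        import dataclasses
        noisy = dataclasses.replace(small_screen_cfg, noise_sd=0.05)
        other = dataclasses.replace(noisy, seed=6)
        a, _ = sd.simulate_screen(noisy)
        b, _ = sd.simulate_screen(other)
        assert not a["cystine_nmol"].equals(b["cystine_nmol"])

    def test_geometry_overflow_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.ScreenSimConfig(n_compounds=10, wells_per_plate=8,
                               neg_ctrl_per_plate=4, pos_ctrl_per_plate=4)

    def test_unknown_planted_compound_rejected(self):
        with pytest.raises(sd.ConfigError, match="not in"):
            sd.ScreenSimConfig(n_compounds=10, planted_hits=(("CPD9999", 0.5),))

    def test_effect_out_of_range_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.ScreenSimConfig(n_compounds=10, planted_hits=(("CPD0001", 1.5),))

    def test_full_screen_hit_recovery(self):
        """1200 compounds, 24 depleters at effect 0.8, noise 0.05: exact recovery."""
        depleters = tuple((c, 0.8) for c in sd.compound_ids(1200)[::50])
        cfg = sd.ScreenSimConfig(n_compounds=1200, planted_hits=depleters,
                                 noise_sd=0.05, seed=7)
        assert len(depleters) == 24
        plates, truth = sd.simulate_screen(cfg)
        results = call_cystine_hits(compound_activities(plates))
        called = set(results.loc[results["hit"], "compound_id"])
        assert called == {c for c, _ in depleters}


class TestCountsSim:
    def test_poisson_limit_at_small_dispersion(self):
        cfg = sd.CountsSimConfig(n_genes=300, n_per_group=200, baseline_mean=200.0,
                                 dispersion=1e-6, seed=3)
        counts, _ = sd.simulate_counts(cfg)
        ratio = counts.var(axis=1, ddof=1) / counts.mean(axis=1)
        assert ratio.mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_effect_law_of_large_numbers(self):
        cfg = sd.CountsSimConfig(n_genes=10, n_per_group=500, baseline_mean=100.0,
                                 dispersion=0.05, planted_up=(("G00004", 2.0),), seed=11)
        counts, _ = sd.simulate_counts(cfg)
        ko = counts.loc["G00004", [c for c in counts if c.startswith("KO")]]
        assert ko.mean() == pytest.approx(400.0, rel=0.05)

    def test_counts_are_nonnegative_integers(self):
        cfg = sd.CountsSimConfig(n_genes=100, n_per_group=3, seed=2)
        counts, _ = sd.simulate_counts(cfg)
        assert (counts.to_numpy() >= 0).all()
        assert np.issubdtype(counts.to_numpy().dtype, np.integer)

    def test_determinism(self):
        cfg = sd.CountsSimConfig(n_genes=50, n_per_group=3, seed=42)
        a, _ = sd.simulate_counts(cfg)
        b, _ = sd.simulate_counts(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_overlapping_planted_sets_rejected(self):
        with pytest.raises(sd.ConfigError, match="both"):
            sd.CountsSimConfig(n_genes=10, planted_up=(("G00001", 1.0),),
                               planted_down=(("G00001", -1.0),))

    def test_weak_effects_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.CountsSimConfig(n_genes=10, planted_up=(("G00001", 0.5),))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(sd.ConfigError):
            sd.CountsSimConfig(n_genes=0)
        with pytest.raises(sd.ConfigError):
            sd.CountsSimConfig(n_genes=10, dispersion=0.0)


class TestPRLSim:
    def genome(self, n=60):
        return tuple(f"g{i:03d}" for i in range(n))

    def cfg(self, planted, n_compounds=5, tail=10, seed=0):
        return sd.PRLSimConfig(genome=self.genome(), n_compounds=n_compounds,
                               planted_reversers=planted, tail_size=tail, seed=seed)

    def test_lists_are_permutations(self):
        lists, _ = sd.simulate_prls(self.cfg((("g005", ("up", 3)),)))
        for rl in lists:
            assert sorted(rl.genes) == sorted(self.genome())

    def test_full_support_gene_in_every_relevant_tail(self):
        lists, _ = sd.simulate_prls(self.cfg((("g005", ("up", 5)),)))
        for rl in lists:
            sig = tails_to_signature(rl, 10)
            assert "g005" in sig.down_set  # disease-up gene -> compound-down tail

    def test_partial_support_outside_tails_elsewhere(self):
        lists, truth = sd.simulate_prls(self.cfg((("g007", ("down", 3)),)))
        supporters = set(truth.loc[truth["gene"] == "g007", "compounds"].iloc[0].split(","))
        in_up, outside = 0, 0
        for rl in lists:
            sig = tails_to_signature(rl, 10)
            if rl.compound_id in supporters:
                assert "g007" in sig.up_set
                in_up += 1
            else:
                assert "g007" not in sig.up_set | sig.down_set
                outside += 1
        assert in_up == 3 and outside == 2

    def test_three_of_five_support_not_selected_at_k4(self):
        deg = pd.DataFrame({"gene": ["g007"], "direction": ["up"]})
        lists, _ = sd.simulate_prls(self.cfg((("g007", ("up", 3)),)))
        sigs = [tails_to_signature(rl, 10) for rl in lists]
        table, _ = vote_reversal(deg, sigs, k=4)
        assert table.empty

    def test_empty_planting_yields_empty_selection(self):
        lists, truth = sd.simulate_prls(self.cfg(()))
        assert truth.empty
        deg = pd.DataFrame({"gene": list(self.genome()), "direction": ["ns"] * 60})
        table, _ = vote_reversal(deg, [tails_to_signature(rl, 10) for rl in lists], k=4)
        assert table.empty

    def test_determinism(self):
        cfg = self.cfg((("g005", ("up", 2)), ("g050", ("down", 4))), seed=13)
        a, ta = sd.simulate_prls(cfg)
        b, tb = sd.simulate_prls(cfg)
        assert [rl.genes for rl in a] == [rl.genes for rl in b]
        pd.testing.assert_frame_equal(ta, tb)

    def test_gene_absent_from_genome_rejected(self):
        with pytest.raises(sd.ConfigError, match="absent"):
            self.cfg((("NOT_THERE", ("up", 2)),))

    def test_support_exceeding_compounds_rejected(self):
        with pytest.raises(sd.ConfigError, match="exceeds"):
            self.cfg((("g005", ("up", 6)),))


class TestDoseResponseSim:
    def test_shape_and_determinism(self):
        a, ta = sd.simulate_dose_response(["X", "Y"], seed=4)
        b, _ = sd.simulate_dose_response(["X", "Y"], seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert len(a) == 2 * 4 * 3
        assert set(ta["compound_id"]) == {"X", "Y"}
        assert ((ta["ec50"] >= 1.0) & (ta["ec50"] <= 10.0)).all()


def test_write_table_has_schema_comment(tmp_path):
    df = pd.DataFrame({"a": [1]})
    path = tmp_path / "t.tsv"
    sd.write_table(df, path, schema="truth-table")
    first = path.read_text().splitlines()[0]
    assert first.startswith("# cystirep truth-table")
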