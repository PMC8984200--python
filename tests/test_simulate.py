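"""Synthetic-data generators: determinism, invariants, planted structure."""

import numpy as np
import pandas as pd
import pytest

import keelscan as ks


class TestPoolCounts:
    def test_fixed_depth_matches_design(self):
        """Pools of 36 and 48 at 5x per individual give depths 180 and 240."""
        cfg = ks.SimConfig(n_snps=500, seed=1)
        assert cfg.pool_depths == (180, 240)
        df = ks.simulate_pool_counts(cfg)
        assert ((df["ref_count_1"] + df["alt_count_1"]) == 180).all()
        assert ((df["ref_count_2"] + df["alt_count_2"]) == 240).all()

    def test_counts_bounded_and_sorted(self):
        cfg = ks.SimConfig(n_chrom=3, n_snps=3000, background_fst=0.1, seed=2)
        df = ks.simulate_pool_counts(cfg)
        assert len(df) == 3000
        for col in ("ref_count_1", "alt_count_1", "ref_count_2", "alt_count_2"):
            assert (df[col] >= 0).all()
        for _, grp in df.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing
            assert grp["pos"].min() >= 1

    def test_zero_background_no_sweeps_identical_frequencies(self):
        cfg = ks.SimConfig(n_snps=2000, background_fst=0.0, seed=3)
        df = ks.simulate_pool_counts(cfg)
        assert np.array_equal(df["true_p1"], df["true_p2"])
        ft = ks.fst_table(df)
        # only read-sampling noise remains; its expected size is
        # (1/d1 + 1/d2)/4 ~ 0.0024 at depths 180/240
        assert abs(ft.loc[ft["defined"], "fst"].mean()) < 0.01

    def test_sweep_region_elevates_windowed_fst(self):
        """Windowed F_ST inside a planted sweep beats outside, 50/50 replicates."""
        wins = 0
        for rep in range(50):
            cfg = ks.SimConfig(
                n_chrom=1,
                chrom_length=2_000_000,
                n_snps=1_000,
                background_fst=0.02,
                sweep_regions=[("chr1", 800_000, 1_200_000, 0.3)],
                seed=1000 + rep,
            )
            ft = ks.fst_table(ks.simulate_pool_counts(cfg))
            win = ks.make_windows(ft)
            inside = win[(win["start"] >= 800_000) & (win["end"] <= 1_200_000)]
            outside = win[(win["end"] <= 800_000) | (win["start"] >= 1_200_000)]
            if inside["mean_fst"].mean() > outside["mean_fst"].mean():
                wins += 1
        assert wins == 50

    def test_overlapping_sweeps_rejected(self):
        cfg = ks.SimConfig(
            sweep_regions=[
                ("chr1", 100_000, 300_000, 0.3),
                ("chr1", 200_000, 400_000, 0.4),
            ]
        )
        with pytest.raises(ValueError, match="overlapping sweep regions"):
            cfg.validate()

    def test_sweep_validation(self):
        with pytest.raises(ValueError, match="exceed background"):
            ks.SimConfig(
                background_fst=0.3, sweep_regions=[("chr1", 0, 1000, 0.1)]
            ).validate()
        with pytest.raises(ValueError, match="outside chromosome"):
            ks.SimConfig(
                chrom_length=1000, sweep_regions=[("chr1", 500, 2000, 0.3)]
            ).validate()

    def test_determinism(self):
        cfg = ks.SimConfig(n_snps=500, background_fst=0.05, seed=9)
        a = ks.simulate_pool_counts(cfg)
        b = ks.simulate_pool_counts(cfg)
        pd.testing.assert_frame_equal(a, b)


class TestPedigreePhenotypes:
    def test_topological_order_and_parent_presence(self):
        cfg = ks.QuantGenConfig(n_founders=50, n_generations=3, seed=4)
        ped, phen = ks.simulate_pedigree_phenotypes(cfg)
        seen = set()
        for row in ped.itertuples(index=False):
            for parent in (row.sire, row.dam):
                assert parent == 0 or parent in seen
            seen.add(row.id)
        assert set(phen["kb_level"]) <= {1, 2, 3, 4}
        assert set(phen["cage_tier"]) <= {"down", "middle", "up"}

    def test_realized_latent_h2_near_design(self):
        """Sample h2 of latent scores within 0.05 of 0.264 at n >= 5000."""
        cfg = ks.QuantGenConfig(
            n_founders=600, n_generations=3, family_size=3,
            sigma2_a=0.043, sigma2_e=0.120, cage_effects=(0.0, 0.0, 0.0), seed=5,
        )
        ped, phen = ks.simulate_pedigree_phenotypes(cfg)
        assert len(phen) >= 5000
        h2_realized = phen["breeding_value"].var() / phen["latent"].var()
        assert h2_realized == pytest.approx(0.2638, abs=0.05)

    def test_null_heritability(self):
        cfg = ks.QuantGenConfig(n_founders=200, sigma2_a=0.0, seed=6)
        _, phen = ks.simulate_pedigree_phenotypes(cfg)
        assert np.allclose(phen["breeding_value"], 0.0)

    def test_degenerate_thresholds_all_level_four(self):
        cfg = ks.QuantGenConfig(n_founders=100, thresholds=(-10.0, -9.0, -8.0), seed=7)
        _, phen = ks.simulate_pedigree_phenotypes(cfg)
        assert (phen["kb_level"] == 4).all()

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="n_generations"):
            ks.QuantGenConfig(n_generations=0).validate()
        with pytest.raises(ValueError, match="increasing"):
            ks.QuantGenConfig(thresholds=(1.0, 0.5, 2.0)).validate()

    def test_determinism(self):
        cfg = ks.QuantGenConfig(n_founders=80, seed=8)
        p1, f1 = ks.simulate_pedigree_phenotypes(cfg)
        p2, f2 = ks.simulate_pedigree_phenotypes(cfg)
        pd.testing.assert_frame_equal(p1, p2)
        pd.testing.assert_frame_equal(f1, f2)


class TestFastq:
    def test_exact_violator_counts(self):
        recs = ks.simulate_fastq(
            100, read_len=100, adapter_fraction=0.10, n_fraction=0.05,
            lowq_fraction=0.05, seed=1,
        )
        assert len(recs) == 100
        from keelscan.simulate import DEFAULT_ADAPTER
        from keelscan.qc import classify_read

        reasons = [classify_read(s, q, DEFAULT_ADAPTER) for _, s, q in recs]
        assert reasons.count("adapter") == 10
        assert reasons.count("nfrac") == 5
        assert reasons.count("lowq") == 5
        assert reasons.count(None) == 80

    def test_empty_and_clean(self):
        assert ks.simulate_fastq(0) == []
        recs = ks.simulate_fastq(50, seed=2)
        assert all(len(s) == 100 and len(q) == 100 for _, s, q in recs)

    def test_read_shorter_than_adapter_rejected(self):
        with pytest.raises(ValueError, match="adapter"):
            ks.simulate_fastq(10, read_len=5, adapter_fraction=0.5)

    def test_determinism(self):
        a = ks.simulate_fastq(30, adapter_fraction=0.2, seed=3)
        b = ks.simulate_fastq(30, adapter_fraction=0.2, seed=3)
        assert a == b


class TestAnnotation:
    def test_disjoint_intervals_and_count(self):
        genes, _ = ks.simulate_annotation(100, {"chr1": 10_000_000}, seed=1)
        assert len(genes) == 100
        g = genes.sort_values("start")
        assert (g["start"].to_numpy()[1:] >= g["end"].to_numpy()[:-1]).all()
        assert (g["start"] >= 0).all() and (g["end"] <= 10_000_000).all()

    def test_gene_sets_sizes_and_membership(self):
        genes, sets = ks.simulate_annotation(
            100, {"chr1": 5_000_000, "chr2": 5_000_000}, seed=2, set_sizes=(10, 20, 30)
        )
        assert [len(v) for v in sets.values()] == [10, 20, 30]
        all_members = [g for v in sets.values() for g in v]
        assert len(all_members) == len(set(all_members))  # partition: disjoint
        assert set(all_members) <= set(genes["gene_id"])

    def test_capacity_error(self):
        with pytest.raises(ValueError, match="do not fit"):
            ks.simulate_annotation(100, {"chr1": 100_000}, gene_length=5_000)

    def test_determinism(self):
        a = ks.simulate_annotation(50, {"chr1": 1_000_000}, seed=5, set_sizes=(10, 15))
        b = ks.simulate_annotation(50, {"chr1": 1_000_000}, seed=5, set_sizes=(10, 15))
        pd.testing.assert_frame_equal(a[0], b[0])
        assert a[1] == b[1]
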