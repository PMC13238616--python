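import json

import numpy as np
import pytest

from abalonepg import diversity, differentiation, roh, simdata, vcfio


def tiny_cfg(**kw):
    base = dict(
        scaffolds=[("s1", 100_000)],
        schedule=[(0, (40,))],
        n_generations=5,
        mu=2e-7,
        recomb=1e-7,
        sample_sizes=(10,),
        seed=1,
    )
    base.update(kw)
    return simdata.SimConfig(**base)


class TestConfigValidation:
    def test_sample_larger_than_deme_rejected(self):
        with pytest.raises(ValueError, match="exceeds final deme size"):
            tiny_cfg(sample_sizes=(50,))

    def test_desk_scale_bounds_enforced(self):
        with pytest.raises(ValueError, match="genome length"):
            tiny_cfg(scaffolds=[("s1", 20_000_000)])
        with pytest.raises(ValueError, match="deme size"):
            tiny_cfg(schedule=[(0, (6000,))], sample_sizes=(10,))

    def test_selected_locus_outside_scaffold_rejected(self):
        with pytest.raises(ValueError, match="outside scaffold"):
            tiny_cfg(selected=[simdata.SelectedLocus("s1", 200_000, 0.5, 0)])

    def test_schedule_lookup(self):
        cfg = tiny_cfg(schedule=[(0, (40,)), (3, (20,))], sample_sizes=(10,))
        assert cfg.sizes_at(0) == (40,)
        assert cfg.sizes_at(2) == (40,)
        assert cfg.sizes_at(3) == (20,)


class TestSimulate:
    def test_no_mutation_no_init_no_sites(self):
        res = simdata.simulate_population(tiny_cfg(mu=0.0, sfs_init=False))
        assert res.gm.n_sites == 0

    def test_seed_makes_output_bit_reproducible(self):
        a = simdata.simulate_population(tiny_cfg(seed=3))
        b = simdata.simulate_population(tiny_cfg(seed=3))
        np.testing.assert_array_equal(a.gm.G, b.gm.G)
        assert list(a.gm.sites["pos"]) == list(b.gm.sites["pos"])

    def test_isolation_drift_fst_matches_expectation(self):
        """Two isolated demes: the Weir-Cockerham (Hudson-like) FST between
        them matches the per-deme drift fixation F = 1 - e^(-t/2N)."""
        t_gen, N = 20, 100
        expect = 1.0 - np.exp(-t_gen / (2.0 * N))
        means = []
        for seed in range(5):
            cfg = simdata.SimConfig(
                scaffolds=[("s1", 400_000)],
                schedule=[(0, (N, N))],
                n_generations=t_gen,
                mu=2e-7,
                recomb=1e-7,
                migration=0.0,
                sample_sizes=(15, 15),
                seed=100 + seed,
            )
            res = simdata.simulate_population(cfg)
            common, _ = vcfio.split_by_maf(res.gm)
            # genome-wide ratio-of-sums (one window per scaffold): the
            # estimator form the drift expectation applies to
            ws = differentiation.fst_windowed(
                common, ("southeast", "northwest"), 400_000
            )
            means.append(ws[0].value)
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean() - expect) < 3 * se + 0.01

    def test_high_migration_removes_structure(self):
        cfg = simdata.SimConfig(
            scaffolds=[("s1", 400_000)],
            schedule=[(0, (100, 100))],
            n_generations=40,
            mu=2e-7,
            recomb=1e-7,
            migration=0.5,
            sample_sizes=(15, 15),
            seed=6,
        )
        res = simdata.simulate_population(cfg)
        common, _ = vcfio.split_by_maf(res.gm)
        snps = differentiation.fst_per_snp(common, ("southeast", "northwest"))
        assert abs(np.nanmean(snps["fst"])) < 0.02

    def test_neutral_constant_mean_d_near_zero_over_replicates(self):
        means = []
        for seed in range(10):
            cfg = tiny_cfg(seed=200 + seed, schedule=[(0, (60,))],
                           sample_sizes=(15,), n_generations=5)
            res = simdata.simulate_population(cfg)
            ws = diversity.windowed_tajimas_d(res.gm, 100_000)
            vals = [w.value for w in ws if not np.isnan(w.value)]
            means.append(np.mean(vals))
        means = np.array(means)
        se = means.std(ddof=1) / np.sqrt(len(means))
        assert abs(means.mean()) < 3 * se + 0.05

    def test_selection_drives_advantaged_allele_up(self):
        cfg = tiny_cfg(
            schedule=[(0, (100,))],
            n_generations=30,
            sample_sizes=(20,),
            selected=[simdata.SelectedLocus("s1", 50_000, 0.8, 0)],
            seed=8,
        )
        res = simdata.simulate_population(cfg)
        sf = res.selected_freqs
        first = sf[sf.generation == 0]["freq"].iloc[0]
        last = sf[sf.generation == 30]["freq"].iloc[0]
        assert last > first

    def test_deme_census_follows_schedule(self):
        # observable via the sampled matrix dimensions at each epoch's end
        cfg = tiny_cfg(schedule=[(0, (40,)), (3, (12,))], sample_sizes=(12,))
        res = simdata.simulate_population(cfg)
        assert res.gm.n_samples == 12
        assert res.true_ne_schedule() == [(0, 40), (3, 12)]


def test_bottleneck_tajimas_d_agrees_with_coalescent_oracle(bottleneck_result):
    """The forward simulator's genome-mean D for the expansion + crash +
    recovery history matches an independent coalescent simulation of the
    same demography (both show the rare-allele excess)."""
    import msprime

    cfg = bottleneck_result.config
    ws = diversity.windowed_tajimas_d(bottleneck_result.gm, 50_000)
    d_forward = diversity.mean_window_value(ws)

    # same epochs, times counted backwards from sampling
    gens = cfg.n_generations
    dem = msprime.Demography()
    dem.add_population(name="A", initial_size=cfg.schedule[-1][1][0])
    for start, sizes in reversed(cfg.schedule[:-1]):
        end_of_epoch = [g for g, _ in cfg.schedule if g > start][0]
        dem.add_population_parameters_change(
            time=gens - end_of_epoch, initial_size=sizes[0], population="A"
        )
    ds = []
    for rep in range(3):
        ts = msprime.sim_ancestry(
            samples={"A": cfg.sample_sizes[0]}, demography=dem,
            sequence_length=1_000_000, recombination_rate=cfg.recomb,
            random_seed=17 + rep,
        )
        ts = msprime.sim_mutations(ts, rate=cfg.mu, random_seed=170 + rep)
        ds.append(np.nanmean(ts.Tajimas_D(windows=np.linspace(0, 1_000_000, 21))))
    d_coalescent = float(np.mean(ds))
    assert d_forward < 0 and d_coalescent < 0
    assert abs(d_forward - d_coalescent) < 0.5


class TestPlantROH:
    def test_plant_then_detect_overlapping_segment(self):
        res = simdata.simulate_population(simdata.roh_config(seed=9, n_sample=5))
        sample = res.gm.samples["sample"].iloc[0]
        simdata.plant_roh(res, sample, "scaffold_1", 300_000, 500_000)
        segs = [
            s for s in roh.detect_roh(res.gm)
            if s.sample == sample and s.scaffold == "scaffold_1"
        ]
        assert any(s.start < 500_000 and s.end > 300_000 for s in segs)

    def test_two_samples_same_interval_collapse_to_one(self):
        res = simdata.simulate_population(simdata.roh_config(seed=9, n_sample=5))
        s1, s2 = res.gm.samples["sample"].iloc[:2]
        for s in (s1, s2):
            simdata.plant_roh(res, s, "scaffold_2", 200_000, 400_000)
        segs = [s for s in roh.detect_roh(res.gm) if s.scaffold == "scaffold_2"]
        uniques = roh.collapse_roh(segs)
        planted = [u for u in uniques if set(u.carriers) >= {s1, s2}]
        assert len(planted) == 1

    def test_unknown_sample_rejected(self):
        res = simdata.simulate_population(tiny_cfg())
        with pytest.raises(ValueError, match="unknown sample"):
            simdata.plant_roh(res, "nobody", "s1", 1, 100)


class TestWriteFixture:
    def test_header_lengths_and_truth(self, tmp_path, small_sim):
        paths = simdata.write_fixture(small_sim, tmp_path)
        header = [
            l for l in paths["vcf"].read_text().splitlines() if l.startswith("##contig")
        ]
        assert header == [
            f"##contig=<ID={n},length={l}>" for n, l in small_sim.config.scaffolds
        ]
        truth = json.loads(paths["truth"].read_text())
        assert truth["seed"] == small_sim.config.seed
        assert [tuple(s) for s in truth["scaffolds"]] == small_sim.config.scaffolds

    def test_truth_selected_loci_match_config(self, tmp_path):
        cfg = tiny_cfg(selected=[simdata.SelectedLocus("s1", 50_000, 0.5, 0)])
        res = simdata.simulate_population(cfg)
        paths = simdata.write_fixture(res, tmp_path)
        truth = json.loads(paths["truth"].read_text())
        assert truth["selected_loci"] == [
            {"scaffold": "s1", "pos": 50_000, "s": 0.5, "deme": 0, "allele": "alt"}
        ]
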