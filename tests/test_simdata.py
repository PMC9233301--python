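import numpy as np
import pandas as pd
import pytest

from hapshare import simdata
from hapshare.simdata import AncestryMosaic, SimConfig


def small_cfg(**kw):
    base = dict(
        n_subpops=1,
        size_per_generation=40,
        n_generations=6,
        chromosomes=((50.0, 300, 50_000_000),),
        seed=1,
    )
    base.update(kw)
    return SimConfig(**base)


class TestPedigree:
    def test_g0_contains_only_founders(self):
        ped = simdata.simulate_pedigree(small_cfg(n_generations=0))
        assert ped.n_generations == 0
        assert (ped.final.mother == -1).all() and (ped.final.father == -1).all()

    def test_identity_migration_keeps_parents_within_subpop(self):
        cfg = small_cfg(n_subpops=3, n_generations=5, size_per_generation=30)
        ped = simdata.simulate_pedigree(cfg)
        for g in range(1, 6):
            gen = ped.generations[g]
            prev = ped.generations[g - 1]
            assert (prev.subpop[gen.mother] == gen.subpop).all()
            assert (prev.subpop[gen.father] == gen.subpop).all()

    def test_deterministic_under_seed(self):
        cfg = small_cfg(n_subpops=2, size_per_generation=50, n_generations=10, seed=1)
        p1 = simdata.simulate_pedigree(cfg)
        p2 = simdata.simulate_pedigree(cfg)
        for g1, g2 in zip(p1.generations, p2.generations):
            assert (g1.mother == g2.mother).all() and (g1.father == g2.father).all()
            assert (g1.subpop == g2.subpop).all() and (g1.sex == g2.sex).all()

    def test_insufficient_parents_rejected(self):
        with pytest.raises(ValueError, match="insufficient parents"):
            SimConfig(n_subpops=1, size_per_generation=1, n_generations=2)

    def test_migration_rows_must_normalise(self):
        with pytest.raises(ValueError, match="migration"):
            SimConfig(n_subpops=2, migration=[[0.5, 0.2], [0.0, 1.0]])


class TestTransmission:
    def test_founder_mosaics_are_single_intervals(self):
        cfg = small_cfg(n_generations=0)
        ped = simdata.simulate_pedigree(cfg)
        mos = simdata.transmit_haplotypes(ped, cfg)
        fids = set()
        for h in mos.haps:
            (starts, ids) = h[0]
            assert starts.tolist() == [0.0] and len(ids) == 1
            fids.add(int(ids[0]))
        assert len(fids) == len(mos.haps)  # founder haplotypes all distinct

    def test_zero_length_chromosome_has_no_crossovers(self):
        cfg = small_cfg(chromosomes=((50.0, 100, 50_000_000), (0.0, 1, 1000)), n_generations=3)
        ped = simdata.simulate_pedigree(cfg)
        mos = simdata.transmit_haplotypes(ped, cfg)
        for h in mos.haps:
            assert len(h[1][1]) == 1  # Poisson(0) crossovers: one founder block

    def test_crossover_count_matches_poisson_rate(self):
        # children of one founder pair on a 100 cM chromosome: every crossover
        # switches founder id, so intervals-1 counts crossovers exactly
        n_child = 5000
        cfg = SimConfig(
            n_subpops=1,
            size_per_generation=np.array([[2, n_child]]),
            n_generations=1,
            chromosomes=((100.0, 10, 100_000_000),),
            seed=3,
        )
        ped = simdata.simulate_pedigree(cfg)
        mos = simdata.transmit_haplotypes(ped, cfg)
        n_cross = [len(h[0][1]) - 1 for h in mos.haps]
        mean = np.mean(n_cross)
        se = np.std(n_cross) / np.sqrt(len(n_cross))
        assert abs(mean - 1.0) <= 3 * se

    def test_mosaics_tile_chromosomes(self):
        cfg = small_cfg(n_generations=5)
        ped = simdata.simulate_pedigree(cfg)
        mos = simdata.transmit_haplotypes(ped, cfg)
        for h in mos.haps:
            starts, ids = h[0]
            assert starts[0] == 0.0
            assert np.all(np.diff(starts) > 0)
            assert starts[-1] < 50.0
            assert np.all(ids[1:] != ids[:-1])


class TestTruthIbd:
    def _mosaic(self, haps, L=100.0):
        built = [
            [(np.array([s for s, _ in h], dtype=float), np.array([f for _, f in h]))]
            for h in haps
        ]
        n = len(haps) // 2
        return AncestryMosaic(built, [L], [f"I{i}" for i in range(n)], 1000)

    def test_unrecombined_copies_share_whole_chromosome(self):
        mos = self._mosaic([[(0, 1)], [(0, 2)], [(0, 1)], [(0, 3)]])
        seg = simdata.truth_ibd(mos, min_cM=1)
        seg = seg[seg.id_a != seg.id_b]
        assert len(seg) == 1
        r = seg.iloc[0]
        assert (r.start_cM, r.end_cM) == (0.0, 100.0)

    def test_disjoint_founder_sets_share_nothing(self):
        mos = self._mosaic([[(0, 1), (40, 2)], [(0, 3)], [(0, 4), (60, 5)], [(0, 6)]])
        assert len(simdata.truth_ibd(mos, min_cM=0)) == 0

    def test_interval_intersection_example(self):
        mos = self._mosaic(
            [[(0, 10), (30, 20)], [(0, 99)], [(0, 10), (50, 30)], [(0, 98)]]
        )
        seg = simdata.truth_ibd(mos, min_cM=1)
        seg = seg[(seg.id_a == "I0") & (seg.id_b == "I1") & (seg.hap_a == 0) & (seg.hap_b == 0)]
        assert len(seg) == 1
        assert (seg.iloc[0].start_cM, seg.iloc[0].end_cM) == (0.0, 30.0)

    def test_negative_threshold_rejected(self):
        mos = self._mosaic([[(0, 1)], [(0, 2)], [(0, 3)], [(0, 4)]])
        with pytest.raises(ValueError):
            simdata.truth_ibd(mos, min_cM=-1)

    def test_segments_disjoint_after_merging(self):
        cfg = small_cfg(n_generations=8, size_per_generation=30)
        sim = simdata.simulate(cfg)
        seg = sim.truth_ibd(min_cM=0.5)
        for _, grp in seg.groupby(["id_a", "hap_a", "id_b", "hap_b", "chrom"]):
            s = grp.sort_values("start_cM")
            assert (s.start_cM.values[1:] > s.end_cM.values[:-1]).all()

    def test_cousin_mating_raises_autozygosity_monotonically(self):
        means = []
        for rate in (0.0, 0.1, 0.3):
            cfg = SimConfig(
                n_subpops=1,
                size_per_generation=300,
                n_generations=12,
                cousin_mating_rate=rate,
                chromosomes=((100.0, 10, 100_000_000),) * 2,
                seed=5,
            )
            ped = simdata.simulate_pedigree(cfg)
            mos = simdata.transmit_haplotypes(ped, cfg)
            means.append(simdata.autozygosity(mos).mean())
        assert means[0] < means[1] < means[2]


class TestSpectrumAgreement:
    def test_truth_lengths_match_closed_form(self):
        """Constant diploid size, deep pedigree: the truth-IBD length
        histogram over disjoint haplotype pairs matches the finite-chromosome
        closed form within Monte-Carlo error.

        The closed form is a per-coalescence marginal approximation: maximal
        truth segments concatenate adjacent IBD of different coalescence
        depths, which inflates the extreme tail at large counts, so the check
        runs at a pair sample where sampling error dominates that bias.
        """
        from scipy import stats

        from hapshare import demography as dm

        cfg = SimConfig(
            n_subpops=1, size_per_generation=200, n_generations=50,
            chromosomes=((100.0, 10, 100_000_000),) * 20, seed=3,
        )
        ped = simdata.simulate_pedigree(cfg)
        mos = simdata.transmit_haplotypes(ped, cfg)
        pairs = [
            (4 * i + a, 4 * i + 2 + b)
            for i in range(12)
            for a in (0, 1)
            for b in (0, 1)
        ]
        truth = simdata.truth_ibd(mos, min_cM=4.0, pairs=pairs)
        edges = np.array([4.0, 5.5, 7.5, 10.0, 14.0, 20.0, 2000.0])
        counts, _ = np.histogram(truth.length_cM.values, bins=edges)
        per_pair = dm.expected_spectrum(
            200.0, 20.0, edges, G=50, chrom_lengths_cM=[100.0] * 20
        )
        expected = per_pair * len(pairs)
        _, p = stats.chisquare(counts, expected * counts.sum() / expected.sum())
        assert p > 0.01


class TestGenotypes:
    def test_identical_mosaics_give_identical_sequences(self):
        mos = AncestryMosaic(
            [
                [(np.array([0.0, 30.0]), np.array([4, 7]))],
                [(np.array([0.0]), np.array([2]))],
                [(np.array([0.0, 30.0]), np.array([4, 7]))],
                [(np.array([0.0]), np.array([5]))],
            ],
            [100.0],
            ["I0", "I1"],
            10,
        )
        panel = simdata.genotype_panel(mos, small_cfg(chromosomes=((100.0, 500, 100_000_000),)))
        assert (panel.alleles[0] == panel.alleles[2]).all()

    def test_total_error_rate_complements_panel(self):
        cfg = small_cfg(n_generations=2)
        ped = simdata.simulate_pedigree(cfg)
        mos = simdata.transmit_haplotypes(ped, cfg)
        clean = simdata.genotype_panel(mos, cfg)
        flipped = simdata.genotype_panel(
            mos, small_cfg(n_generations=2, genotype_error_rate=1.0)
        )
        assert (flipped.alleles == 1 - clean.alleles).all()

    def test_alleles_identical_inside_truth_segments(self, deep_sim, deep_sim_truth):
        panel = deep_sim.panel
        idx = {v: i for i, v in enumerate(panel.individuals)}
        truth = deep_sim_truth[deep_sim_truth.id_a != deep_sim_truth.id_b]
        rng = np.random.default_rng(0)
        rows = truth.sample(min(300, len(truth)), random_state=1)
        for r in rows.itertuples():
            sl = panel.chrom_slice(r.chrom)
            cm = panel.site_cM[sl]
            sel = (cm >= r.start_cM) & (cm <= r.end_cM)
            ha = panel.alleles[2 * idx[r.id_a] + r.hap_a, sl][sel]
            hb = panel.alleles[2 * idx[r.id_b] + r.hap_b, sl][sel]
            assert (ha == hb).all()

    def test_simulate_is_reproducible(self):
        cfg = small_cfg(n_generations=4)
        a = simdata.simulate(cfg)
        b = simdata.simulate(cfg)
        assert (a.panel.alleles == b.panel.alleles).all()
        assert a.labels.equals(b.labels)
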