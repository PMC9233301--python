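import numpy as np
import pandas as pd
import pytest

from conftest import make_panel
from oracles import brute_identity_runs
from hapshare import ibd, simdata


def _filler(rng, S):
    """Two haplotypes that match nothing for long stretches."""
    return rng.integers(0, 2, (2, S)).astype(np.uint8)


class TestDetect:
    def test_fully_identical_pair_one_segment(self):
        rng = np.random.default_rng(0)
        S = 200
        x = rng.integers(0, 2, S).astype(np.uint8)
        a = np.vstack([x, 1 - x, x, 1 - x])
        cm = np.linspace(0, 100, S)
        seg = ibd.detect_ibd(make_panel(a, cm=cm), min_cM=1.0)
        seg = seg[(seg.hap_a == 0) & (seg.hap_b == 0)]
        assert len(seg) == 1
        assert seg.iloc[0].length_cM == pytest.approx(100.0)

    def test_run_below_threshold_not_reported(self):
        rng = np.random.default_rng(1)
        S = 100
        cm = np.linspace(0, 9.9, S)  # 0.1 cM spacing
        a = rng.integers(0, 2, (4, S)).astype(np.uint8)
        a[2] = 1 - a[0]
        a[2, 10:20] = a[0, 10:20]  # 10-site identical run: 0.9 cM
        a[1] = 1 - a[3]
        seg = ibd.detect_ibd(make_panel(a, cm=cm), min_cM=1.0)
        pairs = set(zip(seg.id_a, seg.hap_a, seg.id_b, seg.hap_b))
        assert ("I0", 0, "I1", 0) not in pairs

    def test_matches_brute_force_on_random_panels(self):
        rng = np.random.default_rng(7)
        for _ in range(15):
            n_ind = int(rng.integers(2, 6))
            S = int(rng.integers(10, 150))
            a = rng.integers(0, 2, (2 * n_ind, S)).astype(np.uint8)
            cm = np.sort(rng.uniform(0, 30, S))
            min_cM = float(rng.uniform(0.5, 5.0))
            panel = make_panel(a, cm=cm)
            det = ibd.detect_ibd(panel, min_cM=min_cM)
            got = {
                (2 * panel.individuals.index(r.id_a) + r.hap_a,
                 2 * panel.individuals.index(r.id_b) + r.hap_b,
                 r.start_site, r.end_site)
                for r in det.itertuples()
            }
            expected = {
                (x, y, s, e)
                for (x, y, s, e) in brute_identity_runs(a, cm, min_cM)
                if x // 2 != y // 2
            }
            assert got == expected

    def test_unsorted_cm_rejected(self):
        a = np.zeros((4, 5), dtype=np.uint8)
        cm = np.array([0.0, 2.0, 1.0, 3.0, 4.0])
        with pytest.raises(ValueError):
            ibd.detect_ibd(make_panel(a, cm=cm), min_cM=1.0)


class TestMergeRule:
    def _panel_with_gap(self, gap_cm, n_discordant):
        """Pair (I0 h0, I1 h0) with two adjacent segments separated by a
        5-site gap of the given genetic width holding the given number of
        discordant sites; segments are supplied as a frame, as an upstream
        detector tolerant of isolated errors would."""
        rng = np.random.default_rng(3)
        S = 105
        run1, gap, run2 = slice(0, 50), slice(50, 55), slice(55, 105)
        cm = np.empty(S)
        cm[run1] = np.linspace(0, 10, 50)
        eps = 0.01
        cm[gap] = np.linspace(cm[49] + eps, cm[49] + gap_cm - eps, 5)
        cm[run2] = np.linspace(cm[49] + gap_cm, cm[49] + gap_cm + 10, 50)
        h0 = rng.integers(0, 2, S).astype(np.uint8)
        h1 = h0.copy()
        flip = 50 + np.arange(n_discordant)
        h1[flip] = 1 - h0[flip]
        filler = 1 - np.vstack([h0, h0])
        a = np.vstack([h0, filler[0], h1, filler[1]])
        panel = make_panel(a, cm=cm)
        seg = pd.DataFrame(
            [
                dict(id_a="I0", hap_a=0, id_b="I1", hap_b=0, chrom="chr1",
                     start_bp=int(panel.site_bp[0]), end_bp=int(panel.site_bp[49]),
                     start_cM=cm[0], end_cM=cm[49], length_cM=cm[49] - cm[0],
                     start_site=0, end_site=50),
                dict(id_a="I0", hap_a=0, id_b="I1", hap_b=0, chrom="chr1",
                     start_bp=int(panel.site_bp[55]), end_bp=int(panel.site_bp[104]),
                     start_cM=cm[55], end_cM=cm[104], length_cM=cm[104] - cm[55],
                     start_site=55, end_site=105),
            ],
            columns=ibd.SEGMENT_COLUMNS,
        )
        return panel, seg

    @pytest.mark.parametrize(
        "gap_cm,n_disc,should_merge",
        [(0.5, 1, True), (0.7, 0, False), (0.5, 2, False)],
        ids=["short-gap-one-discordant", "gap-too-wide", "too-many-discordant"],
    )
    def test_boundary_cases(self, gap_cm, n_disc, should_merge):
        panel, seg = self._panel_with_gap(gap_cm, n_disc)
        merged = ibd.merge_ibd(seg, panel)
        if should_merge:
            assert len(merged) == 1
            assert merged.iloc[0].start_site == seg.iloc[0].start_site
            assert merged.iloc[0].end_site == seg.iloc[1].end_site
        else:
            assert len(merged) == 2

    def test_detector_plus_merge_rejoins_split_run(self):
        # a single isolated discordant site splits exact detection in two;
        # the merge rule (gap < 0.6 cM, <= 1 discordant) rejoins them
        panel, _ = self._panel_with_gap(0.2, 1)
        det = ibd.detect_ibd(panel, min_cM=0.5)
        det = det[(det.hap_a == 0) & (det.hap_b == 0)].reset_index(drop=True)
        assert len(det) == 2
        merged = ibd.merge_ibd(det, panel)
        assert len(merged) == 1

    def test_recall_improves_under_genotype_error(self):
        improved = 0
        for seed in (1, 2):
            cfg = simdata.SimConfig(
                n_subpops=1, size_per_generation=300, n_generations=30,
                chromosomes=((100.0, 3000, 100_000_000),),
                genotype_error_rate=0.002, sample_size=80, seed=seed,
            )
            sim = simdata.simulate(cfg)
            truth = sim.truth_ibd(min_cM=1.0)
            truth = truth[truth.id_a != truth.id_b]
            det = ibd.detect_ibd(sim.panel, min_cM=1.0)
            merged = ibd.merge_ibd(det, sim.panel)
            _, r_off = ibd.segment_overlap_stats(det, truth, 2.0, 4.0)
            _, r_on = ibd.segment_overlap_stats(merged, truth, 2.0, 4.0)
            improved += int(r_on > r_off)
        assert improved == 2


class TestSharingSummary:
    def _segments(self, rows):
        out = []
        for id_a, id_b, length in rows:
            out.append(
                dict(id_a=id_a, hap_a=0, id_b=id_b, hap_b=0, chrom="chr1",
                     start_bp=1, end_bp=2, start_cM=0.0, end_cM=length,
                     length_cM=length, start_site=0, end_site=1)
            )
        return pd.DataFrame(out, columns=ibd.SEGMENT_COLUMNS)

    def test_two_member_cluster(self):
        seg = self._segments([("A", "B", 5.0)])
        assign = pd.Series({"A": "c", "B": "c"})
        s = ibd.sharing_summary(seg, assign)
        assert s.loc["A", "mean_total_cM"] == 5.0
        assert s.loc["B", "mean_n_segments"] == 1.0

    def test_hand_accounting_three_members(self):
        seg = self._segments([("A", "B", 5.0), ("A", "C", 3.0), ("A", "C", 2.0)])
        assign = pd.Series({"A": "c", "B": "c", "C": "c"})
        s = ibd.sharing_summary(seg, assign)
        assert s.loc["A", "mean_total_cM"] == pytest.approx(5.0)
        assert s.loc["A", "mean_n_segments"] == pytest.approx(1.5)
        assert s.loc["B", "mean_total_cM"] == pytest.approx(2.5)
        assert s.loc["B", "mean_n_segments"] == pytest.approx(0.5)
        assert s.loc["C", "mean_total_cM"] == pytest.approx(2.5)
        assert s.loc["C", "mean_n_segments"] == pytest.approx(1.0)

    def test_no_sharing_gives_zero_means(self):
        assign = pd.Series({"A": "c", "B": "c", "C": "c"})
        s = ibd.sharing_summary(self._segments([]), assign)
        assert (s["mean_total_cM"] == 0).all()

    def test_singleton_cluster_flagged_missing(self):
        assign = pd.Series({"A": "c", "B": "c", "C": "solo"})
        s = ibd.sharing_summary(self._segments([("A", "B", 4.0)]), assign)
        assert np.isnan(s.loc["C", "mean_total_cM"])


class TestRankTest:
    def test_exact_enumeration_example(self):
        u, p = ibd.rank_test([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)

    def test_identical_groups_give_central_u(self):
        u, _ = ibd.rank_test([1.5, 2.5, 3.5, 9.0], [1.5, 2.5, 3.5, 9.0])
        assert u == pytest.approx(8.0)  # m*n/2

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ibd.rank_test([], [1.0])

    def test_power_under_shift_alternative(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(100):
            a = rng.normal(1.0, 1.0, 50)
            b = rng.normal(0.0, 1.0, 50)
            _, p = ibd.rank_test(a, b)
            hits += int(p < 0.05)
        assert hits >= 90
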