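import numpy as np
import pandas as pd
import pytest

from felpop import (
    PopulationPanel,
    annotate_events,
    di_track,
    genome_fst,
    unique_events,
    weir_cockerham_fst,
    window_scan,
    z_track,
)
from felpop.selection_scan import (
    FstTrack,
    read_bed_intervals,
    subpop_specific_events,
    weir_cockerham_theta,
)
from conftest import build_gm


def oracle_theta(genosA, genosB):
    """Scalar transcription of the 1984 two-population variance components,
    written independently of the vectorised implementation.  Genotypes are
    lists of alt-allele dosages (no missing)."""
    pops = [genosA, genosB]
    r = 2
    n = [len(g) for g in pops]
    p = [sum(g) / (2 * len(g)) for g in pops]
    h = [sum(1 for x in g if x == 1) / len(g) for g in pops]
    nbar = sum(n) / r
    nc = (r * nbar - sum(ni**2 for ni in n) / (r * nbar)) / (r - 1)
    pbar = sum(ni * pi for ni, pi in zip(n, p)) / (r * nbar)
    s2 = sum(ni * (pi - pbar) ** 2 for ni, pi in zip(n, p)) / ((r - 1) * nbar)
    hbar = sum(ni * hi for ni, hi in zip(n, h)) / (r * nbar)
    a = (nbar / nc) * (
        s2 - (1 / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4)
    )
    b = (nbar / (nbar - 1)) * (
        pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
    )
    c = hbar / 2
    return a / (a + b + c)


class TestWeirCockerham:
    def test_fixed_difference_theta_one(self):
        callsA = np.zeros((10, 1), dtype=np.int8)
        callsB = np.full((10, 1), 2, dtype=np.int8)
        assert weir_cockerham_theta(callsA, callsB)[0] == pytest.approx(1.0)

    def test_identical_multisets_nonpositive(self):
        calls = np.array([[0], [1], [1], [2], [0], [1]], dtype=np.int8)
        theta = weir_cockerham_theta(calls, calls.copy())[0]
        assert theta <= 0.0 + 1e-12

    def test_hand_built_case_matches_oracle(self):
        # nA=10: 2 het, 1 hom-alt; nB=10: 6 het, 3 hom-alt
        genosA = [1, 1, 2] + [0] * 7
        genosB = [1] * 6 + [2] * 3 + [0]
        got = weir_cockerham_theta(
            np.array([genosA], dtype=np.int8).T, np.array([genosB], dtype=np.int8).T
        )[0]
        assert got == pytest.approx(oracle_theta(genosA, genosB), abs=1e-12)

    def test_random_cases_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            nA, nB = rng.integers(2, 30, size=2)
            genosA = list(rng.integers(0, 3, size=nA))
            genosB = list(rng.integers(0, 3, size=nB))
            exp = oracle_theta(genosA, genosB)
            got = weir_cockerham_theta(
                np.array([genosA], dtype=np.int8).T,
                np.array([genosB], dtype=np.int8).T,
            )[0]
            if np.isnan(exp) or not np.isfinite(exp):
                assert np.isnan(got) or not np.isfinite(got)
            else:
                assert got == pytest.approx(exp, abs=1e-12)

    def test_symmetry_and_allele_relabelling(self, two_pop_gm):
        gm, panel = two_pop_gm
        t_ab = weir_cockerham_fst(gm, panel, "A", "B")
        t_ba = weir_cockerham_fst(gm, panel, "B", "A")
        np.testing.assert_allclose(t_ab.values, t_ba.values, equal_nan=True)
        flipped = gm.copy()
        mask = flipped.calls != -1
        flipped.calls[mask] = 2 - flipped.calls[mask]
        t_flip = weir_cockerham_fst(flipped, panel, "A", "B")
        np.testing.assert_allclose(t_ab.values, t_flip.values, equal_nan=True)

    def test_small_population_rejected(self, two_pop_gm):
        gm, panel = two_pop_gm
        lonely = PopulationPanel({**panel.population, "s7": "C"})
        with pytest.raises(ValueError):
            weir_cockerham_fst(gm, lonely, "A", "C")

    def test_genome_mean_monotone_in_fst(self):
        from felpop import PopulationSpec, SimConfig, simulate_balding_nichols

        means = []
        for f in (0.01, 0.05, 0.2):
            vals = []
            for seed in range(10):
                cfg = SimConfig(
                    seed=300 + seed, chrom_lengths_bp={"1": 20_000_000},
                    snp_density_per_kb=0.1,
                    populations=[PopulationSpec("A", 30, fst=f),
                                 PopulationSpec("B", 30, fst=f)],
                )
                gm, panel, _ = simulate_balding_nichols(cfg)
                vals.append(genome_fst(gm, panel, "A", "B"))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestDiTrack:
    def _toy_tracks(self):
        tables = [
            [0.10, 0.20, 0.50, 0.05, 0.15],
            [0.30, 0.10, 0.60, 0.20, 0.30],
            [0.00, 0.05, 0.40, 0.10, 0.05],
        ]
        tracks = []
        for k, vals in enumerate(tables):
            v = np.array(vals)
            tracks.append(FstTrack(("focal", f"p{k}"), v,
                                   float(v.mean()), float(v.std(ddof=1))))
        return tables, tracks

    def test_toy_table_matches_spreadsheet_sum(self):
        tables, tracks = self._toy_tracks()
        di = di_track(tracks, "focal")
        for j in range(5):
            expected = sum(
                (t[j] - np.mean(t)) / np.std(t, ddof=1) for t in tables
            )
            assert di.values[j] == pytest.approx(expected)

    def test_snp_at_track_means_is_zero(self):
        tracks = [
            FstTrack(("focal", "x"), np.array([0.2, 0.1, 0.3]), 0.2, 0.1),
            FstTrack(("focal", "y"), np.array([0.5, 0.2, 0.8]), 0.5, 0.3),
        ]
        di = di_track(tracks, "focal")
        assert di.values[0] == pytest.approx(0.0)

    def test_location_invariance(self):
        tables, tracks = self._toy_tracks()
        di1 = di_track(tracks, "focal").values
        shifted = FstTrack(
            tracks[0].pop_pair, tracks[0].values + 0.07,
            tracks[0].mean + 0.07, tracks[0].sd,
        )
        di2 = di_track([shifted] + tracks[1:], "focal").values
        np.testing.assert_allclose(di1, di2)

    def test_missing_snp_excluded(self):
        tracks = [
            FstTrack(("f", "x"), np.array([0.2, np.nan, 0.3]), 0.25, 0.05),
            FstTrack(("f", "y"), np.array([0.5, 0.2, 0.8]), 0.5, 0.3),
        ]
        di = di_track(tracks, "f")
        assert np.isnan(di.values[1]) and di.n_excluded == 1

    def test_degenerate_track_rejected(self):
        tracks = [
            FstTrack(("f", "x"), np.array([0.2, 0.2]), 0.2, 0.0),
            FstTrack(("f", "y"), np.array([0.5, 0.2]), 0.35, 0.2),
        ]
        with pytest.raises(ValueError, match="degenerate"):
            di_track(tracks, "f")


def _di_for_windows(n_windows, snps_per_window=5, hot=None):
    """A DiTrack + matrix whose window means are 0 except ``hot`` windows."""
    n = n_windows * snps_per_window
    pos = []
    for w in range(n_windows):
        pos += [w * 1_000_000 + 1000 * (i + 1) for i in range(snps_per_window)]
    gm = build_gm(np.zeros((2, n), dtype=np.int8), pos=pos)
    rng = np.random.default_rng(0)
    values = rng.normal(0, 0.01, size=n)
    for h in hot or []:
        values[h * snps_per_window : (h + 1) * snps_per_window] += 5.0
    from felpop.selection_scan import DiTrack

    return DiTrack("f", [("f", "x"), ("f", "y")], values, 0), gm


class TestWindowScan:
    def test_top_window_flagged_at_99th(self):
        di, gm = _di_for_windows(100, hot=[7])
        windows = window_scan(di, gm)
        assert windows["outlier"].sum() == 1
        assert windows.loc[windows["outlier"], "window"].iat[0] == 7

    def test_window_with_three_snps_discarded(self):
        di, gm = _di_for_windows(10, snps_per_window=5)
        # knock SNPs out of window 3 by un-scoring them
        di.values[15:17] = np.nan
        windows = window_scan(di, gm, min_snps=4)
        assert 3 not in set(windows["window"])

    def test_null_fraction_about_one_percent(self):
        di, gm = _di_for_windows(200)
        windows = window_scan(di, gm, pct=99.0)
        frac = windows["outlier"].mean()
        assert 0.005 <= frac <= 0.02  # 2/200 at most with ties

    def test_too_few_windows_error(self):
        di, gm = _di_for_windows(1)
        with pytest.raises(ValueError):
            window_scan(di, gm)


class TestUniqueEvents:
    def _windows(self, outlier_map, n_windows=6):
        rows = []
        for w in range(n_windows):
            rows.append({"chrom": "1", "window": w,
                         "start_bp": w * 1_000_000 + 1,
                         "end_bp": (w + 1) * 1_000_000,
                         "n_snps": 5, "mean_di": 0.0,
                         "outlier": w in outlier_map})
        return pd.DataFrame(rows)

    def _gm(self, n_windows=6):
        pos = [w * 1_000_000 + 500_000 for w in range(n_windows)]
        return build_gm(np.zeros((2, n_windows), dtype=np.int8), pos=pos)

    def test_rule_satisfaction(self):
        wbc = {
            "in1": self._windows({2}), "in2": self._windows({2}),
            "out1": self._windows(set()),
        }
        events = unique_events(wbc, ["in1", "in2"], ["out1"], self._gm())
        assert len(events) == 1 and events[0].windows == [("1", 2)]

    def test_out_set_vetoes(self):
        wbc = {
            "in1": self._windows({2}), "in2": self._windows({2}),
            "out1": self._windows({2}),
        }
        assert unique_events(wbc, ["in1", "in2"], ["out1"], self._gm()) == []

    def test_adjacent_windows_merge(self):
        wbc = {"in1": self._windows({2, 3}), "in2": self._windows({2, 3})}
        events = unique_events(wbc, ["in1", "in2"], [], self._gm())
        assert len(events) == 1
        assert events[0].windows == [("1", 2), ("1", 3)]
        # region snaps to first/last SNP inside the merged windows
        assert events[0].start_bp == 2_500_000 and events[0].end_bp == 3_500_000

    def test_monotone_in_required_out(self):
        wbc = {
            "in1": self._windows({1, 4}),
            "out1": self._windows({4}),
            "out2": self._windows({1}),
        }
        e0 = unique_events(wbc, ["in1"], [], self._gm())
        e1 = unique_events(wbc, ["in1"], ["out1"], self._gm())
        e2 = unique_events(wbc, ["in1"], ["out1", "out2"], self._gm())
        assert len(e0) >= len(e1) >= len(e2)

    def test_missing_comparison_error(self):
        with pytest.raises(KeyError):
            unique_events({"in1": self._windows(set())}, ["in1"], ["ghost"],
                          self._gm())


class TestSubpopScan:
    def _dataset(self, fixed_sub=None):
        from felpop import PopulationSpec, SimConfig, simulate_balding_nichols
        from felpop import plant_sweep

        cfg = SimConfig(
            seed=77, chrom_lengths_bp={"1": 30_000_000, "2": 30_000_000},
            snp_density_per_kb=0.1,
            populations=[PopulationSpec(
                "P", 40, fst=0.02,
                subpop_sizes={"w": 10, "x": 10, "y": 10, "z": 10},
            )],
        )
        gm, panel, truth = simulate_balding_nichols(cfg)
        if fixed_sub:
            rows = [gm.sample_index(s) for s in panel.samples_in_subpop(fixed_sub)]
            cols = np.flatnonzero(
                (gm.variants["chrom"] == "1").to_numpy()
                & (gm.variants["pos"].to_numpy() <= 1_000_000)
            )
            gm.calls[np.ix_(rows, cols)] = 2  # near-fixed block in one subpop
        return gm, panel

    def test_fixed_window_reported_for_focal_only(self):
        gm, panel = self._dataset(fixed_sub="x")
        hits = {}
        for sub in ("w", "x", "y", "z"):
            events = subpop_specific_events(gm, panel, "P", sub)
            hits[sub] = any(
                ev.chrom == "1" and ev.start_bp <= 1_000_000 for ev in events
            )
        assert hits["x"]

    def test_too_few_subpops(self, two_pop_gm):
        gm, panel = two_pop_gm
        with pytest.raises(ValueError):
            subpop_specific_events(gm, panel, "A", "nope")


class TestAnnotate:
    def _events(self):
        from felpop.selection_scan import SelectiveEvent

        return [SelectiveEvent("focal-unique", "e1", "1", 1_000, 2_000, [("1", 0)])]

    def test_gene_inside_listed(self):
        genes = pd.DataFrame([{"chrom": "1", "start_bp": 1_200, "end_bp": 1_300,
                               "name": "GENE1"}])
        events = annotate_events(self._events(), genes)
        assert events[0].genes == ["GENE1"]

    def test_abutting_gene_not_listed(self):
        genes = pd.DataFrame([{"chrom": "1", "start_bp": 2_001, "end_bp": 2_100,
                               "name": "GENE2"}])
        events = annotate_events(self._events(), genes)
        assert events[0].genes == []

    def test_random_intervals_match_brute_force(self):
        from felpop.selection_scan import SelectiveEvent

        rng = np.random.default_rng(4)
        genes = pd.DataFrame([
            {"chrom": str(rng.integers(1, 3)),
             "start_bp": (s := int(rng.integers(1, 10_000))),
             "end_bp": s + int(rng.integers(1, 500)),
             "name": f"g{i}"}
            for i in range(100)
        ])
        events = []
        for i in range(30):
            s = int(rng.integers(1, 10_000))
            events.append(SelectiveEvent("focal-unique", f"e{i}",
                                         str(rng.integers(1, 3)),
                                         s, s + int(rng.integers(1, 800)), []))
        annotate_events(events, genes)
        for ev in events:
            expected = sorted(
                g["name"] for _, g in genes.iterrows()
                if g["chrom"] == ev.chrom
                and g["start_bp"] <= ev.end_bp and ev.start_bp <= g["end_bp"]
            )
            assert ev.genes == expected

    def test_bed_round_coordinates(self, tmp_path):
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t999\t2000\tGENEX\n")
        df = read_bed_intervals(bed)
        assert df.iloc[0]["start_bp"] == 1_000 and df.iloc[0]["end_bp"] == 2_000

    def test_consensus_overlap_recorded(self):
        from felpop.roh import ConsensusROH

        regions = [ConsensusROH("1", 1_500, 1_800, 0.10, 0.2, 3, "P")]
        events = annotate_events(self._events(), None, regions)
        assert events[0].consensus_overlaps == [(0.10, "1", 1_500, 1_800)]
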