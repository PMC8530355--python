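"""Map cleaning, interpolation, window construction and quintile correlations."""

import numpy as np
import pandas as pd
import pytest

from admixscan import (
    AncestryMatrix,
    DataValidationError,
    GeneticMap,
    IntervalSet,
    build_windows,
    clean_map,
    quintile_correlation,
    uniform_map,
)


def marker_df(chrom, bp, cm, **extra):
    df = pd.DataFrame({"chrom": chrom, "pos_bp": bp, "pos_cM": cm})
    for k, v in extra.items():
        df[k] = v
    return df


class TestCleanMap:
    def test_minimal_removal_drops_order_breaking_marker(self):
        raw = marker_df("chr1", [100, 200, 300, 400, 500], [0.0, 1.0, 3.0, 2.0, 4.0])
        gmap = clean_map(raw, {"chr1": 1000})
        assert list(gmap.markers["pos_cM"]) == [0.0, 1.0, 3.0, 4.0]
        assert gmap.report["out_of_order"] == 1

    def test_wrong_chromosome_marker_dropped_and_counted(self):
        raw = marker_df("chr1", [100, 200, 300], [0.0, 1.0, 2.0],
                        map_chrom=["chr1", "chr2", "chr1"])
        gmap = clean_map(raw, {"chr1": 1000})
        assert len(gmap.markers) == 2
        assert gmap.report["wrong_chromosome"] == 1

    def test_terminal_rate_extended_to_chromosome_end(self):
        # last interval: 1 cM per 1 Mbp; 2 Mb remain -> +2 cM extrapolated
        raw = marker_df("chr1", [1_000_000, 2_000_000], [0.0, 1.0])
        gmap = clean_map(raw, {"chr1": 4_000_000})
        assert gmap.interpolate_cM("chr1", 4_000_000) == pytest.approx(3.0, abs=1e-9)

    def test_chromosome_with_too_few_markers_excluded(self):
        raw = pd.concat([
            marker_df("chr1", [100, 200], [0.0, 1.0]),
            marker_df("chr2", [100], [0.0]),
        ])
        with pytest.warns(UserWarning, match="chr2"):
            gmap = clean_map(raw, {"chr1": 1000, "chr2": 1000})
        assert gmap.chromosomes == ["chr1"]


class TestInterpolation:
    def simple_map(self):
        return GeneticMap(
            markers=marker_df("chr1", [100, 200], [0.0, 1.0]),
            chrom_lengths={"chr1": 300},
        )

    def test_midpoint_interpolates_halfway(self):
        assert self.simple_map().interpolate_cM("chr1", 150) == pytest.approx(0.5)

    def test_exact_at_markers(self):
        gmap = self.simple_map()
        assert gmap.interpolate_cM("chr1", 100) == pytest.approx(0.0, abs=1e-12)
        assert gmap.interpolate_cM("chr1", 200) == pytest.approx(1.0, abs=1e-12)

    def test_terminal_extrapolation_uses_last_interval_rate(self):
        assert self.simple_map().interpolate_cM("chr1", 250) == pytest.approx(1.5)

    def test_monotone_and_invertible(self):
        gmap = self.simple_map()
        bp = np.linspace(0, 300, 61)
        cm = gmap.interpolate_cM("chr1", bp)
        assert np.all(np.diff(cm) > 0)
        np.testing.assert_allclose(gmap.interpolate_bp("chr1", cm), bp, atol=1e-6)

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(DataValidationError):
            self.simple_map().interpolate_cM("chr9", 100)


def matrix_on(chrom_values: dict, loci_per_chrom=20, length=10_000_000):
    """Ancestry matrix with constant per-chromosome frequency."""
    frames, vals = [], []
    for chrom, v in chrom_values.items():
        pos = np.linspace(1, length - 1, loci_per_chrom).astype(np.int64)
        frames.append(pd.DataFrame({"chrom": chrom, "pos_bp": pos, "pos_cM": pos / 1e6}))
        vals.append(np.full((loci_per_chrom, 2), v))
    loci = pd.concat(frames, ignore_index=True)
    freqs = pd.DataFrame(np.vstack(vals), columns=["popA", "popB"])
    return AncestryMatrix(loci=loci, freqs=freqs).validate()


def rate_map(rates: dict, length=10_000_000):
    """Per-chromosome constant-rate map (rates in cM/Mbp)."""
    rows = []
    for chrom, r in rates.items():
        rows.append((chrom, 1, r / 1e6))
        rows.append((chrom, length, r * length / 1e6))
    return GeneticMap(
        markers=pd.DataFrame(rows, columns=["chrom", "pos_bp", "pos_cM"]),
        chrom_lengths={c: length for c in rates},
    )


class TestBuildWindows:
    def test_uniform_map_gives_equal_quintiles(self):
        gmap = uniform_map({"chr1": 10_000_000}, 1.0)  # 10 windows of 1 cM
        win = build_windows(gmap, None, None)
        full = win[~win["partial"]]
        assert len(full) >= 9
        counts = win.groupby("quintile_rec").size()
        assert counts.max() - counts.min() <= 1

    def test_rec_rate_is_cm_per_mbp(self):
        gmap = rate_map({"chr1": 2.0})  # 1 cM spans 0.5 Mbp
        win = build_windows(gmap, None, None)
        np.testing.assert_allclose(win["rec_rate"], 2.0, atol=1e-6)
        np.testing.assert_allclose(
            win[~win["partial"]]["end_bp"] - win[~win["partial"]]["start_bp"], 500_000, atol=2
        )

    def test_gene_fully_inside_window_counts_its_length(self):
        gmap = uniform_map({"chr1": 1_000_000}, 1.0)
        genes = IntervalSet.from_records([("chr1", 100, 200, "g")])
        win = build_windows(gmap, genes, None)
        assert win["coding_bp"].sum() == 100

    def test_coding_bp_matches_per_bp_membership_count(self):
        rng = np.random.default_rng(7)
        gmap = uniform_map({"chr1": 10_000}, 100.0)
        ivs = []
        for i in range(12):
            s = int(rng.integers(0, 9_900))
            ivs.append(("chr1", s, s + int(rng.integers(1, 100)), f"g{i}"))
        genes = IntervalSet.from_records(ivs)
        win = build_windows(gmap, genes, None)
        covered = np.zeros(10_000, dtype=bool)
        for _, s, e, _ in ivs:
            covered[s:e] = True
        for _, row in win.iterrows():
            expect = int(covered[row["start_bp"]:row["end_bp"]].sum())
            assert row["coding_bp"] == expect

    def test_window_cm_spans_sum_to_map_length(self):
        gmap = uniform_map({"chr1": 7_777_777}, 1.3)
        win = build_windows(gmap, None, None)
        total = gmap.total_cM("chr1")
        assert win["cM_span"].sum() == pytest.approx(total, abs=1e-9)

    def test_quintile_cut_respects_cumulative_bp_rule(self):
        rates = {f"chr{i}": r for i, r in enumerate([0.5, 1.0, 1.5, 2.0, 3.0])}
        gmap = rate_map(rates)
        win = build_windows(gmap, None, None)
        span = win["end_bp"] - win["start_bp"]
        total = span.sum()
        for q in range(5):
            bp = span[win["quintile_rec"] == q].sum()
            assert abs(bp - total / 5) <= span.max()


class TestQuintileCorrelation:
    def monotone_windows(self, sign=+1):
        # 10 chromosomes with increasing rec rate; ancestry increases with it
        rates = {f"chr{i}": 0.5 + 0.3 * i for i in range(10)}
        anc_vals = {c: 0.5 + sign * 0.02 * i for i, c in enumerate(rates)}
        gmap = rate_map(rates, length=4_000_000)
        mat = matrix_on(anc_vals, loci_per_chrom=10, length=4_000_000)
        return build_windows(gmap, None, mat)

    def test_monotone_construction_gives_rho_one(self):
        win = self.monotone_windows(+1)
        res = quintile_correlation(win, metric="rec_rate", level="quintile",
                                   n_boot=200, seed=0)
        assert res.rho == pytest.approx(1.0)
        assert res.ci_low > 0

    def test_antitone_construction_gives_rho_minus_one(self):
        win = self.monotone_windows(-1)
        res = quintile_correlation(win, metric="rec_rate", level="quintile",
                                   n_boot=200, seed=1)
        assert res.rho == pytest.approx(-1.0)
        assert res.ci_high < 0

    def test_independent_ancestry_ci_covers_zero(self):
        # ancestry iid per locus, so window means are exchangeable across
        # quintiles and the bootstrap CI should cover rho = 0 at ~95%
        covered = 0
        reps = 50
        rates = {f"chr{i}": 0.5 + 0.3 * i for i in range(10)}
        gmap = rate_map(rates, length=4_000_000)
        for rep in range(reps):
            rng = np.random.default_rng(rep)
            frames, vals = [], []
            for chrom in rates:
                pos = np.linspace(1, 4_000_000 - 1, 40).astype(np.int64)
                frames.append(
                    pd.DataFrame({"chrom": chrom, "pos_bp": pos, "pos_cM": pos / 1e6})
                )
                vals.append(rng.uniform(0.1, 0.5, (40, 2)))
            mat = AncestryMatrix(
                loci=pd.concat(frames, ignore_index=True),
                freqs=pd.DataFrame(np.vstack(vals), columns=["popA", "popB"]),
            ).validate()
            win = build_windows(gmap, None, mat)
            res = quintile_correlation(win, metric="rec_rate", level="quintile",
                                       n_boot=200, seed=1000 + rep)
            if res.ci_low <= 0 <= res.ci_high:
                covered += 1
        assert covered >= 0.9 * reps

    def test_tied_metric_rejected(self):
        gmap = rate_map({"chr1": 1.0, "chr2": 1.0})
        mat = matrix_on({"chr1": 0.2, "chr2": 0.3})
        win = build_windows(gmap, None, mat)
        with pytest.raises(DataValidationError, match="no variation"):
            quintile_correlation(win, metric="rec_rate", level="quintile", n_boot=10)
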