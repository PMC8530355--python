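"""Estimator hand values, brute-force equivalence, and symmetry properties."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixscan import (
    AlleleFreqPanel,
    UndefinedStatistic,
    ascertain_aims,
    f4,
    f4_ratio_alpha,
    filter_sites,
    hudson_fst,
    pbs,
    pi_within,
    simulate_reference_panels,
    SimConfig,
)


def make_panel(freqs: dict, sizes: dict, pos_cM=None):
    n = len(next(iter(freqs.values())))
    sites = pd.DataFrame({
        "chrom": "chr1",
        "pos_bp": 100 * (1 + np.arange(n)),
        "pos_cM": pos_cM if pos_cM is not None else 0.001 * np.arange(n),
    })
    return AlleleFreqPanel(
        sites=sites,
        freqs=pd.DataFrame({k: np.asarray(v, float) for k, v in freqs.items()}),
        sizes={k: np.full(n, v) for k, v in sizes.items()},
    ).validate()


class TestHudsonFst:
    def test_fixed_difference_is_one(self):
        assert hudson_fst([1.0], [10], [0.0], [10]) == pytest.approx(1.0, abs=1e-15)

    def test_bhatia_correction_hand_value(self):
        # (0 - 0.25/9 - 0.25/9) / 0.5 = -1/9
        assert hudson_fst([0.5], [10], [0.5], [10]) == pytest.approx(-1 / 9, abs=1e-15)

    def test_shared_monomorphic_sites_undefined(self):
        with pytest.raises(UndefinedStatistic):
            hudson_fst([0.0, 0.0], [10, 10], [0.0, 0.0], [10, 10])

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(1)
        p1, p2 = rng.uniform(0, 1, 100), rng.uniform(0, 1, 100)
        n1, n2 = rng.integers(4, 50, 100), rng.integers(4, 50, 100)
        num = den = 0.0
        for a, b, x, y in zip(p1, p2, n1, n2):
            d = a * (1 - b) + b * (1 - a)
            if d > 0:
                num += (a - b) ** 2 - a * (1 - a) / (x - 1) - b * (1 - b) / (y - 1)
                den += d
        assert hudson_fst(p1, n1, p2, n2) == pytest.approx(num / den, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_symmetric_and_label_flip_invariant(self, seed):
        rng = np.random.default_rng(seed)
        p1, p2 = rng.uniform(0, 1, 20), rng.uniform(0, 1, 20)
        n1, n2 = 10, 20
        f = hudson_fst(p1, n1, p2, n2)
        assert hudson_fst(p2, n2, p1, n1) == pytest.approx(f, abs=1e-12)
        assert hudson_fst(1 - p1, n1, 1 - p2, n2) == pytest.approx(f, abs=1e-12)


class TestPBS:
    def test_zero_differentiation_gives_zero(self):
        assert pbs(0.0, 0.0, 0.0) == 0.0

    def test_hand_values(self):
        assert pbs(0.1, 0.1, 0.1) == pytest.approx(-math.log(0.9) / 2, abs=1e-12)
        assert pbs(0.2, 0.2, 0.0) == pytest.approx(-math.log(0.8), abs=1e-12)

    def test_complete_fixation_signalled(self):
        with pytest.raises(UndefinedStatistic):
            pbs(1.0, 0.1, 0.1)

    def test_three_focal_branches_sum_to_tree_total(self):
        f12, f13, f23 = 0.12, 0.05, 0.31
        total = sum(-math.log1p(-f) for f in (f12, f13, f23)) / 2
        s = pbs(f12, f13, f23) + pbs(f12, f23, f13) + pbs(f13, f23, f12)
        assert s == pytest.approx(total, abs=1e-12)


class TestF4:
    def test_equal_sister_pair_gives_zero(self):
        panel = make_panel(
            {"A": [0.3, 0.7], "B": [0.3, 0.7], "C": [0.1, 0.9], "D": [0.5, 0.2]},
            {"A": 10, "B": 10, "C": 10, "D": 10},
        )
        assert f4(panel, ("A", "B", "C", "D")).f4_value == 0.0

    def test_single_site_hand_value(self):
        panel = make_panel(
            {"A": [0.0], "B": [1.0], "C": [0.7], "D": [1.0]},
            {"A": 10, "B": 10, "C": 10, "D": 10},
        )
        assert f4(panel, ("A", "B", "C", "D")).f4_value == pytest.approx(0.3, abs=1e-15)

    def test_invariant_to_site_duplication(self):
        rng = np.random.default_rng(2)
        base = {k: rng.uniform(0, 1, 50) for k in "ABCD"}
        doubled = {k: np.concatenate([v, v]) for k, v in base.items()}
        f_a = f4(make_panel(base, dict.fromkeys("ABCD", 10)), tuple("ABCD")).f4_value
        f_b = f4(make_panel(doubled, dict.fromkeys("ABCD", 10)), tuple("ABCD")).f4_value
        assert f_b == pytest.approx(f_a, abs=1e-12)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(3)
        freqs = {k: rng.uniform(0, 1, 100) for k in "ABCD"}
        panel = make_panel(freqs, dict.fromkeys("ABCD", 10))
        expected = np.mean(
            [(a - b) * (c - d) for a, b, c, d in
             zip(freqs["A"], freqs["B"], freqs["C"], freqs["D"])]
        )
        assert f4(panel, tuple("ABCD")).f4_value == pytest.approx(expected, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_antisymmetry_within_pairs(self, seed):
        rng = np.random.default_rng(seed)
        freqs = {k: rng.uniform(0, 1, 30) for k in "ABCD"}
        panel = make_panel(freqs, dict.fromkeys("ABCD", 10))
        f_abcd = f4(panel, tuple("ABCD")).f4_value
        assert f4(panel, ("B", "A", "C", "D")).f4_value == pytest.approx(-f_abcd, abs=1e-12)
        assert f4(panel, ("A", "B", "D", "C")).f4_value == pytest.approx(-f_abcd, abs=1e-12)


class TestF4RatioAlpha:
    def make_ref_panel(self, alpha, seed=0, n_sites=30_000):
        cfg = SimConfig(seed=seed)
        return simulate_reference_panels(cfg, n_sites, alpha_focal=alpha, seed=seed)

    def test_mexicana_panel_itself_gives_alpha_one(self):
        panel = self.make_ref_panel(0.3, seed=4)
        panel.freqs["focal"] = panel.freqs["mexicana"]
        est = f4_ratio_alpha(panel, seed=4, n_boot=50)
        assert est.alpha == pytest.approx(1.0, abs=1e-12)

    def test_maize_panel_gives_alpha_zero(self):
        panel = self.make_ref_panel(0.3, seed=5)
        panel.freqs["focal"] = panel.freqs["maize"]
        est = f4_ratio_alpha(panel, seed=5, n_boot=50)
        assert est.alpha == pytest.approx(0.0, abs=1e-12)

    def test_recovers_planted_mixture(self):
        panel = self.make_ref_panel(0.3, seed=6, n_sites=100_000)
        est = f4_ratio_alpha(panel, seed=6, n_boot=200)
        assert est.alpha == pytest.approx(0.30, abs=0.02)
        assert est.ci_low <= 0.30 <= est.ci_high

    def test_near_zero_denominator_signalled(self):
        panel = make_panel(
            {"outgroup": [0.5], "parviglumis": [0.5], "mexicana": [0.2],
             "maize": [0.8], "focal": [0.4]},
            dict.fromkeys(["outgroup", "parviglumis", "mexicana", "maize", "focal"], 10),
        )
        with pytest.raises(UndefinedStatistic, match="denominator"):
            f4_ratio_alpha(panel)


class TestPi:
    def test_monomorphic_site_contributes_zero(self):
        per_site, mean = pi_within([0.0], [10])
        assert mean == 0.0

    def test_unbiased_correction_hand_value(self):
        per_site, _ = pi_within([0.5], [4])
        assert per_site[0] == pytest.approx(2 / 3, abs=1e-15)

    def test_large_sample_asymptote(self):
        _, mean = pi_within([0.5], [10**9])
        assert mean == pytest.approx(0.5, abs=1e-6)

    def test_matches_bruteforce_loops(self):
        rng = np.random.default_rng(4)
        p = rng.uniform(0, 1, 100)
        n = rng.integers(2, 40, 100)
        expected = [2 * a * (1 - a) * b / (b - 1) for a, b in zip(p, n)]
        per_site, mean = pi_within(p, n)
        np.testing.assert_allclose(per_site, expected, atol=1e-12)
        assert mean == pytest.approx(np.mean(expected), abs=1e-12)


class TestFilterSites:
    def toy_table(self, mafs, n=200, depth=100):
        return pd.DataFrame({
            "maf": mafs,
            "n_with_data": n,
            "total_depth": depth,
        })

    def test_maf_rule_keeps_boundary(self):
        table = self.toy_table([0.01, 0.05, 0.2, 0.5, 0.04])
        kept, report = filter_sites(table, n_min=0)
        assert len(kept) == 3  # 0.05 survives the >= rule
        assert report["maf"] == 2

    def test_depth_exactly_at_cutoff_kept(self):
        table = pd.DataFrame({
            "maf": [0.2, 0.2], "n_with_data": [200, 200], "total_depth": [100, 250],
        })
        kept, _ = filter_sites(table, n_min=0, mean_depth=100.0)
        assert len(kept) == 2  # 250 == 2.5 x 100: strict 'exceeding' removes
        kept2, _ = filter_sites(
            pd.DataFrame({"maf": [0.2], "n_with_data": [200], "total_depth": [251]}),
            n_min=0, mean_depth=100.0,
        )
        assert len(kept2) == 0

    def test_all_failing_n_min_reports_counts(self):
        table = self.toy_table([0.2, 0.3], n=10)
        kept, report = filter_sites(table, n_min=150)
        assert len(kept) == 0
        assert report["n_with_data"] == 2


class TestAscertainAims:
    def base_panel(self, n=20, seed=7):
        rng = np.random.default_rng(seed)
        freqs = {k: rng.uniform(0.3, 0.7, n) for k in ("maize", "mexicana", "parviglumis")}
        return freqs

    def test_extreme_pbs_site_always_retained(self):
        freqs = self.base_panel(20)
        freqs["maize"][7] = 0.99   # strongly differentiated on the maize branch
        freqs["mexicana"][7] = 0.01
        freqs["parviglumis"][7] = 0.01
        panel = make_panel(freqs, dict.fromkeys(freqs, 50))
        kept = ascertain_aims(panel)
        assert panel.sites.loc[7, "pos_bp"] in kept["pos_bp"].to_numpy()

    def test_greedy_spacing_keeps_first_of_close_pair(self):
        freqs = {k: np.full(12, 0.5) for k in ("maize", "mexicana", "parviglumis")}
        for i in (5, 6):
            freqs["maize"][i], freqs["mexicana"][i], freqs["parviglumis"][i] = 0.99, 0.01, 0.01
        pos_cM = np.arange(12) * 0.01
        pos_cM[6] = pos_cM[5] + 0.0005  # closer than the 0.001 cM minimum
        panel = make_panel(freqs, dict.fromkeys(freqs, 50), pos_cM=pos_cM)
        kept = ascertain_aims(panel)
        assert 600 in kept["pos_bp"].to_numpy()      # site 5 (1-based grid of 100)
        assert 700 not in kept["pos_bp"].to_numpy()  # site 6 dropped by spacing

    def test_zero_spacing_is_identity_on_qualifiers(self):
        freqs = self.base_panel(30, seed=8)
        panel = make_panel(freqs, dict.fromkeys(freqs, 50))
        loose = ascertain_aims(panel, min_spacing_cM=0.0)
        spaced = ascertain_aims(panel, min_spacing_cM=0.001)
        assert set(spaced["pos_bp"]) <= set(loose["pos_bp"])

    def test_too_few_sites_refused(self):
        freqs = {k: np.full(5, 0.5) for k in ("maize", "mexicana", "parviglumis")}
        panel = make_panel(freqs, dict.fromkeys(freqs, 50))
        with pytest.raises(Exception, match="10 sites"):
            ascertain_aims(panel)
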