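"""Mg correlation screens: exact permutation oracle, monotone invariance,
null calibration, partial-correlation behavior, and dichotomization."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import mgomics as mg
from mgomics.association import spearman_with_p, protein_adjusted_phospho_screen

from conftest import make_matrix


class TestSpearmanWithP:
    def test_perfect_monotone(self):
        x = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 13.0, 21.0, 34.0, 55.0, 89.0])
        rho, p, n = spearman_with_p(x, x**2)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(0.0, abs=1e-12)
        rho_neg, _, _ = spearman_with_p(x, -x)
        assert rho_neg == pytest.approx(-1.0)

    def test_exact_p_matches_brute_force_720_permutations(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0])
        rho, p, n = spearman_with_p(x, y)
        assert n == 6
        rho_obs = stats.spearmanr(x, y).statistic
        assert rho == pytest.approx(rho_obs)
        count = 0
        for perm in permutations(range(6)):
            if abs(stats.spearmanr(x[list(perm)], y).statistic) >= abs(rho_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / 720)

    def test_t_approximation_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p, _ = spearman_with_p(x, y)
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearmanScreen:
    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(30, 40))
        vals[rng.random((30, 40)) < 0.15] = np.nan
        m = make_matrix(vals, stage="zscore")
        mg_map = {f"s{j}": v for j, v in enumerate(rng.uniform(162, 920, 40))}
        res1 = mg.spearman_screen(m, mg_map)
        res2 = mg.spearman_screen(m, {k: np.exp(v / 200.0) for k, v in mg_map.items()})
        pd.testing.assert_series_equal(res1["rho"], res2["rho"])
        pd.testing.assert_series_equal(res1["p"], res2["p"])

    def test_global_null_calibration(self):
        rng = np.random.default_rng(2)
        n_feat, n = 2000, 100
        m = make_matrix(rng.normal(size=(n_feat, n)), stage="zscore")
        mg_map = {f"s{j}": v for j, v in enumerate(rng.uniform(162, 920, n))}
        res = mg.spearman_screen(m, mg_map)
        rate = res["significant"].mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / n_feat)
        assert 0.05 - half < rate < 0.05 + half

    def test_min_pairs_and_constant_feature_untested(self):
        vals = np.full((2, 12), 3.0)
        vals[1, 4:] = np.nan
        m = make_matrix(vals, stage="zscore")
        mg_map = {f"s{j}": float(j) for j in range(12)}
        res = mg.spearman_screen(m, mg_map, min_pairs=10)
        assert not res["tested"].any()
        assert "constant" in res.loc["f0", "reason"]
        assert "min_pairs" in res.loc["f1", "reason"]

    def test_planted_features_detected(self, protein_matrix, mg_content, small_bundle):
        res = mg.spearman_screen(protein_matrix, mg_content)
        truth = small_bundle.truth
        pos = [f for f in truth["pos_corr_proteins"] if f in res.index]
        neg = [f for f in truth["neg_corr_proteins"] if f in res.index]
        # small fixture (8 features per sign, n = 30): check the planted
        # signal dominates sampling noise rather than per-feature signs
        assert res.loc[pos, "rho"].mean() > 0.25
        assert res.loc[neg, "rho"].mean() < -0.25
        assert (res.loc[pos, "rho"] > 0).mean() >= 0.75
        assert (res.loc[neg, "rho"] < 0).mean() >= 0.75


class TestStratifiedScreen:
    def _matrix_and_mg(self, seed=3, n=48):
        rng = np.random.default_rng(seed)
        mg_vals = rng.uniform(162, 920, n)
        # f0 correlated only in the right stratum
        vals = rng.normal(size=(30, n))
        right = np.arange(n) >= n // 2
        vals[0, right] = stats.rankdata(mg_vals[right]) + rng.normal(0, 1.5, right.sum())
        m = make_matrix(vals, stage="zscore")
        mg_map = {f"s{j}": mg_vals[j] for j in range(n)}
        strata = {f"s{j}": ("right" if right[j] else "left") for j in range(n)}
        return m, mg_map, strata

    def test_identical_strata_full_overlap(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=(20, 24))
        vals = np.concatenate([base, base], axis=1)
        mg_half = rng.uniform(162, 920, 24)
        m = make_matrix(vals, stage="zscore",
                        samples=[f"L{j}" for j in range(24)] + [f"R{j}" for j in range(24)])
        mg_map = {f"L{j}": mg_half[j] for j in range(24)}
        mg_map.update({f"R{j}": mg_half[j] for j in range(24)})
        strata = {s: ("left" if s.startswith("L") else "right") for s in mg_map}
        out = mg.stratified_screen(m, mg_map, strata)
        for direction in ("positive", "negative"):
            counts = out["overlap"][direction]["counts"]
            assert counts["left_only"] == 0
            assert counts["right_only"] == 0

    def test_right_only_feature(self):
        m, mg_map, strata = self._matrix_and_mg()
        out = mg.stratified_screen(m, mg_map, strata)
        assert "f0" in out["overlap"]["positive"]["right_only"]

    def test_overlap_counts_partition_significant_sets(self):
        m, mg_map, strata = self._matrix_and_mg(seed=5)
        out = mg.stratified_screen(m, mg_map, strata)
        left = out["results"]["left"]
        for direction in ("positive", "negative"):
            counts = out["overlap"][direction]["counts"]
            n_left_sig = int(((left["significant"]) & (left["direction"] == direction)).sum())
            assert counts["both"] + counts["left_only"] == n_left_sig


class TestProteinAdjustedScreen:
    def _screen(self, site_latent, prot_latent, mg_vals, seed=0):
        n = len(mg_vals)
        samples = [f"s{j}" for j in range(n)]
        phos = make_matrix(site_latent[None, :], stage="zscore",
                           features=["P1_S10"], samples=samples)
        prot = make_matrix(prot_latent[None, :], stage="zscore",
                           features=["P1"], samples=samples)
        return protein_adjusted_phospho_screen(
            phos, prot, dict(zip(samples, mg_vals)))

    def test_site_equal_to_protein_excluded(self):
        rng = np.random.default_rng(6)
        mg_vals = rng.uniform(0, 1, 60)
        prot = 2 * mg_vals + rng.normal(0, 0.3, 60)
        res = self._screen(prot.copy(), prot, mg_vals)
        assert abs(res["partial_rho"].iloc[0]) < 0.2
        assert not res["protein_independent"].iloc[0]

    def test_independent_site_keeps_marginal_rho(self):
        rng = np.random.default_rng(7)
        mg_vals = rng.uniform(0, 1, 100)
        site = 2 * mg_vals + rng.normal(0, 0.8, 100)
        prot = rng.normal(size=100)
        res = self._screen(site, prot, mg_vals)
        assert res["protein_independent"].iloc[0]
        assert res["partial_rho"].iloc[0] == pytest.approx(
            res["marginal_rho"].iloc[0], abs=0.15)

    def test_unmapped_site_marginal_only(self):
        rng = np.random.default_rng(8)
        samples = [f"s{j}" for j in range(20)]
        phos = make_matrix(rng.normal(size=(1, 20)), stage="zscore",
                           features=["ORPHAN_S5"], samples=samples)
        prot = make_matrix(rng.normal(size=(1, 20)), stage="zscore",
                           features=["OTHER"], samples=samples)
        res = protein_adjusted_phospho_screen(
            phos, prot, {s: float(i) for i, s in enumerate(samples)})
        assert res["marginal_only"].iloc[0]
        assert "not quantified" in res["reason"].iloc[0]

    def test_protein_driven_sites_rarely_pass_partial(self):
        """Calibration: when the parent protein drives the Mg association
        and the site is protein + noise, the partial screen detects at
        most ~10% of sites at alpha = 0.05."""
        rng = np.random.default_rng(9)
        n, n_sites = 100, 200
        mg_vals = rng.uniform(0, 1, n)
        flags = 0
        samples = [f"s{j}" for j in range(n)]
        prot_vals = np.empty((n_sites, n))
        site_vals = np.empty((n_sites, n))
        for i in range(n_sites):
            prot = 2 * mg_vals + rng.normal(0, 0.6, n)
            site_vals[i] = prot + rng.normal(0, 0.6, n)
            prot_vals[i] = prot
        phos = make_matrix(site_vals, stage="zscore",
                           features=[f"P{i}_S1" for i in range(n_sites)], samples=samples)
        prot = make_matrix(prot_vals, stage="zscore",
                           features=[f"P{i}" for i in range(n_sites)], samples=samples)
        res = protein_adjusted_phospho_screen(phos, prot, dict(zip(samples, mg_vals)))
        assert res["protein_independent"].mean() <= 0.10

    def test_planted_independent_sites_detected_with_power(self):
        """Planted protein-independent effects (|rho| ~ 0.5 at n = 100)
        are detected with power > 0.8."""
        rng = np.random.default_rng(10)
        n, n_sites = 100, 150
        mg_vals = rng.uniform(0, 1, n)
        z = stats.rankdata(mg_vals) / n
        samples = [f"s{j}" for j in range(n)]
        # latent Pearson for Spearman 0.5 via the Gaussian copula
        r = 2 * np.sin(np.pi * 0.5 / 6)
        gz = stats.norm.ppf((stats.rankdata(mg_vals) - 0.5) / n)
        site_vals = r * gz[None, :] + np.sqrt(1 - r**2) * rng.standard_normal((n_sites, n))
        prot_vals = rng.standard_normal((n_sites, n))
        phos = make_matrix(site_vals, stage="zscore",
                           features=[f"P{i}_S1" for i in range(n_sites)], samples=samples)
        prot = make_matrix(prot_vals, stage="zscore",
                           features=[f"P{i}" for i in range(n_sites)], samples=samples)
        res = protein_adjusted_phospho_screen(phos, prot, dict(zip(samples, mg_vals)))
        assert res["protein_independent"].mean() > 0.8


class TestDichotomizeMg:
    def _clinical(self, mg_vals, times, events):
        return pd.DataFrame(
            {"mg_content": mg_vals, "os_months": times, "os_event": events},
            index=[f"s{j}" for j in range(len(mg_vals))],
        )

    def test_median_split(self):
        clin = self._clinical([1.0, 2.0, 3.0, 4.0], [10, 20, 30, 40], [1, 1, 1, 1])
        groups = mg.dichotomize_mg(clin, method="median")
        assert groups.threshold == 2.5
        assert len(groups.low) == 2 and len(groups.high) == 2

    def test_max_logrank_finds_gap(self):
        # two Mg clusters with a strong hazard difference, observed over a
        # finite follow-up window so the good-prognosis side is censored
        rng = np.random.default_rng(11)
        n = 60
        mg_vals = np.concatenate([rng.uniform(200, 380, n // 2),
                                  rng.uniform(600, 900, n // 2)])
        rate = np.where(mg_vals < 500, 1 / 5.0, 1 / 200.0)
        times = rng.exponential(1 / rate)
        events = (times < 30.0).astype(int)
        times = np.maximum(np.minimum(times, 30.0), 0.1)
        clin = self._clinical(mg_vals, times, events)
        groups = mg.dichotomize_mg(clin, method="max_logrank", n_perm=0)
        assert 380 < groups.threshold < 600
        sub = {f"s{j}": mg_vals[j] for j in range(5)}
        relabeled = groups.relabel(sub)
        assert set(relabeled.labels) == set(sub)

    def test_no_events_errors(self):
        clin = self._clinical([1.0, 2.0, 3.0, 4.0] * 5, [10] * 20, [0] * 20)
        with pytest.raises(ValueError):
            mg.dichotomize_mg(clin, method="max_logrank", n_perm=0)

    def test_fixed_requires_threshold(self):
        clin = self._clinical([1.0, 2.0], [1, 2], [1, 1])
        with pytest.raises(ValueError):
            mg.dichotomize_mg(clin, method="fixed")
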