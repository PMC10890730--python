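"""Rank weighting, threshold exclusion, GSEA engine, PWF and over-representation."""

from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from darseq import (
    dar_weight_ranks,
    fit_pwf,
    gsea_preranked,
    overrep_test,
    ranking_statistic,
    read_gmt,
    threshold_exclude,
    write_gmt,
)
from darseq.enrichment import PWF, PWF_FLOOR
from darseq.errors import InputError


def de_frame(rows):
    return pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "fdr"])


def gene_dar_frame(pairs):
    return pd.DataFrame(
        [{"gene_id": g, "gene_dar": d} for g, d in pairs]
    )


def literal_es(stats, members, exponent=1.0):
    """Verbatim running-sum enrichment score for one set (plain loop)."""
    hits = [i for i, (g, _) in enumerate(stats) if g in members]
    absw = [abs(s) ** exponent for _, s in stats]
    tot = sum(absw[i] for i in hits)
    n, k = len(stats), len(hits)
    miss = 1.0 / (n - k) if n > k else 0.0
    running, best = 0.0, 0.0
    for i, (g, _) in enumerate(stats):
        if g in members:
            running += (absw[i] / tot) if tot > 0 else 1.0 / k
        else:
            running -= miss
        if abs(running) > abs(best):
            best = running
    return best


class TestRankingStatistic:
    def test_signed_log10(self):
        ranked = ranking_statistic(
            de_frame([("up", 2.0, 0.01, 0.1), ("dn", -1.0, 0.001, 0.1),
                      ("null", 0.0, 0.5, 0.9)])
        )
        stat = ranked.set_index("gene_id")["stat"]
        assert stat["up"] == pytest.approx(2.0)
        assert stat["dn"] == pytest.approx(-3.0)
        assert stat["null"] == 0.0
        assert list(ranked["gene_id"]) == ["up", "null", "dn"]

    def test_zero_pvalue_clamped_finite(self):
        ranked = ranking_statistic(de_frame([("g", 1.0, 0.0, 0.0)]))
        assert np.isfinite(ranked["stat"].iloc[0])
        assert ranked["stat"].iloc[0] > 300

    def test_deterministic_tiebreak(self):
        rows = [("b", 1.0, 0.1, 0.1), ("a", 1.0, 0.1, 0.1), ("c", 2.0, 0.1, 0.1)]
        ranked = ranking_statistic(de_frame(rows))
        # equal stats: larger |log2fc| first, then lexicographic id
        assert list(ranked["gene_id"]) == ["c", "a", "b"]


class TestDarWeighting:
    def test_complement_weighting(self):
        ranked = ranking_statistic(
            de_frame([("hi", 1.0, 1e-3, 0.01), ("lo", 1.0, 1e-2, 0.05)])
        )
        weighted = dar_weight_ranks(
            ranked, gene_dar_frame([("hi", 0.9), ("lo", 0.1)])
        )
        stat = weighted.set_index("gene_id")["stat"]
        assert stat["hi"] == pytest.approx(3 * 0.1)
        assert stat["lo"] == pytest.approx(2 * 0.9)
        assert list(weighted["gene_id"]) == ["lo", "hi"]  # order inverted

    def test_extreme_dar_values(self):
        ranked = ranking_statistic(
            de_frame([("full", 1.0, 1e-4, 0.01), ("none", -1.0, 1e-4, 0.01)])
        )
        weighted = dar_weight_ranks(
            ranked, gene_dar_frame([("full", 1.0), ("none", 0.0)])
        )
        stat = weighted.set_index("gene_id")["stat"]
        assert stat["full"] == 0.0
        assert stat["none"] == pytest.approx(-4.0)

    def test_undefined_dar_left_unweighted(self):
        ranked = ranking_statistic(de_frame([("g", 1.0, 1e-2, 0.05)]))
        weighted = dar_weight_ranks(ranked, gene_dar_frame([("g", np.nan)]))
        assert weighted["stat"].iloc[0] == pytest.approx(2.0)

    def test_shrinks_magnitude_never_flips_sign(self):
        rng = np.random.default_rng(3)
        rows = [(f"g{i}", rng.normal(), rng.uniform(1e-6, 1), 0.5)
                for i in range(50)]
        ranked = ranking_statistic(de_frame(rows))
        dars = gene_dar_frame([(f"g{i}", rng.uniform(0, 1)) for i in range(50)])
        weighted = dar_weight_ranks(ranked, dars).set_index("gene_id")
        orig = ranked.set_index("gene_id")
        for g in orig.index:
            s0, s1 = orig.loc[g, "stat"], weighted.loc[g, "stat"]
            assert abs(s1) <= abs(s0) + 1e-12
            assert s0 * s1 >= 0


class TestThresholdExclude:
    UNIVERSE = ["a", "b", "c", "d"]
    DARS = gene_dar_frame([("a", 0.2), ("b", 0.6), ("c", 0.9), ("d", np.nan)])
    DE = de_frame([("a", 1, 0.01, 0.01), ("b", 1, 0.5, 0.5),
                   ("c", 1, 0.01, 0.01), ("d", 1, 0.5, 0.5)])

    def test_threshold_one_removes_nothing(self):
        kept, ex_de, ex_nonde = threshold_exclude(
            self.UNIVERSE, self.DARS, self.DE, 1.0
        )
        assert kept == self.UNIVERSE
        assert (ex_de, ex_nonde) == (0, 0)

    def test_strict_inequality_at_boundary(self):
        kept, ex_de, ex_nonde = threshold_exclude(
            self.UNIVERSE, self.DARS, self.DE, 0.6
        )
        assert kept == ["a", "b", "d"]  # 0.6 retained, only 0.9 removed
        assert (ex_de, ex_nonde) == (1, 0)

    def test_undefined_dar_never_removed(self):
        kept, _, _ = threshold_exclude(self.UNIVERSE, self.DARS, self.DE, 0.1)
        assert "d" in kept

    def test_monotone_in_threshold(self):
        prev = set(self.UNIVERSE)
        for thr in np.arange(1.0, 0.05, -0.1):
            kept, _, _ = threshold_exclude(
                self.UNIVERSE, self.DARS, self.DE, float(thr)
            )
            assert set(kept) <= prev
            prev = set(kept)


class TestGseaEngine:
    def _ranked(self, stats):
        return pd.DataFrame(
            {"gene_id": [g for g, _ in stats],
             "stat": [s for _, s in stats],
             "log2fc": [s for _, s in stats]}
        )

    def test_es_matches_literal_loop(self):
        rng = np.random.default_rng(9)
        genes = [f"g{i}" for i in range(40)]
        stats = sorted(
            zip(genes, rng.normal(size=40)), key=lambda t: -t[1]
        )
        ranked = self._ranked(stats)
        for seed in range(5):
            members = set(np.random.default_rng(seed).choice(genes, 8, replace=False))
            res = gsea_preranked(ranked, {"s": sorted(members)}, n_perm=10, seed=0)
            assert res["es"].iloc[0] == pytest.approx(
                literal_es(stats, members), abs=1e-12
            )

    def test_top_k_set_maximises_es(self):
        """Brute force: among all k-subsets of a strictly positive ranked
        universe, the set of the top k genes attains the maximal ES."""
        genes = [f"g{i}" for i in range(10)]
        stats = list(zip(genes, np.linspace(5.0, 0.5, 10)))
        ranked = self._ranked(stats)
        for k in (2, 3):
            es_by_set = {}
            for sub in combinations(genes, k):
                res = gsea_preranked(
                    ranked, {"s": list(sub)}, n_perm=10, seed=0, min_size=k
                )
                es_by_set[sub] = res["es"].iloc[0]
            assert max(es_by_set, key=es_by_set.get) == tuple(genes[:k])

    def test_sign_reversal_negates_es(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(30)]
        vals = rng.normal(size=30)
        members = sorted(rng.choice(genes, 6, replace=False))
        up = gsea_preranked(
            self._ranked(sorted(zip(genes, vals), key=lambda t: -t[1])),
            {"s": members}, n_perm=10, seed=0,
        )
        dn = gsea_preranked(
            self._ranked(sorted(zip(genes, -vals), key=lambda t: -t[1])),
            {"s": members}, n_perm=10, seed=0,
        )
        assert dn["es"].iloc[0] == pytest.approx(-up["es"].iloc[0], abs=1e-12)

    def test_running_sum_returns_to_zero(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(25)]
        stats = sorted(zip(genes, rng.normal(size=25)), key=lambda t: -t[1])
        members = set(genes[3:9])
        absw = [abs(s) for _, s in stats]
        tot = sum(absw[i] for i, (g, _) in enumerate(stats) if g in members)
        running = 0.0
        for i, (g, _) in enumerate(stats):
            running += absw[i] / tot if g in members else -1.0 / (25 - 6)
        assert running == pytest.approx(0.0, abs=1e-12)

    def test_whole_universe_set_is_degenerate(self):
        genes = [f"g{i}" for i in range(8)]
        ranked = self._ranked(list(zip(genes, np.arange(8, 0, -1.0))))
        res = gsea_preranked(ranked, {"all": genes}, n_perm=50, seed=0)
        assert res["es"].iloc[0] == pytest.approx(1.0)
        assert res["pval"].iloc[0] == pytest.approx(1.0)

    def test_small_sets_dropped(self):
        genes = [f"g{i}" for i in range(20)]
        ranked = self._ranked(list(zip(genes, np.arange(20, 0, -1.0))))
        res = gsea_preranked(
            ranked, {"tiny": genes[:3], "ok": genes[:6]}, n_perm=20, seed=0
        )
        assert list(res["set_name"]) == ["ok"]

    def test_leading_edge_subset_of_members(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(30)]
        stats = sorted(zip(genes, rng.normal(size=30)), key=lambda t: -t[1])
        members = sorted(rng.choice(genes, 8, replace=False))
        res = gsea_preranked(self._ranked(stats), {"s": members}, n_perm=20, seed=0)
        assert set(res["leading_edge"].iloc[0]) <= set(members)
        assert res["n_leading_edge"].iloc[0] >= 1

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(8)
        genes = [f"g{i}" for i in range(50)]
        ranked = self._ranked(
            sorted(zip(genes, rng.normal(size=50)), key=lambda t: -t[1])
        )
        sets = {"s1": genes[:10], "s2": genes[20:30]}
        a = gsea_preranked(ranked, sets, n_perm=200, seed=5)
        b = gsea_preranked(ranked, sets, n_perm=200, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestPwf:
    def test_constant_bias_gives_overall_rate(self):
        flags = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        pwf = fit_pwf(flags, np.full(10, 0.5))
        assert np.allclose(pwf.weights, 0.2)
        assert pwf.direction == 0

    def test_no_bias_limit_is_flat(self):
        rng = np.random.default_rng(0)
        flags = rng.random(2000) < 0.3
        bias = rng.uniform(0, 1, size=2000)
        pwf = fit_pwf(flags, bias, n_bins=50)
        assert np.all(np.abs(pwf.weights - 0.3) < 0.15)

    def test_step_recovery(self):
        rng = np.random.default_rng(1)
        bias = rng.uniform(0, 1, size=4000)
        prob = np.where(bias > 0.5, 0.6, 0.1)
        flags = rng.random(4000) < prob
        pwf = fit_pwf(flags, bias, n_bins=100)
        low = pwf.weights[bias < 0.4].mean()
        high = pwf.weights[bias > 0.6].mean()
        assert abs(low - 0.1) < 0.05
        assert abs(high - 0.6) < 0.05
        assert pwf.direction == 1

    def test_monotone_along_bias(self):
        rng = np.random.default_rng(2)
        bias = rng.uniform(0, 1, size=1000)
        flags = rng.random(1000) < 0.1 + 0.7 * bias
        pwf = fit_pwf(flags, bias, n_bins=40)
        order = np.argsort(bias)
        diffs = np.diff(pwf.weights[order])
        assert (diffs >= -1e-12).all()

    def test_nan_bias_gets_overall_rate(self):
        flags = np.array([1, 0, 1, 0, 0, 0])
        bias = np.array([0.1, 0.2, 0.3, 0.4, np.nan, np.nan])
        pwf = fit_pwf(flags, bias)
        assert pwf.weights[4] == pytest.approx(max(flags.mean(), PWF_FLOOR))

    def test_weights_floored_positive(self):
        flags = np.zeros(100)
        bias = np.linspace(0, 1, 100)
        pwf = fit_pwf(flags, bias, n_bins=10)
        assert (pwf.weights >= PWF_FLOOR).all()


class TestOverrep:
    def _uniform_pwf(self, genes):
        n = len(genes)
        return PWF(list(genes), np.full(n, 0.5), 0, np.array([]), np.array([]),
                   fallback=0.5)

    def test_constant_pwf_matches_hypergeometric(self):
        """With uniform weights the sampling null is the hypergeometric
        distribution; check against exact enumeration on 20 genes."""
        genes = [f"g{i}" for i in range(20)]
        flags = np.array([True] * 6 + [False] * 14)
        members = genes[:4] + genes[10:16]  # 10-gene set, 4 DE members
        obs = 4
        n_samples = 20000
        res = overrep_test(
            flags, {"s": members}, self._uniform_pwf(genes), genes=genes,
            n_samples=n_samples, seed=7,
        )
        # exact tail: P(X >= 4), X ~ Hypergeom(N=20, K=10 set genes, n=6 draws)
        exact = sum(
            comb(10, k) * comb(10, 6 - k) for k in range(obs, 7)
        ) / comb(20, 6)
        mc_se = np.sqrt(exact * (1 - exact) / n_samples)
        assert abs(res["pval"].iloc[0] - exact) < 3 * mc_se + 2 / n_samples

    def test_heavy_weight_on_set_inflates_null(self):
        """Loading PWF weight onto the set's genes makes its DE content
        unremarkable under the null: p rises toward 1."""
        genes = [f"g{i}" for i in range(40)]
        flags = np.array([True] * 5 + [False] * 35)
        members = genes[:5] + genes[20:25]
        biased = np.where(np.isin(genes, members), 50.0, 1e-3)
        pwf_b = PWF(list(genes), biased, 1, np.array([]), np.array([]), fallback=1.0)
        res_b = overrep_test(flags, {"s": members}, pwf_b, genes=genes,
                             n_samples=4000, seed=1)
        res_u = overrep_test(flags, {"s": members}, self._uniform_pwf(genes),
                             genes=genes, n_samples=4000, seed=1)
        assert res_b["pval"].iloc[0] > res_u["pval"].iloc[0]
        assert res_b["pval"].iloc[0] > 0.9

    def test_small_and_empty_sets_excluded(self):
        genes = [f"g{i}" for i in range(20)]
        flags = np.array([True] * 4 + [False] * 16)
        sets = {
            "four_members": genes[:4],
            "no_de": genes[10:16],
            "kept": genes[:6],
        }
        res = overrep_test(flags, sets, self._uniform_pwf(genes), genes=genes,
                           n_samples=500, seed=0)
        assert list(res["set_name"]) == ["kept"]

    def test_reproducible_given_seed(self):
        genes = [f"g{i}" for i in range(30)]
        flags = np.array([True] * 6 + [False] * 24)
        sets = {"s": genes[:8]}
        a = overrep_test(flags, sets, self._uniform_pwf(genes), genes=genes,
                         n_samples=2000, seed=11)
        b = overrep_test(flags, sets, self._uniform_pwf(genes), genes=genes,
                         n_samples=2000, seed=11)
        pd.testing.assert_frame_equal(a, b)


class TestGmtIO:
    def test_roundtrip(self, tmp_path):
        sets = {"alpha": ["g1", "g2", "g3"], "beta": ["g4", "g5"]}
        path = tmp_path / "x.gmt"
        write_gmt(sets, str(path))
        assert read_gmt(str(path)) == sets

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("only_name\tdesc\n")
        with pytest.raises(InputError, match="line 1"):
            read_gmt(str(path))
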