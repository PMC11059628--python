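"""mPPM/DmPPM statistics, ANOVA/Tukey, correlations, GC regression."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from epiphase.calls import MISSING
from epiphase.stats import (
    anova_oneway,
    dmppm_test,
    gc_reads_regression,
    kruskal_wallis,
    level_correlations,
    mppm,
    mppm_table,
    pairwise_dmppm,
    site_levels,
    site_levels_and_anova,
    tukey_hsd,
    within_molecule_context_stats,
)
from epiphase.targets import context_indices

from .conftest import make_call, make_target


# ---------------------------------------------------------------------------
# independent oracles

def kw_oracle(*groups):
    """Rank-based H computed from first principles, plus exact permutation p."""
    pooled = np.concatenate([np.asarray(g, float) for g in groups])
    n = len(pooled)
    sizes = [len(g) for g in groups]

    def h_statistic(values_by_group):
        flat = np.concatenate(values_by_group)
        order = np.argsort(flat, kind="stable")
        ranks = np.empty(n)
        # mid-ranks for ties
        sorted_vals = flat[order]
        i = 0
        while i < n:
            j = i
            while j < n and sorted_vals[j] == sorted_vals[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        h = 0.0
        start = 0
        for g in values_by_group:
            r = ranks[start : start + len(g)]
            h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
            start += len(g)
        h *= 12.0 / (n * (n + 1))
        _, counts = np.unique(flat, return_counts=True)
        correction = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
        return h / correction if correction > 0 else 0.0

    h_obs = h_statistic([np.asarray(g, float) for g in groups])
    # exact permutation distribution of H over all label assignments
    count = total = 0
    for combo in itertools.combinations(range(n), sizes[0]):
        mask = np.zeros(n, bool)
        mask[list(combo)] = True
        h_perm = h_statistic([pooled[mask], pooled[~mask]])
        total += 1
        if h_perm >= h_obs - 1e-12:
            count += 1
    return h_obs, count / total


# ---------------------------------------------------------------------------
# mPPM

class TestMppm:
    def test_proportion(self, small_target):
        sites = small_target.sites()
        cg = context_indices(sites, "CG")
        calls = np.zeros(len(sites), dtype=np.int8)
        calls[cg[:4]] = [1, 0, 1, 1]
        rec = mppm(make_call(calls), sites, "CG")
        assert rec.n_sites == len(cg)
        assert rec.mppm == pytest.approx(3 / len(cg))

    def test_all_zero(self, small_target):
        sites = small_target.sites()
        rec = mppm(make_call(np.zeros(len(sites), np.int8)), sites, "CHH")
        assert rec.mppm == 0.0

    def test_absent_context_omitted(self):
        target = make_target("ACGAACGA", "nochh")  # no CHH sites
        sites = target.sites()
        assert all(s.context == "CG" for s in sites)
        call = make_call(np.zeros(len(sites), np.int8), target_id="nochh")
        assert mppm(call, sites, "CHH") is None

    def test_requires_full_length(self, small_target):
        sites = small_target.sites()
        calls = np.zeros(len(sites), np.int8)
        calls[context_indices(sites, "CG")[0]] = MISSING
        with pytest.raises(ValueError, match="full-length"):
            mppm(make_call(calls), sites, "CG")

    def test_simulated_mean_matches_binomial_oracle(self, small_target):
        from epiphase.simulate import EpialleleClass, simulate_molecules

        p = 0.6
        cls = EpialleleClass("c", 1.0, {"CG": p, "CHG": 0.0, "CHH": 0.0})
        truths = simulate_molecules(small_target, [cls], 10000, seed=21)
        sites = small_target.sites()
        calls = [make_call(t.states, read_id=t.molecule_id) for t in truths]
        table = mppm_table(calls, sites)
        values = table.loc[table["context"] == "CG", "mppm"]
        k = len(context_indices(sites, "CG"))
        se = np.sqrt(p * (1 - p) / (k * len(values)))
        assert abs(values.mean() - p) < 3 * se

    def test_pooling_replicates_equals_concatenation(self, small_target, rng):
        sites = small_target.sites()
        reps = {}
        for rep in ("R1", "R2"):
            reps[rep] = [
                make_call(rng.integers(0, 2, len(sites)), read_id=f"{rep}r{i}", replicate=rep)
                for i in range(20)
            ]
        pooled = mppm_table(reps["R1"] + reps["R2"], sites)
        concat = pd.concat([mppm_table(reps["R1"], sites), mppm_table(reps["R2"], sites)])
        merged = pooled.sort_values(["read_id", "context"]).reset_index(drop=True)
        concat = concat.sort_values(["read_id", "context"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, concat)


# ---------------------------------------------------------------------------
# DmPPM / Kruskal-Wallis

class TestDmppm:
    def test_identical_groups(self):
        a = [0.1, 0.4, 0.4, 0.9]
        res = dmppm_test(a, list(a))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.significant

    def test_all_identical_values(self):
        res = dmppm_test([0.5, 0.5], [0.5, 0.5, 0.5])
        assert (res.statistic, res.p_value) == (0.0, 1.0)

    def test_symmetric_in_group_order(self, rng):
        a = rng.random(15)
        b = rng.random(20)
        assert dmppm_test(a, b).p_value == pytest.approx(dmppm_test(b, a).p_value)

    def test_small_group_returns_na(self):
        res = dmppm_test([0.5], [0.1, 0.2, 0.3])
        assert np.isnan(res.p_value) and not res.significant

    def test_against_exact_permutation_oracle(self):
        """H tracks the rank statistic exactly; chi-square p is within
        approximation error of the exhaustive permutation p on 10 points."""
        a = [0.0] * 5
        b = [1.0] * 5
        h_oracle, p_exact = kw_oracle(a, b)
        h, p = kruskal_wallis(a, b)
        assert h == pytest.approx(h_oracle, abs=1e-10)
        assert abs(p - p_exact) < 0.01

    def test_permutation_oracle_distinct_values(self, rng):
        a = list(rng.random(5))
        b = list(rng.random(5))
        h_oracle, p_exact = kw_oracle(a, b)
        h, p = kruskal_wallis(a, b)
        assert h == pytest.approx(h_oracle, abs=1e-10)
        # chi-square approximation error in the mid p range at n = 10 is ~0.1
        assert abs(p - p_exact) < 0.12

    def test_median_diff_sign(self):
        res = dmppm_test([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert res.median_diff == pytest.approx(0.6)

    def test_pairwise_table_with_bh(self):
        groups = {
            "a": [0.1, 0.2, 0.15, 0.12],
            "b": [0.8, 0.9, 0.85, 0.82],
            "c": [0.5, 0.55, 0.52, 0.51],
        }
        frame = pairwise_dmppm(groups, "t", "CG", adjust="bh")
        assert len(frame) == 3
        assert "p_adj_bh" in frame
        assert (frame["p_adj_bh"] >= frame["p_value"] - 1e-12).all()


# ---------------------------------------------------------------------------
# site levels + ANOVA/Tukey

class TestSiteLevels:
    def test_non_missing_denominator(self, small_target):
        sites = small_target.sites()
        first = context_indices(sites, "CG")[0]
        vec = np.zeros(len(sites), np.int8)
        calls = []
        for value in (1, 0, MISSING):
            v = vec.copy()
            v[first] = value
            calls.append(make_call(v))
        levels = site_levels(calls, sites, "CG")
        assert levels[0] == pytest.approx(0.5)  # [1, 0, missing] -> 0.5

    def test_constant_data_gives_f0_p1(self, small_target):
        sites = small_target.sites()
        calls = []
        for sample in ("a", "b"):
            for rep in ("R1", "R2"):
                for i in range(3):
                    calls.append(
                        make_call(
                            np.ones(len(sites), np.int8),
                            read_id=f"{sample}{rep}{i}",
                            sample=sample,
                            replicate=rep,
                        )
                    )
        _, anova, tukey = site_levels_and_anova(calls, sites, "CG")
        assert anova["F"] == 0.0 and anova["p_value"] == 1.0
        assert (tukey["p_value"] == 1.0).all()

    def test_anova_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        groups = [rng.normal(mu, 1.0, size=4) for mu in (0.0, 0.5, 1.0, 2.0)]
        f, p = anova_oneway(groups)
        frame = pd.DataFrame(
            {
                "y": np.concatenate(groups),
                "g": np.repeat([f"g{i}" for i in range(4)], 4),
            }
        )
        table = sm.stats.anova_lm(ols("y ~ C(g)", data=frame).fit(), typ=1)
        assert f == pytest.approx(table["F"].iloc[0], abs=1e-8)
        assert p == pytest.approx(table["PR(>F)"].iloc[0], abs=1e-8)

    def test_tukey_matches_scipy_reference(self, rng):
        groups = [rng.normal(mu, 1.0, size=5) for mu in (0.0, 0.4, 1.1)]
        mine = tukey_hsd(groups)
        ref = sps.tukey_hsd(*groups)
        for _, row in mine.iterrows():
            i = int(row["group_a"][1:])
            j = int(row["group_b"][1:])
            assert row["p_value"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)
            assert row["mean_diff"] == pytest.approx(
                groups[j].mean() - groups[i].mean(), abs=1e-12
            )

    def test_tukey_matches_statsmodels_coarsely(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        groups = [rng.normal(mu, 1.0, size=6) for mu in (0.0, 0.8, 1.5, 1.6)]
        mine = tukey_hsd(groups)
        res = pairwise_tukeyhsd(
            np.concatenate(groups), np.repeat([f"g{i}" for i in range(4)], 6)
        )
        np.testing.assert_allclose(
            mine["p_value"].to_numpy(), res.pvalues, atol=2e-3
        )

    def test_replicate_shift_detected(self, small_target, rng):
        from epiphase.simulate import EpialleleClass, simulate_molecules

        sites = small_target.sites()
        calls = []
        for sample, p in (("low", 0.2), ("high", 0.8)):
            for rep in ("R1", "R2", "R3"):
                cls = EpialleleClass("c", 1.0, {"CG": p, "CHG": p, "CHH": 0.0})
                truths = simulate_molecules(
                    small_target, [cls], 60, seed=abs(hash((sample, rep))) % 2**31
                )
                calls += [
                    make_call(t.states, read_id=f"{sample}{rep}{t.molecule_id}",
                              sample=sample, replicate=rep)
                    for t in truths
                ]
        _, anova, tukey = site_levels_and_anova(calls, sites, "CG")
        assert anova["p_value"] < 0.01
        assert tukey["significant"].all()

    def test_too_few_replicates_skips_test(self, small_target):
        sites = small_target.sites()
        calls = [
            make_call(np.zeros(len(sites), np.int8), sample=s, replicate="R1")
            for s in ("a", "b")
        ]
        _, anova, tukey = site_levels_and_anova(calls, sites, "CG")
        assert np.isnan(anova["F"]) and tukey is None


# ---------------------------------------------------------------------------
# correlations, context coupling, GC regression

class TestCorrelations:
    def test_self_correlation(self, rng):
        x = rng.random(30)
        assert level_correlations(x, x) == pytest.approx(1.0)

    def test_anti_monotone(self, rng):
        x = rng.random(30)
        assert level_correlations(x, 1 - x) == pytest.approx(-1.0)

    def test_too_few_sites_nan(self):
        assert np.isnan(level_correlations([0.1, 0.2], [0.3, 0.4]))

    def test_nan_sites_dropped(self):
        a = np.array([0.1, np.nan, 0.5, 0.9, 0.2])
        b = np.array([0.2, 0.5, np.nan, 0.8, 0.1])
        ok = ~(np.isnan(a) | np.isnan(b))
        expected = sps.pearsonr(a[ok], b[ok]).statistic
        assert level_correlations(a, b) == pytest.approx(expected)

    def test_spearman_flag(self, rng):
        x = rng.random(20)
        y = x**3  # monotone, nonlinear
        assert level_correlations(x, y, method="spearman") == pytest.approx(1.0)

    def test_simulated_replicates_correlate(self, small_target):
        from epiphase.simulate import EpialleleClass, simulate_molecules

        sites = small_target.sites()
        cls = EpialleleClass(
            "c", 1.0, {"CG": 0.7, "CHG": 0.4, "CHH": 0.1}, persistence=0.3
        )
        profiles = []
        for seed in (31, 32):
            truths = simulate_molecules(small_target, [cls], 300, seed=seed)
            calls = [make_call(t.states, read_id=t.molecule_id) for t in truths]
            profiles.append(
                np.concatenate(
                    [site_levels(calls, sites, c) for c in ("CG", "CHG", "CHH")]
                )
            )
        assert level_correlations(*profiles) > 0.9


class TestContextCoupling:
    def test_ordering_fractions_strict_inequality(self, small_target):
        sites = small_target.sites()
        cg = context_indices(sites, "CG")
        chg = context_indices(sites, "CHG")
        chh = context_indices(sites, "CHH")

        def call_with(p_cg, p_chg, p_chh, read_id):
            v = np.zeros(len(sites), np.int8)
            v[cg[: int(round(p_cg * len(cg)))]] = 1
            v[chg[: int(round(p_chg * len(chg)))]] = 1
            v[chh[: int(round(p_chh * len(chh)))]] = 1
            return make_call(v, read_id=read_id)

        calls = [
            call_with(1.0, 0.5, 0.25, "a"),  # counts toward both fractions
            call_with(0.5, 0.5, 0.25, "b"),  # tie CG=CHG: only the second
        ]
        _, fractions, _ = within_molecule_context_stats(calls, sites)
        assert fractions["frac_cg_gt_chg"] == pytest.approx(0.5)
        assert fractions["frac_chg_gt_chh"] == pytest.approx(1.0)

    def test_coupling_raises_pairwise_correlation(self, small_target):
        from epiphase.simulate import EpialleleClass, simulate_molecules

        sites = small_target.sites()

        def corr(sd):
            cls = EpialleleClass(
                "c", 1.0, {"CG": 0.7, "CHG": 0.35, "CHH": 0.1}, propensity_sd=sd
            )
            truths = simulate_molecules(small_target, [cls], 5000, seed=41)
            calls = [make_call(t.states, read_id=t.molecule_id) for t in truths]
            _, _, c = within_molecule_context_stats(calls, sites)
            return c.loc["CG", "CHG"]

        assert corr(2.0) > corr(0.0)


class TestGcRegression:
    def test_exact_log_fit(self):
        gc = np.linspace(0.2, 0.5, 10)
        reads = 5 + 2 * np.log(gc)
        fit = gc_reads_regression(gc, reads)
        assert fit["r_squared"] == pytest.approx(1.0)
        assert fit["slope"] == pytest.approx(2.0)
        assert fit["intercept"] == pytest.approx(5.0)

    def test_constant_counts(self):
        fit = gc_reads_regression(np.linspace(0.2, 0.5, 8), np.full(8, 7.0))
        assert fit["r_squared"] == 0.0

    def test_permutation_null_r2(self, rng):
        """Under permutation, E[R^2] = 1/(n-1); empirical p roughly uniform."""
        n = 20
        gc = rng.uniform(0.19, 0.52, n)
        reads = rng.poisson(100, n).astype(float)
        r2 = []
        pvals = []
        for _ in range(1000):
            permuted = rng.permutation(reads)
            fit = gc_reads_regression(gc, permuted)
            r2.append(fit["r_squared"])
            pvals.append(fit["p_value"])
        assert np.mean(r2) == pytest.approx(1 / (n - 1), abs=0.02)
        # uniformity of p: KS test should not reject wildly
        assert sps.kstest(pvals, "uniform").pvalue > 0.001

    def test_nonpositive_gc_excluded_and_minimum(self):
        with pytest.raises(ValueError, match=">= 3"):
            gc_reads_regression([0.0, 0.3], [1.0, 2.0])


class TestExternalConcordance:
    def test_perfect_agreement_with_external_table(self, tmp_path, small_target, rng):
        from epiphase.stats import external_concordance, load_external_levels
        from epiphase.targets import genomic_position

        sites = small_target.sites()
        calls = [make_call(rng.integers(0, 2, len(sites)), read_id=f"r{i}") for i in range(80)]
        rows = ["chrom\tposition\tcontext\tsample\tlevel"]
        for context in ("CG", "CHG", "CHH"):
            levels = site_levels(calls, sites, context)
            offsets = [s.offset for s in sites if s.context == context]
            for offset, level in zip(offsets, levels):
                position = genomic_position(small_target, offset)
                rows.append(f"{small_target.chrom}\t{position}\t{context}\twgbs\t{level}")
        path = tmp_path / "external.tsv"
        path.write_text("\n".join(rows) + "\n")
        table = load_external_levels(path)
        r = external_concordance(calls, small_target, table, "wgbs")
        assert r == pytest.approx(1.0)

    def test_missing_columns_fatal(self, tmp_path):
        from epiphase.stats import load_external_levels

        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tposition\n")
        with pytest.raises(ValueError, match="missing columns"):
            load_external_levels(path)
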