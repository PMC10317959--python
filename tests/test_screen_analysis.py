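"""Tests of screen analysis: normalization exactness, TMM vs a naive
trimmed-mean oracle, log2FC arithmetic, t-test calibration, the exponential
fitness fit vs normal-equations and statsmodels oracles, rank aggregation vs
a closed-form Beta/binomial oracle, differential calling and secondary hit
categories."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import statsmodels.api as sm
from crisprtile import screen_analysis as sa

from conftest import make_counts


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

class TestNormalizeToControls:
    def test_median_exactly_target(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.integers(1, 5000, size=(200, 6)).astype(float),
            index=[f"g{i}" for i in range(200)],
            columns=[f"MPM1_rep{r}_day{d}" for r in (1, 2) for d in (0, 8, 22)],
        )
        controls = [f"g{i}" for i in range(11)]  # odd count: median is an element
        norm = sa.normalize_to_controls(counts, controls)
        med = norm.loc[controls].median(axis=0)
        assert (med == 1000.0).all()

    def test_halved_controls_double_everything(self):
        counts = pd.DataFrame(
            {"MPM1_rep1_day0": [500.0, 500.0, 500.0, 123.0]},
            index=["c1", "c2", "c3", "x"],
        )
        norm = sa.normalize_to_controls(counts, ["c1", "c2", "c3"])
        assert norm.loc["x", "MPM1_rep1_day0"] == 246.0

    def test_identity_when_median_is_target(self):
        counts = pd.DataFrame(
            {"MPM1_rep1_day0": [1000.0, 1000.0, 1000.0, 77.0]},
            index=["c1", "c2", "c3", "x"],
        )
        norm = sa.normalize_to_controls(counts, ["c1", "c2", "c3"])
        pd.testing.assert_frame_equal(norm, counts)

    def test_ratios_preserved(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            rng.integers(1, 1000, (50, 2)).astype(float),
            index=[f"g{i}" for i in range(50)],
            columns=["MPM1_rep1_day0", "MPM1_rep1_day22"],
        )
        norm = sa.normalize_to_controls(counts, [f"g{i}" for i in range(5)])
        for col in counts:
            np.testing.assert_allclose(
                norm[col] / norm[col].iloc[0], counts[col] / counts[col].iloc[0]
            )

    def test_errors(self):
        counts = pd.DataFrame({"MPM1_rep1_day0": [0.0, 5.0]}, index=["c", "x"])
        with pytest.raises(ValueError, match="non-empty"):
            sa.normalize_to_controls(counts, [])
        with pytest.raises(ValueError, match="absent"):
            sa.normalize_to_controls(counts, ["nope"])
        with pytest.raises(ValueError, match="zero control median"):
            sa.normalize_to_controls(counts, ["c"])


# ---------------------------------------------------------------------------
# TMM
# ---------------------------------------------------------------------------

def naive_tmm_pair(obs, ref, trim_M=0.3, trim_A=0.05):
    """Percentile-mask reimplementation of the doubly trimmed weighted mean."""
    n_o, n_r = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    o, r = obs[keep] / n_o, ref[keep] / n_r
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    w = 1.0 / ((n_o - obs[keep]) / (n_o * obs[keep]) + (n_r - ref[keep]) / (n_r * ref[keep]))
    n = M.size
    rM, rA = stats.rankdata(M), stats.rankdata(A)
    lo_l, lo_s = np.floor(n * trim_M) + 1, np.floor(n * trim_A) + 1
    sel = (rM >= lo_l) & (rM <= n + 1 - lo_l) & (rA >= lo_s) & (rA <= n + 1 - lo_s)
    return 2.0 ** (np.sum(M[sel] * w[sel]) / np.sum(w[sel]))


class TestTMM:
    def test_identical_samples_unit_factors(self):
        rng = np.random.default_rng(2)
        col = rng.integers(1, 2000, 500).astype(float)
        counts = pd.DataFrame({"MPM1_rep1_day0": col, "MPM1_rep2_day0": col})
        f = sa.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0)

    def test_pure_depth_change_unit_factors(self):
        rng = np.random.default_rng(3)
        col = rng.integers(1, 2000, 500).astype(float)
        counts = pd.DataFrame({"MPM1_rep1_day0": col, "MPM1_rep2_day0": col * 3})
        f = sa.tmm_factors(counts)
        np.testing.assert_allclose(f, 1.0, rtol=1e-12)

    def test_planted_composition_bias_corrected(self):
        rng = np.random.default_rng(4)
        a = rng.integers(100, 2000, 2000).astype(float)
        b = a.copy()
        enriched = rng.choice(2000, 100, replace=False)
        b[enriched] *= 20
        counts = pd.DataFrame({"MPM1_rep1_day0": a, "MPM1_rep2_day0": b})
        norm = sa.tmm_normalize(counts)
        mask = np.ones(2000, bool)
        mask[enriched] = False
        ratio = (norm.iloc[mask.nonzero()[0], 1] / norm.iloc[mask.nonzero()[0], 0]).mean()
        assert abs(ratio - 1.0) < 0.02

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            rng.negative_binomial(20, 0.02, size=(1000, 4)).astype(float) + 1,
            columns=[f"MPM1_rep{r}_day{d}" for r, d in ((1, 0), (1, 8), (2, 0), (2, 8))],
        )
        f = sa.tmm_factors(counts)
        Y = counts.to_numpy()
        lib = Y.sum(axis=0)
        uq = np.array([np.percentile(Y[:, j] / lib[j], 75) for j in range(4)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        raw = np.array(
            [1.0 if j == ref else naive_tmm_pair(Y[:, j], Y[:, ref]) for j in range(4)]
        )
        raw /= np.exp(np.mean(np.log(raw)))
        np.testing.assert_allclose(f.to_numpy(), raw, rtol=1e-10)

    def test_errors(self):
        one = pd.DataFrame({"MPM1_rep1_day0": [1.0, 2.0]})
        with pytest.raises(ValueError, match="two samples"):
            sa.tmm_factors(one)


# ---------------------------------------------------------------------------
# per-guide statistics
# ---------------------------------------------------------------------------

class TestGuideLfc:
    def test_doubling_gives_lfc_one(self):
        # the tiny guide pins the min-nonzero pseudocount at 1, negligible
        # against the large counts
        counts = pd.DataFrame(
            {"MPM1_rep1_day0": [1000.0, 500.0, 1.0], "MPM1_rep1_day22": [2000.0, 1000.0, 2.0]},
            index=["a", "b", "tiny"],
        )
        out = sa.guide_lfc(counts).set_index("guide_id")
        assert out.loc[["a", "b"], "lfc"].to_numpy() == pytest.approx([1.0, 1.0], abs=0.01)

    def test_identical_counts_zero_lfc(self):
        counts = pd.DataFrame(
            {"MPM1_rep1_day0": [300.0], "MPM1_rep1_day8": [300.0]}, index=["a"]
        )
        assert sa.guide_lfc(counts)["lfc"].iloc[0] == 0.0

    def test_zero_count_with_min_nonzero_pseudocount(self):
        counts = pd.DataFrame(
            {"MPM1_rep1_day0": [2000.0, 2.0], "MPM1_rep1_day22": [0.0, 2.0]},
            index=["a", "b"],
        )
        out = sa.guide_lfc(counts)  # pseudocount = min nonzero = 2
        lfc_a = out[out["guide_id"] == "a"]["lfc"].iloc[0]
        assert lfc_a == pytest.approx(np.log2(2.0 / 2002.0), abs=1e-9)

    def test_missing_day0_error(self):
        counts = pd.DataFrame({"MPM1_rep1_day8": [1.0]}, index=["a"])
        with pytest.raises(ValueError, match="day-0"):
            sa.guide_lfc(counts)


class TestDepletionTest:
    def _per_rep(self, lfcs):
        return pd.DataFrame(
            {
                "guide_id": "g",
                "cell_line": "MPM1",
                "replicate": range(1, len(lfcs) + 1),
                "day": 22,
                "lfc": lfcs,
            }
        )

    def test_all_zero_gives_p_one(self):
        out = sa.guide_depletion_test(self._per_rep([0.0, 0.0, 0.0]))
        assert out["p"].iloc[0] == 1.0
        assert out["t"].iloc[0] == 0.0

    def test_sign_symmetry(self):
        p_neg = sa.guide_depletion_test(self._per_rep([-1.0, -1.2, -0.8]))["p"].iloc[0]
        p_pos = sa.guide_depletion_test(self._per_rep([1.0, 1.2, 0.8]))["p"].iloc[0]
        assert p_neg == pytest.approx(p_pos, rel=1e-12)

    def test_zero_variance_nonzero_mean_flagged(self):
        out = sa.guide_depletion_test(self._per_rep([-1.0, -1.0]))
        assert out["degenerate"].iloc[0]
        assert out["p"].iloc[0] == sa.P_FLOOR

    def test_null_calibration_on_nb_counts(self):
        alphas = {f"g{i}": 0.0 for i in range(10_000)}
        counts = make_counts(
            alphas, list(alphas), replicates=4, timepoints=(0, 22),
            depth=1000.0, dispersion=0.05, seed=8,
        )
        out = sa.guide_depletion_test(sa.guide_lfc(counts.astype(float)))
        frac = (out["p"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07


# ---------------------------------------------------------------------------
# fitness model
# ---------------------------------------------------------------------------

def normal_equations_slope(region, pseudocount=0.0):
    """Independent oracle: explicit normal equations for the guide-intercept
    + shared-slope regression."""
    from crisprtile.workflow_io import sample_metadata

    meta = sample_metadata(region.columns)
    ys, ts, gs = [], [], []
    for gi, gid in enumerate(region.index):
        v = region.loc[gid, meta["sample"]].to_numpy(float) + pseudocount
        ok = v > 0
        ys.append(np.log(v[ok]))
        ts.append(meta["day"].to_numpy(float)[ok])
        gs.append(np.full(ok.sum(), gi))
    y = np.concatenate(ys)
    t = np.concatenate(ts)
    g = np.concatenate(gs).astype(int)
    m = len(region.index)
    X = np.zeros((y.size, m + 1))
    X[np.arange(y.size), g] = 1
    X[:, -1] = t
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    s2 = resid @ resid / (y.size - m - 1)
    cov = s2 * np.linalg.inv(X.T @ X)
    return beta[-1], np.sqrt(cov[-1, -1]), X, y


class TestFitFitness:
    def test_noiseless_exponential_recovered_exactly(self):
        t = np.array([0, 8, 15, 22])
        counts = pd.DataFrame(
            [1000.0 * np.exp(-0.1 * t), 400.0 * np.exp(-0.1 * t)],
            index=["g1", "g2"],
            columns=[f"MPM1_rep1_day{d}" for d in t],
        )
        res = sa.fit_fitness(counts)
        assert res.alpha == pytest.approx(-0.1, abs=1e-10)

    def test_constant_counts_zero_alpha(self):
        counts = pd.DataFrame(
            {f"MPM1_rep1_day{d}": [500.0] for d in (0, 8, 15, 22)}, index=["g"]
        )
        res = sa.fit_fitness(counts)
        assert res.alpha == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_normal_equations_and_statsmodels(self):
        for seed in range(20):
            counts = make_counts(
                {f"g{i}": -0.12 for i in range(3)}, [f"g{i}" for i in range(3)],
                replicates=2, depth=800.0, dispersion=0.05, seed=seed,
            ).astype(float)
            res = sa.fit_fitness(counts)
            a_o, se_o, X, y = normal_equations_slope(counts)
            assert res.alpha == pytest.approx(a_o, abs=1e-8)
            assert res.se == pytest.approx(se_o, abs=1e-8)
            ols = sm.OLS(y, X).fit()
            assert res.alpha == pytest.approx(ols.params[-1], abs=1e-8)
            assert res.p == pytest.approx(ols.pvalues[-1], abs=1e-8)

    def test_monte_carlo_bias_small(self):
        alphas = []
        for seed in range(50):
            counts = make_counts(
                {f"g{i}": -0.15 for i in range(4)}, [f"g{i}" for i in range(4)],
                replicates=2, depth=1000.0, dispersion=0.05, seed=100 + seed,
            ).astype(float)
            alphas.append(sa.fit_fitness(counts).alpha)
        assert abs(np.mean(alphas) + 0.15) < 0.01

    def test_too_few_timepoints_error(self):
        counts = pd.DataFrame({"MPM1_rep1_day0": [10.0]}, index=["g"])
        with pytest.raises(ValueError, match="timepoints"):
            sa.fit_fitness(counts)


# ---------------------------------------------------------------------------
# rank aggregation
# ---------------------------------------------------------------------------

def beta_tail_binomial(u, k, m):
    """P(Beta(k, m-k+1) <= u) = P(Binomial(m, u) >= k), the closed form."""
    return sum(stats.binom.pmf(j, m, u) for j in range(k, m + 1))


class TestRRA:
    def _pvals(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return pd.Series(rng.random(n), index=[f"g{i}" for i in range(n)])

    def test_single_guide_rho_is_percentile(self):
        p = self._pvals(100)
        p.iloc[0] = 0.0  # best rank
        g2r = pd.Series({"g0": "r"})
        out = sa.aggregate_region_rra(p, g2r, n_permutations=100)
        assert out["rho"].iloc[0] == pytest.approx(1.0 / 100)

    def test_four_best_ranks_match_closed_form(self):
        p = self._pvals(1000, seed=1)
        order = np.argsort(p.to_numpy())
        members = [p.index[i] for i in order[:4]]
        g2r = pd.Series({g: "r" for g in members})
        out = sa.aggregate_region_rra(p, g2r, n_permutations=100)
        u = (np.arange(1, 5)) / 1000.0
        expected = min(beta_tail_binomial(u[k - 1], k, 4) for k in range(1, 5))
        assert out["rho"].iloc[0] == pytest.approx(expected, abs=1e-6)

    def test_invariant_to_nonmember_rearrangement(self):
        # members occupy the best ranks; shuffling how non-members fill the
        # worse ranks must not change rho
        n = 500
        base = np.arange(n) / n + 1e-6
        members = [f"g{i}" for i in range(5)]
        others = [f"x{i}" for i in range(n - 5)]
        g2r = pd.Series({g: "r" for g in members})
        rng = np.random.default_rng(3)
        rhos = []
        for _ in range(3):
            vals = np.concatenate([base[:5], rng.permutation(base[5:])])
            p = pd.Series(vals, index=members + others)
            rhos.append(
                sa.aggregate_region_rra(p, g2r, n_permutations=50)["rho"].iloc[0]
            )
        assert rhos[0] == rhos[1] == rhos[2]

    def test_no_guide_below_alpha0_gives_rho_one(self):
        p = self._pvals(100, seed=2)
        worst = p.sort_values().index[-1]
        out = sa.aggregate_region_rra(p, pd.Series({worst: "r"}), n_permutations=50)
        assert out["rho"].iloc[0] == 1.0

    def test_permutation_pvalues_uniform_under_null(self):
        # calibration is checked on the untruncated statistic (alpha0 = 1);
        # the alpha0 cutoff adds a conservative atom of rho = 1 regions
        n_regions, m = 250, 4
        p = self._pvals(n_regions * m, seed=5)
        g2r = pd.Series(
            {f"g{i}": f"r{i // m}" for i in range(n_regions * m)}
        )
        out = sa.aggregate_region_rra(p, g2r, alpha0=1.0, n_permutations=1000, seed=6)
        ks = stats.kstest(out["p_perm"], "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# differential and secondary hits
# ---------------------------------------------------------------------------

def _per_rep(guides, lfcs, cl, reps=3, day=22):
    rows = []
    for g, base in zip(guides, lfcs):
        for r in range(1, reps + 1):
            rows.append((g, cl, r, day, base[r - 1]))
    return pd.DataFrame(rows, columns=["guide_id", "cell_line", "replicate", "day", "lfc"])


class TestDifferential:
    def test_identical_tables_nothing_differential(self):
        guides = [f"g{i}" for i in range(20)]
        lfcs = [(0.1, -0.1, 0.0)] * 20
        a = _per_rep(guides, lfcs, "MPM1")
        b = _per_rep(guides, lfcs, "UM1")
        out = sa.differential_lineage(a, b)
        assert not out["differential"].any()

    def test_planted_differential_guides_recovered(self):
        rng = np.random.default_rng(9)
        n, k = 5000, 50
        guides = [f"g{i}" for i in range(n)]
        a_lfc, b_lfc = [], []
        for i in range(n):
            mu = -3.0 if i < k else 0.0
            a_lfc.append(tuple(mu + rng.normal(0, 0.1, 3)))
            b_lfc.append(tuple(rng.normal(0, 0.1, 3)))
        out = sa.differential_lineage(
            _per_rep(guides, a_lfc, "MPM1"), _per_rep(guides, b_lfc, "UM1")
        )
        hit = out[out["differential"]]
        planted = {f"g{i}" for i in range(k)}
        assert len(planted & set(hit["guide_id"])) >= 45
        assert (hit[hit["guide_id"].isin(planted)]["label"] == "MPM1").all()

    def test_bh_monotone_in_raw_p_order(self):
        rng = np.random.default_rng(10)
        p = rng.random(200)
        adj = sa.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_universe_mismatch_error(self):
        a = _per_rep(["g1"], [(0, 0, 0)], "MPM1")
        b = _per_rep(["g2"], [(0, 0, 0)], "UM1")
        with pytest.raises(ValueError, match="universe"):
            sa.differential_lineage(a, b)


class TestCallHitsSecondary:
    LINEAGES = {"MPM1": "MPM", "MPM2": "MPM", "UM1": "UM", "UM2": "UM"}

    def _fitness(self, spec):
        rows = []
        for rid, scoring in spec.items():
            for cl in self.LINEAGES:
                if cl in scoring:
                    rows.append((rid, cl, -0.1, 0.001))
                else:
                    rows.append((rid, cl, 0.01, 0.6))
        return pd.DataFrame(rows, columns=["union_id", "cell_line", "alpha", "p"])

    def test_categories(self):
        fitness = self._fitness(
            {
                "all4": {"MPM1", "MPM2", "UM1", "UM2"},
                "three": {"MPM1", "MPM2", "UM1"},
                "mpm_only": {"MPM1", "MPM2"},
                "um_only": {"UM1", "UM2"},
                "one": {"MPM1"},
                "split": {"MPM1", "UM1"},
                "none": set(),
            }
        )
        out = sa.call_hits_secondary(fitness, self.LINEAGES).set_index("union_id")
        assert out.loc["all4", "category"] == "common"
        assert out.loc["three", "category"] == "common"
        assert out.loc["mpm_only", "category"] == "lineage-MPM"
        assert out.loc["um_only", "category"] == "lineage-UM"
        assert out.loc["one", "category"] == "none"
        assert out.loc["split", "category"] == "none"
        assert out.loc["none", "category"] == "none"

    def test_negative_alpha_required(self):
        fitness = pd.DataFrame(
            [("r", cl, 0.2, 0.0001) for cl in self.LINEAGES],
            columns=["union_id", "cell_line", "alpha", "p"],
        )
        out = sa.call_hits_secondary(fitness, self.LINEAGES)
        assert out["category"].iloc[0] == "none"

    def test_missing_model_error(self):
        fitness = self._fitness({"r": {"MPM1"}})
        with pytest.raises(ValueError, match="missing"):
            sa.call_hits_secondary(
                fitness[fitness["cell_line"] != "UM2"], self.LINEAGES
            )
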