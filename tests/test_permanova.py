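"""The sequential-SS PERMANOVA engine, its permutation inference, and the
dispersion / batch-similarity tests."""

import itertools
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from permapart import (
    DesignSpec,
    DistanceMatrix,
    Term,
    ValidationError,
    bray_curtis,
    fit_permanova,
    gower_center,
    permdisp,
    screen_variable,
    within_batch_similarity_test,
)

from conftest import euclid_dm, make_metadata


class TestGowerCenter:
    def test_zero_distances_give_zero_g(self):
        dm = DistanceMatrix(np.zeros((4, 4)), list("abcd"), "euclidean")
        g = gower_center(dm)
        assert np.abs(g).max() == 0.0

    def test_two_group_hand_case(self):
        # 4 points, within-group d=0, between-group d=1 (groups of 2):
        # SS_total = (1/4) * (4 pairs at d=1) = 1
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(d, list("abcd"), "euclidean")
        g = gower_center(dm)
        assert np.trace(g) == pytest.approx(1.0, abs=1e-12)
        assert np.abs(g.sum(axis=0)).max() < 1e-10  # row sums zero

    def test_trace_identity_on_random_matrices(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            y = rng.random((8, 3))
            dm = euclid_dm(y)
            g = gower_center(dm)
            d = dm.values
            brute = sum(d[i, j] ** 2 for i in range(8) for j in range(i + 1, 8)) / 8
            assert np.trace(g) == pytest.approx(brute, rel=1e-10)


class TestFitPermanova:
    def test_perfect_two_group_separation(self):
        d = np.ones((4, 4)) - np.eye(4)
        d[0, 1] = d[1, 0] = 0.0
        d[2, 3] = d[3, 2] = 0.0
        dm = DistanceMatrix(d, [f"s{i}" for i in range(4)], "euclidean")
        md = make_metadata(4, g=["a", "a", "b", "b"])
        res = fit_permanova(dm, md, DesignSpec.from_names([], ["g"]), B=0)
        assert res.r2("g") == pytest.approx(1.0, abs=1e-10)
        assert res.residual_ss == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_design(self):
        rng = np.random.default_rng(0)
        dm = euclid_dm(rng.random((6, 2)))
        md = make_metadata(6)
        res = fit_permanova(dm, md, DesignSpec([]), B=0)
        assert res.residual_ss == pytest.approx(res.total_ss, rel=1e-12)
        assert len(res.terms) == 0

    def test_r2_equals_anova_eta_squared_for_euclidean(self):
        # single-factor distance R2 must equal classical eta2 summed over
        # coordinates when the distance is Euclidean
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(12, 30))
            y = rng.normal(size=(n, int(rng.integers(2, 6))))
            g = rng.choice(list("abc"), n)
            md = make_metadata(n, g=g)
            res = fit_permanova(euclid_dm(y), md, DesignSpec.from_names([], ["g"]), B=0)
            ss_tot = ((y - y.mean(0)) ** 2).sum()
            ss_b = sum(
                (g == lev).sum() * ((y[g == lev].mean(0) - y.mean(0)) ** 2).sum()
                for lev in set(g)
            )
            assert res.r2("g") == pytest.approx(ss_b / ss_tot, abs=1e-8)

    def test_f_matches_skbio_single_factor(self):
        import skbio

        rng = np.random.default_rng(2)
        y = rng.normal(size=(20, 4))
        g = rng.choice(["u", "v"], 20)
        ids = [f"s{i}" for i in range(20)]
        md = make_metadata(20, g=g)
        res = fit_permanova(euclid_dm(y, ids), md, DesignSpec.from_names([], ["g"]), B=0)
        sk = skbio.stats.distance.permanova(
            skbio.DistanceMatrix(euclid_dm(y, ids).values, ids),
            pd.Series(g, index=ids, name="g"),
            permutations=9,
        )
        assert res.terms.loc["g", "F"] == pytest.approx(sk["test statistic"], rel=1e-10)

    def test_exact_enumeration_p_small_n(self):
        # with every non-identity permutation supplied, the +1/+1 p-value
        # equals the exact enumeration fraction #{F* >= F}/n! (identity incl.)
        rng = np.random.default_rng(3)
        y = rng.normal(size=(6, 2))
        y[:3] += 1.5
        md = make_metadata(6, g=["a"] * 3 + ["b"] * 3)
        perms = np.array([p for p in itertools.permutations(range(6))
                          if p != tuple(range(6))])
        dm = euclid_dm(y)
        res = fit_permanova(dm, md, DesignSpec.from_names([], ["g"]), permutations=perms)
        # brute-force enumeration with an independent R2-based statistic
        d2 = dm.values**2
        g_arr = np.array(["a"] * 3 + ["b"] * 3)
        f_obs = _brute_f(y, g_arr)
        count = sum(
            _brute_f(y[list(p)], g_arr) >= f_obs - 1e-12
            for p in itertools.permutations(range(6))
        )
        assert res.p("g") == pytest.approx(count / 720, abs=1e-12)

    def test_sequential_ss_matches_vegan_adonis2(self, tmp_path):
        # independent oracle: vegan's adonis2 sequential decomposition
        if shutil.which("Rscript") is None:
            pytest.skip("Rscript unavailable")
        rng = np.random.default_rng(7)
        x = rng.normal(size=30)
        g = np.repeat(["a", "b", "c"], 10)
        y = np.abs(rng.normal(size=(30, 5)))
        p = (y.T / y.sum(axis=1)).T
        np.savetxt(tmp_path / "P.tsv", p, delimiter="\t")
        pd.DataFrame({"g": g, "x": x}).to_csv(tmp_path / "meta.tsv", sep="\t", index=False)
        script = tmp_path / "oracle.R"
        script.write_text(
            "library(vegan)\n"
            f"P <- as.matrix(read.table('{tmp_path}/P.tsv'))\n"
            f"m <- read.table('{tmp_path}/meta.tsv', header=TRUE)\n"
            "m$g <- factor(m$g)\n"
            "d <- vegdist(P, method='bray')\n"
            "r <- adonis2(d ~ x + g, data=m, permutations=0, by='terms')\n"
            "cat(sprintf('%.12f\\n', r$SumOfSqs))\n"
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True,
                             timeout=240)
        assert out.returncode == 0, out.stderr
        ss_x, ss_g, ss_resid, ss_total = [float(v) for v in out.stdout.split()]
        ids = [f"s{i}" for i in range(30)]
        md = make_metadata(30, g=g, x=x)
        dm = bray_curtis(p.T, ids)
        res = fit_permanova(dm, md, DesignSpec.from_names([], ["x", "g"]), B=0)
        assert res.terms.loc["x", "SS"] == pytest.approx(ss_x, abs=1e-8)
        assert res.terms.loc["g", "SS"] == pytest.approx(ss_g, abs=1e-8)
        assert res.residual_ss == pytest.approx(ss_resid, abs=1e-8)
        assert res.total_ss == pytest.approx(ss_total, abs=1e-8)

    def test_ss_decomposition_and_total_order_invariance(self):
        rng = np.random.default_rng(5)
        n = 40
        y = rng.normal(size=(n, 4))
        md = make_metadata(
            n,
            a=rng.choice(["p", "q"], n),
            b=rng.choice(["x", "y", "z"], n),
            c=rng.normal(size=n),
        )
        dm = euclid_dm(y)
        r1 = fit_permanova(dm, md, DesignSpec.from_names([], ["a", "b", "c"]), B=0)
        r2 = fit_permanova(dm, md, DesignSpec.from_names([], ["c", "b", "a"]), B=0)
        for r in (r1, r2):
            total = r.terms["SS"].sum() + r.residual_ss
            assert total == pytest.approx(r.total_ss, rel=1e-8)
        assert r1.terms["SS"].sum() == pytest.approx(r2.terms["SS"].sum(), rel=1e-8)
        # per-term sequential SS depends on order
        assert r1.terms.loc["a", "SS"] != pytest.approx(r2.terms.loc["a", "SS"], rel=1e-3)

    def test_aliased_variable_gets_zero_df(self):
        rng = np.random.default_rng(6)
        n = 20
        g = rng.choice(["a", "b"], n)
        md = make_metadata(n, g=g, twin=g.copy())
        dm = euclid_dm(rng.normal(size=(n, 3)))
        res = fit_permanova(dm, md, DesignSpec.from_names([], ["g", "twin"]), B=0)
        assert res.terms.loc["twin", "df"] == 0
        assert np.isnan(res.terms.loc["twin", "F"])

    def test_missing_design_values_dropped(self):
        rng = np.random.default_rng(8)
        n = 12
        x = rng.normal(size=n)
        x[0] = np.nan
        md = make_metadata(n, x=x)
        dm = euclid_dm(rng.normal(size=(n, 2)))
        res = fit_permanova(dm, md, DesignSpec.from_names([], ["x"]), B=0)
        assert res.n == n - 1
        assert len(res.dropped_samples) == 1

    def test_n_too_small_rejected(self):
        rng = np.random.default_rng(9)
        md = make_metadata(4, g=["a", "b", "c", "d"])
        dm = euclid_dm(rng.normal(size=(4, 2)))
        with pytest.raises(ValidationError):
            fit_permanova(dm, md, DesignSpec.from_names([], ["g"]), B=0)


def _brute_f(y, groups):
    """One-way pseudo-F from scratch (Euclidean)."""
    n = len(y)
    ss_tot = ((y - y.mean(0)) ** 2).sum()
    ss_w = sum(((y[groups == g] - y[groups == g].mean(0)) ** 2).sum()
               for g in set(groups))
    k = len(set(groups))
    return ((ss_tot - ss_w) / (k - 1)) / (ss_w / (n - k))


class TestScreenVariable:
    def test_refuses_excluded_variable(self):
        rng = np.random.default_rng(0)
        md = make_metadata(10, v=rng.choice(["a", "b"], 10))
        md.exclude("v", "*", "too many missing")
        dm = euclid_dm(rng.normal(size=(10, 2)))
        with pytest.raises(ValidationError, match="excluded"):
            screen_variable(dm, md, "v")

    def test_refuses_confounder_as_variable(self):
        rng = np.random.default_rng(0)
        md = make_metadata(10, v=rng.choice(["a", "b"], 10))
        dm = euclid_dm(rng.normal(size=(10, 2)))
        with pytest.raises(ValidationError):
            screen_variable(dm, md, "v", confounders=["v"])

    def test_reports_sequential_values_after_confounder(self):
        rng = np.random.default_rng(1)
        n = 30
        md = make_metadata(n, conf=rng.normal(size=n), v=rng.choice(["a", "b"], n))
        dm = euclid_dm(rng.normal(size=(n, 3)))
        res = screen_variable(dm, md, "v", confounders=["conf"], B=49, seed=1)
        assert list(res.terms.index) == ["conf", "v"]
        assert 0 <= res.r2("v") <= 1


class TestPermdisp:
    def test_detects_doubled_dispersion(self):
        rng = np.random.default_rng(10)
        n = 60
        y = np.vstack([rng.normal(0, 1, (n // 2, 3)), rng.normal(0, 2.5, (n // 2, 3))])
        md = make_metadata(n, g=["tight"] * (n // 2) + ["wide"] * (n // 2))
        res = permdisp(euclid_dm(y), md, "g", B=199, seed=0)
        assert res.p < 0.05
        assert res.uneven

    def test_identical_points_reported_degenerate(self):
        d = np.zeros((6, 6))
        dm = DistanceMatrix(d, [f"s{i}" for i in range(6)], "euclidean")
        md = make_metadata(6, g=["a", "a", "a", "b", "b", "b"])
        res = permdisp(dm, md, "g", B=19, seed=0)
        assert res.p == 1.0
        assert not res.uneven
        assert "degenerate" in (res.warning or "")

    def test_singleton_level_dropped_with_warning(self):
        rng = np.random.default_rng(11)
        y = rng.normal(size=(9, 2))
        md = make_metadata(9, g=["a"] * 4 + ["b"] * 4 + ["lonely"])
        res = permdisp(euclid_dm(y), md, "g", B=19, seed=0)
        assert "lonely" in res.warning
        assert set(res.groups.unique()) == {"a", "b"}


class TestWithinBatchSimilarity:
    def test_pair_counting_two_batches_of_two(self):
        rng = np.random.default_rng(12)
        y = rng.normal(size=(4, 2))
        md = make_metadata(4, batch=["b1", "b1", "b2", "b2"])
        rec = within_batch_similarity_test(euclid_dm(y), md, "batch")
        assert rec["n_within_pairs"] == 2
        assert rec["n_between_pairs"] == 4

    def test_planted_batch_effect_lowers_within_distances(self):
        rng = np.random.default_rng(13)
        centers = {"b1": 0.0, "b2": 3.0, "b3": -3.0}
        batches = np.repeat(list(centers), 8)
        y = np.array([rng.normal(centers[b], 1, 2) for b in batches])
        md = make_metadata(24, batch=batches)
        rec = within_batch_similarity_test(euclid_dm(y), md, "batch")
        assert rec["median_within"] < rec["median_between"]
        assert rec["p"] < 0.01
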