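"""FDR, screening orchestration, covariate redundancy and family dyads."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from permapart import (
    DistanceMatrix,
    SampleMetadata,
    ValidationError,
    bh_fdr,
    family_dyad_analysis,
    screen_all,
    screen_interaction,
    spearman_matrix,
    stratified_screen,
    symmetric_uncertainty,
)

from conftest import euclid_dm, make_metadata


def _brute_bh(p):
    """Independent BH step-up: q_(i) = min_{j>=i} min(1, m p_(j) / j)."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        prev = min(prev, min(1.0, m * p[i] / rank_from_top))
        q[i] = prev
    return q


class TestBhFdr:
    def test_hand_stepup_example(self):
        assert np.allclose(bh_fdr([0.01, 0.04]), [0.02, 0.04])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.3, 0.3, 0.3]), [0.3, 0.3, 0.3])

    def test_single_pvalue_identity(self):
        assert bh_fdr([0.123])[0] == pytest.approx(0.123)

    def test_empty_vector(self):
        assert bh_fdr([]).size == 0

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 40))
    def test_matches_brute_force_stepup(self, seed, m):
        p = np.random.default_rng(seed).random(m)
        assert np.allclose(bh_fdr(p), _brute_bh(p), atol=1e-12)

    def test_q_at_least_p(self):
        p = np.random.default_rng(0).random(200)
        assert np.all(bh_fdr(p) >= p - 1e-12)


class TestSymmetricUncertainty:
    def _md_from(self, x, y):
        return make_metadata(len(x), x=x, y=y)

    def test_identical_binary_variables_give_one(self):
        x = ["a", "b"] * 10
        md = self._md_from(x, list(x))
        assert symmetric_uncertainty("x", "y", md) == pytest.approx(1.0, abs=1e-12)

    def test_independent_uniform_2x2_gives_zero(self):
        x = ["a", "a", "b", "b"] * 3
        y = ["u", "v", "u", "v"] * 3
        md = self._md_from(x, y)
        assert symmetric_uncertainty("x", "y", md) == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_dependent_2x2(self):
        # counts [[2,1],[1,2]]: plug-in MI = 0.0566330122651324 nats,
        # H1 = H2 = ln 2, SU = 2 MI / (2 ln 2) = 0.08170416594551036
        x = ["a", "a", "a", "b", "b", "b"]
        y = ["u", "u", "v", "u", "v", "v"]
        md = self._md_from(x * 2, y * 2)
        assert symmetric_uncertainty("x", "y", md) == pytest.approx(
            0.08170416594551036, abs=1e-10
        )

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(1)
        x = rng.choice(["a", "b", "c"], 60)
        y = rng.choice(["u", "v"], 60)
        md = self._md_from(x, y)
        assert symmetric_uncertainty("x", "y", md) == pytest.approx(
            symmetric_uncertainty("y", "x", md), abs=1e-12
        )

    def test_constant_variable_reported_missing(self):
        md = self._md_from(["a"] * 20, ["u", "v"] * 10)
        assert np.isnan(symmetric_uncertainty("x", "y", md))

    def test_numeric_variable_discretized(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        md = self._md_from(x, list(x))  # same values -> SU 1 after binning
        assert symmetric_uncertainty("x", "y", md) == pytest.approx(1.0, abs=1e-12)

    def test_too_few_observations_rejected(self):
        md = self._md_from(["a"] * 5, ["b"] * 5)
        with pytest.raises(ValidationError):
            symmetric_uncertainty("x", "y", md)


class TestSpearman:
    def test_monotone_and_reversed(self):
        md = make_metadata(10, a=np.arange(10.0), b=np.arange(10.0) ** 2,
                           c=-np.arange(10.0))
        out = spearman_matrix(md, ["a", "b", "c"])
        ab = out[(out.var1 == "a") & (out.var2 == "b")].iloc[0]
        ac = out[(out.var1 == "a") & (out.var2 == "c")].iloc[0]
        assert ab.rho == pytest.approx(1.0)
        assert ac.rho == pytest.approx(-1.0)
        assert ab.fair and ac.fair

    def test_boundary_rho_not_flagged(self):
        # construct a pair whose Spearman rho is below the strict 0.3 cutoff
        rng = np.random.default_rng(3)
        x = np.arange(50.0)
        y = rng.permutation(50).astype(float)
        md = make_metadata(50, a=x, b=y)
        out = spearman_matrix(md, ["a", "b"])
        row = out.iloc[0]
        assert row.fair == (abs(row.rho) > 0.3)


class TestScreenAll:
    def test_single_variable_q_equals_p(self):
        rng = np.random.default_rng(4)
        n = 24
        md = make_metadata(n, v=rng.choice(["a", "b"], n))
        dm = euclid_dm(rng.normal(size=(n, 3)))
        rep = screen_all({"3m": dm}, md, ["v"], B=49, seed=0)
        row = rep.table.iloc[0]
        assert row["q"] == pytest.approx(row["p"])

    def test_flags_pure_function_of_p_and_q(self):
        rng = np.random.default_rng(5)
        n = 30
        md = make_metadata(n, v=rng.choice(["a", "b"], n), w=rng.normal(size=n))
        dm = euclid_dm(rng.normal(size=(n, 3)))
        rep = screen_all({"3m": dm}, md, ["v", "w"], B=49, seed=0)
        recomputed = (rep.table["p"] < 0.05) & (rep.table["q"] < 0.1)
        assert (rep.table["significant"] == recomputed).all()


class TestInteraction:
    def test_constant_second_variable_refused(self):
        rng = np.random.default_rng(6)
        n = 24
        md = make_metadata(n, a=rng.choice(["x", "y"], n), b=["only"] * n)
        dm = euclid_dm(rng.normal(size=(n, 3)))
        with pytest.raises(ValidationError, match="aliased"):
            screen_interaction(dm, md, "a", "b", B=9, seed=0)

    def test_pure_interaction_detected_mains_nearly_null(self):
        rng = np.random.default_rng(7)
        n = 80
        a = rng.choice(["x", "y"], n)
        b = rng.choice(["u", "v"], n)
        y = rng.normal(size=(n, 3))
        cell = (a == "y") & (b == "v")  # effect only in one cell
        y[cell] += 2.0
        md = make_metadata(n, a=a, b=b)
        res = screen_interaction(euclid_dm(y), md, "a", "b", B=99, seed=0)
        assert res.p("a:b") < 0.05


class TestStratified:
    def test_single_stratum_equals_unstratified(self):
        rng = np.random.default_rng(8)
        n = 30
        md = make_metadata(n, v=rng.choice(["a", "b"], n), s=["one"] * n)
        dm = euclid_dm(rng.normal(size=(n, 3)))
        strat = stratified_screen(dm, md, "v", "s", B=49, seed=3)
        from permapart import screen_variable

        ref = screen_variable(dm, md, "v", B=49, seed=3)
        assert strat["one"].r2("v") == pytest.approx(ref.r2("v"), rel=1e-10)

    def test_effect_only_in_one_stratum(self):
        rng = np.random.default_rng(9)
        n = 120
        s = np.array(["A"] * 60 + ["B"] * 60)
        v = rng.choice(["x", "y"], n)
        y = rng.normal(size=(n, 3))
        y[(s == "A") & (v == "y")] += 2.0
        md = make_metadata(n, v=v, s=s)
        strat = stratified_screen(euclid_dm(y), md, "v", "s", B=199, seed=0)
        assert strat["A"].p("v") < 0.05
        assert strat["B"].p("v") > 0.05

    def test_tiny_stratum_skipped(self):
        rng = np.random.default_rng(10)
        n = 33
        s = np.array(["big"] * 30 + ["tiny"] * 3)
        v = np.concatenate([rng.choice(["a", "b", "c"], 30), ["a", "b", "c"]])
        md = make_metadata(n, v=v, s=s)
        strat = stratified_screen(euclid_dm(rng.normal(size=(n, 3))), md, "v", "s",
                                  B=9, seed=0)
        assert strat["tiny"] is None
        assert strat["big"] is not None


class TestFamilyDyads:
    def _dyad_md(self, n_fam, seed=0, shared=0.0):
        """n_fam families, one infant (3w) + one mother sample each."""
        rng = np.random.default_rng(seed)
        rows, ys = [], []
        for f in range(n_fam):
            u = rng.normal(0, 1, 3)
            for role, tp in (("infant", "3w"), ("mother", "parental")):
                sid = f"F{f}-{role}"
                rows.append({"sample_id": sid, "subject_id": sid,
                             "family_id": f"F{f}", "role": role, "timepoint": tp})
                ys.append(shared * u + rng.normal(0, 1, 3))
        tbl = pd.DataFrame(rows).set_index("sample_id")
        md = SampleMetadata(tbl)
        dm = euclid_dm(np.array(ys), list(tbl.index))
        return dm, md

    def test_two_family_counting(self):
        dm, md = self._dyad_md(5)
        rec = family_dyad_analysis(dm, md, "mother-infant", "3w")
        assert rec["n_within"] == 5
        assert rec["n_between"] == 5 * 4

    def test_insufficient_dyads_rejected(self):
        dm, md = self._dyad_md(3)
        with pytest.raises(ValidationError):
            family_dyad_analysis(dm, md, "mother-infant", "3w")

    def test_shared_family_component_detected(self):
        dm, md = self._dyad_md(40, seed=1, shared=1.5)
        rec = family_dyad_analysis(dm, md, "mother-infant", "3w")
        assert rec["median_within"] < rec["median_between"]
        assert rec["p"] < 0.01

    def test_independent_families_not_flagged(self):
        ps = []
        for s in range(10):
            dm, md = self._dyad_md(30, seed=100 + s, shared=0.0)
            ps.append(family_dyad_analysis(dm, md, "mother-infant", "3w")["p"])
        assert min(ps) > 0.001  # no systematic signal
        assert np.median(ps) > 0.1
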