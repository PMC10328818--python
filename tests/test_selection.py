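"""AICc and backward elimination of cumulative distance models."""

import numpy as np
import pandas as pd
import pytest

from permapart import (
    DesignSpec,
    ValidationError,
    aicc,
    backward_select,
    fit_permanova,
    pooled_model,
)
from permapart.types import SampleMetadata

from conftest import euclid_dm, make_metadata


class TestAicc:
    def test_hand_value_default_form(self):
        # 2*2 + 10*ln(1) + 2*2*3/7 = 4 + 12/7
        assert aicc(10, 2, 10.0) == pytest.approx(4 + 12 / 7, abs=1e-10)

    def test_hand_value_literal_form(self):
        # 2*2 + 10 + ln(1) + 12/7
        assert aicc(10, 2, 10.0, literal=True) == pytest.approx(14 + 12 / 7, abs=1e-10)

    def test_smaller_rss_always_better(self):
        assert aicc(50, 4, 5.0) < aicc(50, 4, 10.0)

    def test_singular_correction_rejected(self):
        with pytest.raises(ValidationError):
            aicc(5, 4, 1.0)


def _selection_problem(seed, n=150, n_true=2, n_null=4, effect=1.2):
    rng = np.random.default_rng(seed)
    cols = {}
    y = rng.normal(size=(n, 4))
    true_vars, null_vars = [], []
    for i in range(n_true):
        v = rng.choice(["a", "b"], n)
        y[v == "b", i % 4] += effect
        cols[f"true_{i}"] = v
        true_vars.append(f"true_{i}")
    for i in range(n_null):
        cols[f"null_{i}"] = rng.choice([f"L{j}" for j in range(6)], n)
        null_vars.append(f"null_{i}")
    cols["conf"] = rng.normal(size=n)
    md = make_metadata(n, **cols)
    return euclid_dm(y), md, true_vars, null_vars


class TestBackwardSelect:
    def test_recovers_true_terms_drops_nulls(self):
        dm, md, true_vars, null_vars = _selection_problem(0)
        trace = backward_select(dm, md, true_vars + null_vars, ["conf"], B=49, seed=0)
        final = set(trace.final_terms)
        assert set(true_vars) <= final
        assert not (set(null_vars) & final)
        assert "conf" in final  # confounders never droppable

    def test_all_null_candidates_reduced_to_confounders(self):
        dm, md, _, null_vars = _selection_problem(1, n_true=0, n_null=5)
        trace = backward_select(dm, md, null_vars, ["conf"], B=9, seed=0)
        assert trace.final_terms == ["conf"]

    def test_empty_candidates_zero_steps(self):
        dm, md, _, _ = _selection_problem(2, n_true=0, n_null=1)
        trace = backward_select(dm, md, [], ["conf"], B=9, seed=0)
        assert [s.action for s in trace.steps] == ["start", "stop"]

    def test_aliased_candidate_dropped_at_step_zero(self):
        rng = np.random.default_rng(3)
        n = 60
        g = rng.choice(["a", "b"], n)
        md = make_metadata(n, g=g, twin=g.copy())
        dm = euclid_dm(rng.normal(size=(n, 3)))
        trace = backward_select(dm, md, ["g", "twin"], [], B=9, seed=0)
        assert "twin" in trace.dropped

    def test_trace_replay_reproduces_decisions(self):
        dm, md, true_vars, null_vars = _selection_problem(4)
        trace = backward_select(dm, md, true_vars + null_vars, ["conf"], B=9, seed=0)
        assert trace.replay_ok()
        tf = trace.to_frame()
        assert (np.diff(tf["k"][tf["action"] != "stop"]) <= 0).all()

    def test_aicc_decreases_at_least_two_per_step(self):
        dm, md, true_vars, null_vars = _selection_problem(5)
        trace = backward_select(dm, md, true_vars + null_vars, ["conf"], B=9, seed=0)
        scores = [s.aicc for s in trace.steps if s.action != "stop"]
        assert all(a - b >= 2 - 1e-9 for a, b in zip(scores, scores[1:]))

    def test_null_multi_df_interaction_dropped_mains_kept(self):
        # mains planted, interaction absent; the 4-df null interaction is
        # removable under the >=2-unit AICc rule, the mains are not
        rng = np.random.default_rng(6)
        n = 150
        a = rng.choice(["x", "y", "z"], n)
        b = rng.choice(["u", "v", "w"], n)
        y = rng.normal(size=(n, 3))
        y[a == "y", 0] += 1.5
        y[b == "v", 1] += 1.5
        md = make_metadata(n, a=a, b=b)
        trace = backward_select(euclid_dm(y), md, ["a", "b", ("a", "b")], [], B=9, seed=0)
        final = set(trace.final_terms)
        assert "a:b" not in final
        assert {"a", "b"} <= final

    def test_interaction_hierarchy_preserved(self):
        # interaction planted: final model keeps both mains alongside it
        rng = np.random.default_rng(16)
        n = 150
        a = rng.choice(["x", "y"], n)
        b = rng.choice(["u", "v"], n)
        y = rng.normal(size=(n, 3))
        y[(a == "y") & (b == "v")] += 2.0
        md = make_metadata(n, a=a, b=b)
        trace = backward_select(euclid_dm(y), md, ["a", "b", ("a", "b")], [], B=9, seed=0)
        final = set(trace.final_terms)
        if "a:b" in final:
            assert {"a", "b"} <= final

    def test_final_model_r2_sums_below_one(self):
        dm, md, true_vars, null_vars = _selection_problem(7)
        trace = backward_select(dm, md, true_vars + null_vars, ["conf"], B=19, seed=0)
        assert trace.final.terms["R2"].sum() <= 1.0 + 1e-9


class TestPooledModel:
    def _longitudinal(self, seed, subject_sd, n_subj=40, n_tp=3):
        rng = np.random.default_rng(seed)
        rows, ys = [], []
        for s in range(n_subj):
            u = rng.normal(0, subject_sd, 3)
            for t in range(n_tp):
                sid = f"S{s}-t{t}"
                rows.append({"sample_id": sid, "subject_id": f"S{s}",
                             "family_id": f"S{s}", "role": "infant",
                             "timepoint": f"tp{t}",
                             "reads": float(rng.integers(5000, 20000))})
                ys.append(u + 0.5 * t + rng.normal(0, 1, 3))
        tbl = pd.DataFrame(rows).set_index("sample_id")
        md = SampleMetadata(tbl)
        return euclid_dm(np.array(ys), list(tbl.index)), md

    def test_strong_subject_effect_dominates_age(self):
        dm, md = self._longitudinal(0, subject_sd=2.5)
        res = pooled_model(dm, md, B=0)
        assert res.r2("subject_id") > res.r2("timepoint")

    def test_null_subject_effect_near_df_expectation(self):
        dm, md = self._longitudinal(1, subject_sd=0.0)
        res = pooled_model(dm, md, B=0)
        # with no subject signal, R2 is close to its df share of what is
        # left after the confounder
        df_share = res.terms.loc["subject_id", "df"] / (res.n - 1)
        assert abs(res.r2("subject_id") - df_share) < 0.1

    def test_single_timepoint_refused(self):
        dm, md = self._longitudinal(2, subject_sd=1.0, n_tp=1)
        with pytest.raises(ValidationError):
            pooled_model(dm, md, B=0)
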