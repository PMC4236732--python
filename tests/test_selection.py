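"""Two-round effect selection: forward AICc stepwise and p-ordered pruning."""

import numpy as np
import pandas as pd
import pytest

from chlamydoe.factors import EffectTerm, enumerate_candidate_effects
from chlamydoe.regression import ModelSpec, build_model_matrix
from chlamydoe.selection import SelectionConfig, backward_prune, run_two_round, stepwise_forward
from chlamydoe.simulate import NoiseModel, generate_responses


def _linear(*names):
    return [EffectTerm("linear", (n,)) for n in names]


class TestStepwiseForward:
    def test_heredity_on_interaction_only_signal(self, design):
        """y driven purely by acetate x ammonium still pulls in the parents."""
        data = design.factor_data()
        rng = np.random.default_rng(0)
        ac = data["acetate"] - data["acetate"].mean()
        am = data["ammonium"] - data["ammonium"].mean()
        y = 5.0 + 4.0 * (ac * am).to_numpy() + rng.normal(0, 0.1, len(data))
        trace = stepwise_forward(design, y)
        names = set(trace.final_spec.term_names)
        assert {"acetate", "ammonium", "acetate:ammonium"} <= names

    def test_pure_noise_selects_little(self, design):
        sizes = []
        for seed in range(50):
            y = np.random.default_rng(seed).normal(0, 1, design.n_runs)
            sizes.append(len(stepwise_forward(design, y).final_spec.terms))
        assert np.median(sizes) <= 2

    def test_recovers_linear_truth(self, design, models):
        """MA_CYT truth (acetate + light + ammonium) at its fitted noise."""
        hits = 0
        for seed in range(60):
            resp = generate_responses(design, {"MA_CYT": models["MA_CYT"]},
                                      NoiseModel(sigma={"MA_CYT": 3.5}, seed=seed,
                                                 missing_runs={}))
            trace = stepwise_forward(design, resp["MA_CYT"].to_numpy())
            if {"acetate", "light", "ammonium"} <= set(trace.final_spec.term_names):
                hits += 1
        assert hits / 60 >= 0.85

    def test_aicc_non_increasing_along_adds(self, design, models):
        resp = generate_responses(design, models, NoiseModel(seed=5))
        trace = stepwise_forward(design, resp["P800"].to_numpy())
        adds = [s.aicc for s in trace.steps if s.action == "add"]
        assert all(b <= a + 1e-9 for a, b in zip(adds, adds[1:]))

    def test_deterministic(self, design, models):
        resp = generate_responses(design, models, NoiseModel(seed=2))
        y = resp["CR"].to_numpy()
        t1 = stepwise_forward(design, y)
        t2 = stepwise_forward(design, y)
        assert t1.final_spec.term_names == t2.final_spec.term_names
        assert [s.aicc for s in t1.steps] == [s.aicc for s in t2.steps]


class TestBackwardPrune:
    def test_strong_model_nothing_removed(self, design):
        """Every term essential: the first tentative removal is rejected."""
        data = design.factor_data()
        rng = np.random.default_rng(1)
        y = (2.0 + 8.0 * data["acetate"] + 0.05 * data["light"]
             - 0.9 * data["ammonium"]).to_numpy() + rng.normal(0, 0.05, len(data))
        spec = ModelSpec("y", _linear("acetate", "light", "ammonium"))
        trace = backward_prune(design, y, spec)
        assert [s.action for s in trace.steps] == ["stop"]
        assert set(trace.final_spec.term_names) == {"acetate", "light", "ammonium"}

    def test_noise_term_usually_pruned(self, design):
        data = design.factor_data()
        removed = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            y = (1.0 + 9.0 * data["acetate"] - 0.5 * data["ammonium"]).to_numpy()
            y = y + rng.normal(0, 1.0, len(data))
            spec = ModelSpec("y", _linear("acetate", "ammonium", "nitrate"))
            trace = backward_prune(design, y, spec)
            if "nitrate" not in trace.final_spec.term_names:
                removed += 1
        assert removed / n_seeds >= 0.8

    def test_heredity_repair_restores_parent(self, design):
        data = design.factor_data()
        rng = np.random.default_rng(3)
        ac = data["acetate"] - data["acetate"].mean()
        am = data["ammonium"] - data["ammonium"].mean()
        y = 3.0 + 5.0 * (ac * am).to_numpy() + 2.0 * am.to_numpy()
        y = y + rng.normal(0, 0.1, len(data))
        # round-1 spec stranded: interaction present, acetate parent absent
        spec = ModelSpec("y", [EffectTerm("interaction", ("acetate", "ammonium")),
                               EffectTerm("linear", ("ammonium",))])
        trace = backward_prune(design, y, spec)
        assert "acetate" in trace.final_spec.term_names

    def test_relaxed_floor_for_weak_round1_fit(self, design):
        """When round-1 R2 < 0.60, the floor drops to that R2 minus slack."""
        data = design.factor_data()
        rng = np.random.default_rng(7)
        y = (1.0 + 2.0 * data["acetate"]).to_numpy() + rng.normal(0, 1.5, len(data))
        spec = ModelSpec("y", _linear("acetate", "light"))
        trace = backward_prune(design, y, spec, config=SelectionConfig(slack=0.05))
        # pruning proceeded instead of stopping immediately at R2 < 0.60
        assert trace.final_spec.term_names  # still a non-empty model
        stop = [s for s in trace.steps if s.action == "stop"]
        assert stop, "trace must end with an explicit stop or exhaust terms"


class TestTwoRound:
    def test_constant_response_flagged(self, design):
        responses = pd.DataFrame({"run_id": design.frame["run_id"],
                                  "FLAT": np.ones(design.n_runs)})
        with pytest.warns(UserWarning, match="constant"):
            out = run_two_round(design, responses)
        assert out["FLAT"].skipped == "constant response"
        assert out["FLAT"].trace1.final_spec.terms == []

    def test_short_response_skipped(self, design):
        y = np.full(design.n_runs, np.nan)
        y[:4] = [1.0, 2.0, 1.5, 2.5]
        responses = pd.DataFrame({"run_id": design.frame["run_id"], "SPARSE": y})
        with pytest.warns(UserWarning, match="skipped"):
            out = run_two_round(design, responses)
        assert out["SPARSE"].round2 is None

    def test_round2_subset_of_round1_plus_parents(self, design, models):
        resp = generate_responses(design, models, NoiseModel(seed=11))
        out = run_two_round(design, resp)
        for sel in out.values():
            if sel.trace2 is None:
                continue
            r1 = set(sel.trace1.final_spec.term_names)
            parents = {p.name for t in sel.trace2.final_spec.terms for p in t.parents()}
            assert set(sel.trace2.final_spec.term_names) <= r1 | parents

    def test_accepted_model_meets_stopping_criteria(self, design, models):
        resp = generate_responses(design, models, NoiseModel(seed=13))
        config = SelectionConfig()
        out = run_two_round(design, resp, config)
        for sel in out.values():
            if sel.round2 is None or sel.round1 is None:
                continue
            floor = (config.r2_floor if sel.round1.rsquared >= config.r2_floor
                     else sel.round1.rsquared - config.slack)
            assert sel.round2.rsquared >= floor - 1e-9
            lof = sel.round2.lack_of_fit
            if lof.available:
                assert lof.pvalue > config.alpha

    def test_missing_rows_recenter(self, design, models):
        """CR's centering constants come from its 40 surviving rows."""
        resp = generate_responses(design, models, NoiseModel(seed=4))
        out = run_two_round(design, resp)
        sel = out["CR"]
        if sel.round2 is None:
            pytest.skip("no CR model selected at this seed")
        kept = resp["CR"].notna()
        expected = design.factor_data().loc[kept, "acetate"].mean()
        got = sel.round2.model.centers["acetate"]
        assert got == pytest.approx(expected)
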