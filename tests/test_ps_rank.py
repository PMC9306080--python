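"""Protein-space classifier, beta score and windowed ranking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahiot.ps_rank import (PSModelConfig, ThresholdWindow, fit_ps_model,
                           rank_hits, score_beta)

SMALL_CFG = dict(layers=(32, 16, 2), epochs=30, folds=3)


class TestPSModelConfig:
    def test_defaults_match_protocol(self):
        cfg = PSModelConfig()
        assert cfg.layers == (400, 200, 400, 2)
        assert cfg.activation == "tanh"
        assert (cfg.epochs, cfg.folds) == (50, 5)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError, match="grid"):
            PSModelConfig(momentum_grid=())

    def test_grid_points_cartesian(self):
        cfg = PSModelConfig(momentum_grid=(0.5, 0.9), input_dropout_grid=(0.0, 0.1))
        assert len(cfg.grid_points()) == 4


class TestFitPSModel:
    def _data(self, n=60, width=80, seed=0, effect=4.0):
        from ahiot.synthetic import gen_fingerprint_dataset

        return gen_fingerprint_dataset(n=n, k_informative=8, effect=effect,
                                       seed=seed, width=width, background_cols=20)

    def test_probabilities_sum_to_one(self):
        X, y, _ = self._data()
        model = fit_ps_model(X, y, PSModelConfig(seed=0, **SMALL_CFG))
        proba = model.net.predict_proba(X / model.scale)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_single_grid_point_selected_trivially(self):
        X, y, _ = self._data()
        model = fit_ps_model(X, y, PSModelConfig(seed=0, **SMALL_CFG))
        assert model.best_point == {"momentum": 0.9, "rate_annealing": 1e-6,
                                    "input_dropout": 0.0}
        assert len(model.cv_results) == 1

    def test_grid_selection_prefers_highest_cv_auc(self):
        X, y, _ = self._data(seed=3)
        cfg = PSModelConfig(seed=3, momentum_grid=(0.0, 0.9), **SMALL_CFG)
        model = fit_ps_model(X, y, cfg)
        best_row = model.cv_results.sort_values(
            ["cv_auc", "cv_accuracy", "grid_index"],
            ascending=[False, False, True]).iloc[0]
        assert model.best_point["momentum"] == best_row["momentum"]

    def test_single_class_rejected(self):
        X, y, _ = self._data()
        with pytest.raises(ValueError, match="classes"):
            fit_ps_model(X, np.ones_like(y), PSModelConfig(**SMALL_CFG))

    def test_negative_counts_rejected(self):
        X, y, _ = self._data()
        X = X.astype(float)
        X[0, 0] = -1
        with pytest.raises(ValueError, match="non-negative"):
            fit_ps_model(X, y, PSModelConfig(**SMALL_CFG))

    def test_informative_signal_learned(self):
        X, y, _ = self._data(n=80, seed=5)
        model = fit_ps_model(X, y, PSModelConfig(seed=5, **SMALL_CFG))
        assert model.cv_results["cv_auc"].iloc[0] >= 0.85


class TestScoreBeta:
    @pytest.mark.parametrize("f,d,expected", [(0.75, 11, 11.75), (0.0, 0, 0.0), (1.0, 9, 10.0)])
    def test_worked_values(self, f, d, expected):
        assert score_beta(f, d) == expected

    @given(f=st.floats(0, 1), d=st.integers(0, 30))
    @settings(max_examples=60, deadline=None)
    def test_monotone_in_both_arguments(self, f, d):
        assert score_beta(f, d + 1) > score_beta(f, d)
        assert score_beta(1.0, d) >= score_beta(f, d)  # equality only at float resolution
        # an integer step in d_i dominates any probability difference
        # (strictly, for any probability below the f = 1 boundary)
        assert score_beta(0.0, d + 1) >= score_beta(f, d)
        if f < 1:
            assert score_beta(0.0, d + 1) > score_beta(f, d)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_beta(1.2, 3)
        with pytest.raises(ValueError):
            score_beta(0.5, -1)


class TestRankHits:
    def test_worked_candidate_set(self):
        hits = rank_hits({"A": 0.9, "B": 0.8, "C": 0.7},
                         {"A": 10, "B": 13, "C": 9}, ThresholdWindow(9, 12))
        ranked = [h for h in hits if h.rank is not None]
        assert [h.molecule_id for h in ranked] == ["A", "C"]
        assert [h.beta for h in ranked] == pytest.approx([10.9, 9.7])
        out = {h.molecule_id: h for h in hits if h.rank is None}
        assert set(out) == {"B"} and not out["B"].passed_window

    def test_all_outside_window_flagged(self):
        hits = rank_hits({"A": 0.9, "B": 0.8}, {"A": 1, "B": 20}, ThresholdWindow(9, 12))
        assert all(h.rank is None and not h.passed_window for h in hits)

    def test_equal_beta_tie_broken_by_id(self):
        hits = rank_hits({"b": 0.5, "a": 0.5}, {"a": 10, "b": 10}, ThresholdWindow(9, 12))
        assert [h.molecule_id for h in hits] == ["a", "b"]

    def test_truth_mode_keeps_only_true_positives(self):
        hits = rank_hits({"tp": 0.9, "fp": 0.8, "fn": 0.4},
                         {"tp": 10, "fp": 10, "fn": 10},
                         ThresholdWindow(9, 12),
                         truth={"tp": 1, "fp": 0, "fn": 1})
        assert [h.molecule_id for h in hits] == ["tp"]

    def test_missing_profile_named(self):
        with pytest.raises(ValueError, match="B"):
            rank_hits({"A": 0.9, "B": 0.8}, {"A": 10}, ThresholdWindow(9, 12))

    def test_unbounded_window_equals_plain_beta_sort(self, rng):
        ids = [f"m{i}" for i in range(30)]
        preds = {i: float(p) for i, p in zip(ids, rng.uniform(0.5, 1.0, 30))}
        profs = {i: int(d) for i, d in zip(ids, rng.integers(0, 15, 30))}
        hits = rank_hits(preds, profs, ThresholdWindow(0, 10**6))
        got = [h.molecule_id for h in hits]
        oracle = sorted(ids, key=lambda i: (-(preds[i] + profs[i]), -preds[i], i))
        assert got == oracle
        assert sorted(h.rank for h in hits) == list(range(1, 31))

    def test_window_boundaries_inclusive(self):
        hits = rank_hits({"lo": 0.9, "hi": 0.9, "out": 0.9},
                         {"lo": 9, "hi": 12, "out": 13}, ThresholdWindow(9, 12))
        passed = {h.molecule_id for h in hits if h.passed_window}
        assert passed == {"lo", "hi"}
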