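"""RMSE/PCC/MAE and fit / LOO / external evaluation semantics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from foldbench.datasets import PredictionTable
from foldbench.model import fit_loglinear
from foldbench.simulate import GeneratorConfig, generate_dataset
from foldbench.validation import (
    EvaluationReport,
    UndefinedCorrelationError,
    evaluate_external,
    evaluate_fit,
    loo_cv,
    mae,
    pcc,
    rmse,
)

from conftest import make_dataset


class TestMetrics:
    def test_rmse_hand_values(self):
        assert rmse([1, 2, 3], [1, 2, 3]) == 0.0
        assert rmse([1, 2, 3], [2, 2, 2]) == pytest.approx(math.sqrt(2 / 3), abs=1e-12)
        assert rmse([0.0], [3.0]) == 3.0

    def test_mae_hand_values(self):
        assert mae([1, 2, 3], [1, 2, 3]) == 0.0
        assert mae([1, 2, 3], [2, 2, 2]) == pytest.approx(2 / 3, abs=1e-12)
        assert mae([0.0], [3.0]) == 3.0

    def test_pcc_affine_invariance_and_sign(self):
        obs = [1.0, 2.0, 4.0]
        assert pcc(obs, [2 * v + 1 for v in obs]) == pytest.approx(1.0, abs=1e-12)
        assert pcc(obs, [-v for v in obs]) == pytest.approx(-1.0, abs=1e-12)

    def test_pcc_hand_value(self):
        assert pcc([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5, abs=1e-12)

    def test_pcc_undefined_raised_not_zeroed(self):
        with pytest.raises(UndefinedCorrelationError):
            pcc([1, 1, 1], [1, 2, 3])
        with pytest.raises(UndefinedCorrelationError):
            pcc([1.0], [2.0])

    def test_length_mismatch_and_empty_rejected(self):
        with pytest.raises(ValueError):
            rmse([1, 2], [1])
        with pytest.raises(ValueError):
            mae([], [])

    @settings(max_examples=100, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(-50, 50), st.floats(-50, 50)), min_size=1, max_size=30
        )
    )
    def test_rmse_dominates_mae(self, pairs):
        obs = [p[0] for p in pairs]
        pred = [p[1] for p in pairs]
        assert rmse(obs, pred) >= mae(obs, pred) - 1e-12


class TestEvaluationReport:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            EvaluationReport(mode="fit", n=3, rmse=1.0, pcc=None, mae=2.0)
        with pytest.raises(ValueError):
            EvaluationReport(mode="bogus", n=3, rmse=1.0, pcc=0.5, mae=0.5)

    def test_undefined_pcc_displayed_as_flag(self):
        rep = EvaluationReport(mode="fit", n=3, rmse=1.0, pcc=None, mae=0.5)
        assert "undef" in str(rep)


class TestEvaluateFit:
    def test_noiseless_line_perfect(self):
        lengths = [40, 80, 160, 320]
        ds = make_dataset(
            "line",
            [(f"P{i}", L, 10.0 - 3.0 * math.log(L)) for i, L in enumerate(lengths)],
        )
        res = fit_loglinear(ds)
        rep = evaluate_fit(res, ds)
        assert rep.mode == "fit"
        assert rep.rmse == pytest.approx(0.0, abs=1e-9)
        assert rep.pcc == pytest.approx(1.0, abs=1e-9)

    def test_fit_rmse_equals_residual_rms(self, toy_dataset):
        res = fit_loglinear(toy_dataset)
        rep = evaluate_fit(res, toy_dataset)
        assert rep.rmse == pytest.approx(res.rmse_fit, abs=1e-12)


def leverage_loo_oracle(lengths, ln_kf):
    """Closed-form LOO via the hat-matrix identity e_(i) = e_i / (1 - h_i)."""
    x = np.log(np.asarray(lengths, dtype=float))
    y = np.asarray(ln_kf, dtype=float)
    n = len(x)
    xbar = x.mean()
    sxx = np.sum((x - xbar) ** 2)
    a1 = np.sum((x - xbar) * (y - y.mean())) / sxx
    a0 = y.mean() - a1 * xbar
    resid = y - (a0 + a1 * x)
    h = 1.0 / n + (x - xbar) ** 2 / sxx
    return resid / (1.0 - h)


class TestLOO:
    def test_refit_loo_matches_leverage_identity_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = int(rng.integers(6, 40))
            lengths = rng.integers(40, 400, size=n)
            y = 25.0 - 5.0 * np.log(lengths) + rng.normal(0, 2.5, size=n)
            ds = make_dataset(
                "r", [(f"{i:04d}", int(L), float(v)) for i, (L, v) in enumerate(zip(lengths, y))]
            )
            rep = loo_cv(ds)
            loo_resid = leverage_loo_oracle(lengths, y)
            assert rep.rmse == pytest.approx(
                float(np.sqrt(np.mean(loo_resid**2))), abs=1e-9
            )
            # leverage in [0,1) inflates every held-out residual
            assert rep.rmse >= fit_loglinear(ds).rmse_fit - 1e-12

    def test_degenerate_reduced_design_names_record(self):
        ds = make_dataset(
            "deg", [("PAAA", 50, 1.0), ("P2", 50, 2.0), ("P3", 50, 1.5), ("P4", 99, 0.0)]
        )
        with pytest.raises(ValueError, match="P4"):
            loo_cv(ds)

    def test_too_small_rejected(self):
        ds = make_dataset("s", [("P1", 50, 1.0), ("P2", 60, 2.0), ("P3", 70, 3.0)])
        with pytest.raises(ValueError):
            loo_cv(ds)


class TestEvaluateExternal:
    def test_perfect_prediction_table(self, toy_dataset):
        table = PredictionTable("perfect", {r.pdb_id: r.ln_kf for r in toy_dataset})
        rep = evaluate_external(table, toy_dataset)
        assert rep.mode == "external"
        assert rep.rmse == 0.0

    def test_min_length_filter_semantics(self):
        ds = make_dataset("f", [("P1", 45, 1.0), ("P2", 60, 2.0), ("P3", 70, 3.0)])
        table = PredictionTable("srv", {"P1": 0.0, "P2": 0.0, "P3": 0.0})
        rep = evaluate_external(table, ds, min_length=50)
        assert rep.n == 2
        assert rep.min_length_filter == 50

    def test_model_on_train_equals_fit_report(self, toy_dataset):
        res = fit_loglinear(toy_dataset)
        fit_rep = evaluate_fit(res, toy_dataset)
        ext_rep = evaluate_external(res, toy_dataset)
        assert ext_rep.rmse == pytest.approx(fit_rep.rmse, abs=1e-12)
        assert ext_rep.mae == pytest.approx(fit_rep.mae, abs=1e-12)
        assert ext_rep.pcc == pytest.approx(fit_rep.pcc, abs=1e-12)

    def test_unmatched_ids_warned_and_skipped(self, toy_dataset, caplog):
        table = PredictionTable(
            "partial", {r.pdb_id: r.ln_kf for r in toy_dataset.records[:3]}
        )
        with caplog.at_level("WARNING"):
            rep = evaluate_external(table, toy_dataset)
        assert rep.n == 3
        assert "P004" in caplog.text

    def test_no_matches_is_error(self, toy_dataset):
        table = PredictionTable("none", {"XXXX": 1.0})
        with pytest.raises(ValueError):
            evaluate_external(table, toy_dataset)

    def test_predictions_never_refit(self):
        # an offset prediction table keeps its offset: external evaluation
        # must not re-estimate anything
        ds = make_dataset("o", [(f"P{i}", 50 + 10 * i, float(i)) for i in range(5)])
        table = PredictionTable("off", {r.pdb_id: r.ln_kf + 2.0 for r in ds})
        rep = evaluate_external(table, ds)
        assert rep.rmse == pytest.approx(2.0, abs=1e-12)
        assert rep.mae == pytest.approx(2.0, abs=1e-12)
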