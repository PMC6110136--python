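"""ROC sweep, trapezoidal AUC, naive model, rescaling and consensus."""

import numpy as np
import pytest

from fepbench.exceptions import DegenerateLabelsError
from fepbench.records import DeltaDeltaG, Provenance
from fepbench.roc import (
    add_method,
    consensus,
    fit_scale,
    naive_predictions,
    roc_curve,
)
from fepbench.transform import cutoff_from_fold

from conftest import make_record


def pairwise_auc(labels, preds):
    """Brute-force Mann–Whitney AUC with ties counted one half."""
    pos = [p for lab, p in zip(labels, preds) if lab]
    neg = [p for lab, p in zip(labels, preds) if not lab]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def records_from(exps, preds, method="m"):
    return [
        make_record(mutation=f"A{i + 1}B", exp=e, methods={method: (p, 0.0)})
        for i, (e, p) in enumerate(zip(exps, preds))
    ]


THRESHOLD = cutoff_from_fold(10)


class TestRocCurve:
    def test_constant_predictor_scores_exactly_one_half(self):
        recs = records_from([3.0, 0.5, 2.0, 0.2], [0.0, 0.0, 0.0, 0.0])
        curve = roc_curve(recs, "m", THRESHOLD)
        assert curve.auc == 0.5

    def test_perfect_separation_scores_one(self):
        recs = records_from([3.0, 2.5, 0.5, 0.2], [4.0, 3.5, 0.1, -0.5])
        assert roc_curve(recs, "m", THRESHOLD).auc == pytest.approx(1.0)

    def test_matches_pairwise_oracle_with_ties(self):
        exps = [3.0, 2.0, 1.8, 0.5, 0.2, 1.0, -0.3, 0.8]
        preds = [2.0, 1.0, 1.0, 1.0, 0.3, 0.3, -0.5, 2.0]
        recs = records_from(exps, preds)
        labels = [e > THRESHOLD.cutoff for e in exps]
        oracle = pairwise_auc(labels, preds)
        step = 0.001
        assert roc_curve(recs, "m", THRESHOLD, step).auc == pytest.approx(
            oracle, abs=step
        )

    def test_matches_sklearn_on_tie_free_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        exps = rng.normal(1.0, 1.2, size=40)
        preds = exps + rng.normal(0, 1.0, size=40)
        recs = records_from(list(exps), list(preds))
        labels = exps > THRESHOLD.cutoff
        assert roc_curve(recs, "m", THRESHOLD).auc == pytest.approx(
            roc_auc_score(labels, preds), abs=0.001
        )

    def test_invariant_under_monotone_transform(self):
        exps = [3.0, 2.0, 0.5, 0.2, 1.0, -0.3]
        preds = [2.2, 0.9, 0.4, -0.6, 1.7, 0.0]
        base = roc_curve(records_from(exps, preds), "m", THRESHOLD).auc
        warped = [float(np.expm1(p)) for p in preds]
        warped_auc = roc_curve(records_from(exps, warped), "m", THRESHOLD).auc
        assert warped_auc == pytest.approx(base, abs=0.002)

    def test_single_class_rejected(self):
        recs = records_from([0.1, 0.2], [1.0, 2.0])
        with pytest.raises(DegenerateLabelsError):
            roc_curve(recs, "m", THRESHOLD)

    def test_anchors_present_and_points_sorted(self):
        recs = records_from([3.0, 0.5], [1.0, 0.2])
        curve = roc_curve(recs, "m", THRESHOLD)
        assert [0.0, 0.0] in curve.points.tolist()
        assert [1.0, 1.0] in curve.points.tolist()
        fpr = curve.points[:, 0]
        assert (np.diff(fpr) >= 0).all()


class TestNaiveModel:
    def test_every_prediction_is_zero(self, toy_records):
        preds = naive_predictions(toy_records)
        assert all(p.value == 0.0 and p.sigma == 0.0 for p in preds)
        assert all(p.provenance == Provenance.NAIVE for p in preds)

    def test_zero_sensitivity_at_tenfold(self, toy_records):
        from fepbench.evaluate import build_truth_table, sensitivity

        recs = add_method(toy_records, "naive", naive_predictions(toy_records))
        t = build_truth_table(recs, "naive", THRESHOLD)
        assert sensitivity(t) == 0.0

    def test_roc_of_naive_model_is_one_half(self, toy_records):
        recs = add_method(toy_records, "naive", naive_predictions(toy_records))
        assert roc_curve(recs, "naive", THRESHOLD).auc == 0.5


class TestFitScale:
    def test_identity_when_predictions_equal_experiment(self):
        recs = records_from([1.0, 2.0, -0.5], [1.0, 2.0, -0.5])
        fit = fit_scale(recs, "m")
        assert fit.slope == pytest.approx(1.0)
        assert fit.rmse == pytest.approx(0.0, abs=1e-12)

    def test_halves_doubled_predictions(self):
        recs = records_from([1.0, 2.0, -0.5], [2.0, 4.0, -1.0])
        assert fit_scale(recs, "m").slope == pytest.approx(0.5)

    def test_matches_grid_search_oracle(self):
        exps = [0.3, 1.9, -0.7, 2.4, 0.9]
        preds = [0.8, 2.6, -0.1, 3.9, 1.1]
        recs = records_from(exps, preds)
        fit = fit_scale(recs, "m")
        grid = np.arange(-5.0, 5.0, 1e-4)
        e, p = np.array(exps), np.array(preds)
        rmses = np.sqrt(np.mean((grid[:, None] * p - e) ** 2, axis=1))
        assert fit.slope == pytest.approx(grid[np.argmin(rmses)], abs=1e-4)
        assert fit.rmse == pytest.approx(rmses.min(), abs=1e-6)

    def test_never_worse_than_unit_slope(self):
        rng = np.random.default_rng(1)
        exps = rng.normal(0.5, 1.2, 25)
        preds = 1.8 * exps + rng.normal(0, 1.0, 25)
        recs = records_from(list(exps), list(preds))
        fit = fit_scale(recs, "m")
        unit_rmse = float(np.sqrt(np.mean((preds - exps) ** 2)))
        assert fit.rmse <= unit_rmse + 1e-12

    def test_all_zero_predictions_rejected(self):
        recs = records_from([1.0, 2.0], [0.0, 0.0])
        with pytest.raises(ValueError, match="zero"):
            fit_scale(recs, "m")


class TestConsensus:
    def _two_method_records(self, exps, a, b):
        return [
            make_record(mutation=f"A{i + 1}B", exp=e,
                        methods={"fep": (x, 0.0), "prime": (y, 0.0)})
            for i, (e, x, y) in enumerate(zip(exps, a, b))
        ]

    def test_equal_errors_give_arithmetic_mean(self):
        # both methods are the same noisy copy, so equal RMSE and weights 1/2
        exps = [0.5, 1.5, -0.2, 2.0]
        a = [1.0, 1.0, 0.0, 2.5]
        recs = self._two_method_records(exps, a, a)
        out = consensus(recs, "fep", "prime")
        fit = fit_scale(recs, "fep")
        for rec, pred in zip(recs, out):
            scaled = fit.slope * rec.predictions["fep"].value
            assert pred.value == pytest.approx(scaled)

    def test_known_weights_by_hand(self):
        # construct records whose scaled RMSEs are sigma_a=1 and sigma_b=2 by
        # checking the weight formula directly on the consensus output
        exps = [0.0, 1.0, 2.0, 3.0, -1.0]
        a = [0.4, 1.2, 1.9, 3.3, -0.6]
        b = [1.5, -0.2, 3.8, 1.0, 0.5]
        recs = self._two_method_records(exps, a, b)
        fa, fb = fit_scale(recs, "fep"), fit_scale(recs, "prime")
        wa = (1 / fa.rmse**2) / (1 / fa.rmse**2 + 1 / fb.rmse**2)
        out = consensus(recs, "fep", "prime")
        for rec, pred in zip(recs, out):
            expect = wa * fa.slope * rec.predictions["fep"].value + (
                1 - wa
            ) * fb.slope * rec.predictions["prime"].value
            assert pred.value == pytest.approx(expect)
            assert pred.provenance == Provenance.CONSENSUS

    def test_infinitely_noisy_partner_recovers_single_method(self):
        rng = np.random.default_rng(3)
        exps = list(rng.normal(0.5, 1.0, 30))
        good = exps  # rmse 0 after scaling
        bad = list(rng.normal(0, 3.0, 30))
        recs = self._two_method_records(exps, good, bad)
        out = consensus(recs, "fep", "prime")
        fit = fit_scale(recs, "fep")
        for rec, pred in zip(recs, out):
            assert pred.value == pytest.approx(
                fit.slope * rec.predictions["fep"].value, abs=1e-9
            )

    def test_consensus_beats_both_methods_on_average(self):
        # independent errors: inverse-variance averaging reduces RMSE in
        # expectation over replicated synthetic datasets
        rng = np.random.default_rng(7)
        from fepbench.evaluate import rmse as rmse_metric

        wins = 0
        n_rep = 100
        for _ in range(n_rep):
            exps = rng.normal(0.5, 1.2, 60)
            a = exps + rng.normal(0, 1.0, 60)
            b = exps + rng.normal(0, 1.4, 60)
            recs = self._two_method_records(list(exps), list(a), list(b))
            out = consensus(recs, "fep", "prime")
            crecs = add_method(recs, "consensus", out)
            r_cons = rmse_metric(crecs, "consensus")
            r_best = min(
                np.sqrt(np.mean((fit_scale(recs, m).slope * np.array(
                    [r.predictions[m].value for r in recs]
                ) - exps) ** 2))
                for m in ("fep", "prime")
            )
            wins += r_cons <= r_best
        assert wins / n_rep > 0.5

    def test_degenerate_zero_rmse_pair_warns_and_averages(self):
        exps = [1.0, 2.0, -0.5]
        recs = self._two_method_records(exps, exps, exps)
        with pytest.warns(RuntimeWarning, match="unweighted"):
            out = consensus(recs, "fep", "prime")
        assert out[0].value == pytest.approx(1.0)

    def test_per_record_weights_use_sigmas(self):
        recs = [
            make_record(mutation="A1B", exp=1.0,
                        methods={"fep": (2.0, 0.5), "prime2": (0.0, 1.0)}),
            make_record(mutation="C2D", exp=0.5,
                        methods={"fep": (0.5, 0.5), "prime2": (1.5, 1.0)}),
        ]
        out = consensus(recs, "fep", "prime2", per_record_weights=True)
        fa, fb = fit_scale(recs, "fep"), fit_scale(recs, "prime2")
        sa, sb = fa.slope * 0.5, fb.slope * 1.0
        qa, qb = 1 / sa**2, 1 / sb**2
        expect = (qa * fa.slope * 2.0 + qb * fb.slope * 0.0) / (qa + qb)
        assert out[0].value == pytest.approx(expect)
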