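import numpy as np
import pandas as pd
import pytest

import habcircuit as hc
from habcircuit.analysis import (cross_validate, default_factors, make_report,
                                 node_contributions, normalize_first10_median,
                                 sensitivity_scan)
from habcircuit.mlp import MLPParams, forward


class TestNodeContributions:
    def test_reconstruction_identities_random_params(self):
        rng = np.random.default_rng(0)
        p = MLPParams(rng.normal(size=(6, 2)), rng.normal(size=2),
                      rng.normal(size=2), float(rng.normal()))
        X = rng.normal(size=(500, 6))
        cs = node_contributions(p, X)
        h = np.maximum(cs.input_to_hidden.sum(axis=1) + p.b1, 0.0)
        assert np.max(np.abs(h - cs.hidden)) <= 1e-12
        y = np.maximum(cs.hidden_to_output.sum(axis=1) + p.b2, 0.0)
        assert np.max(np.abs(y - cs.output)) <= 1e-12
        assert np.max(np.abs(cs.output - forward(p, X))) <= 1e-12

    def test_ablated_inputs_contribute_zero(self, design_truth, circuit):
        ci = list(design_truth.conditions).index("V-ON")
        X = design_truth.X[design_truth.condition_index == ci]
        cs = node_contributions(circuit.mlp, X)
        col = design_truth.columns.index("V-ON-Tonic")
        assert np.all(cs.input_to_hidden[:, col, :] == 0.0)

    def test_hand_case(self):
        p = MLPParams(np.vstack([[2.0, -1.0], np.zeros((5, 2))]),
                      np.zeros(2), np.ones(2), 0.0)
        cs = node_contributions(p, np.eye(6)[:1])
        assert cs.input_to_hidden[0, 0].tolist() == [2.0, -1.0]

    def test_table_subsamples_to_1s(self, design_truth, circuit):
        X = design_truth.X[design_truth.condition_index == 0]
        tbl = node_contributions(circuit.mlp, X).table()
        assert len(tbl) == 100
        assert tbl["t"].iloc[1] - tbl["t"].iloc[0] == pytest.approx(1.0)


class TestNormalizeFirst10Median:
    def test_already_normalised_unchanged(self):
        c = np.ones(9901)
        assert np.allclose(normalize_first10_median(c), c)

    def test_constant_five_becomes_one(self):
        assert np.allclose(normalize_first10_median(np.full(9901, 5.0)), 1.0)

    def test_median_of_first_10s_is_one_for_arbitrary_input(self):
        c = np.random.default_rng(0).normal(size=9901)
        out = normalize_first10_median(c)
        assert np.median(out[:1000]) == pytest.approx(1.0, abs=1e-12)


class TestSensitivityScan:
    def test_factor_grid_contains_one_and_respects_range(self):
        f = default_factors(25)
        assert f.size == 25
        assert 1.0 in f
        assert f.min() == pytest.approx(0.1) and f.max() == pytest.approx(10.0)
        with pytest.raises(ValueError):
            sensitivity_scan(hc.default_circuit().mlp, np.zeros((4, 6)),
                             np.zeros(4), factors=np.array([0.5, 2.0]))

    def test_factor_one_column_constant_equals_base_error(self, design_truth, circuit):
        # perturbed params so the base error is nonzero
        p = circuit.mlp.copy()
        p.b2 += 0.1
        grid = sensitivity_scan(p, design_truth.X, design_truth.y,
                                condition_index=design_truth.condition_index,
                                conditions=design_truth.conditions)
        col = grid.table[1.0].to_numpy()
        assert np.allclose(col, col[0], atol=1e-12)
        assert col[0] == pytest.approx(grid.base_error)
        assert grid.base_error > 0

    def test_zero_input_column_weight_has_flat_error(self, circuit):
        X = np.zeros((200, 6))
        X[:, 3] = np.linspace(0, 1, 200)   # only V-ON-Tonic active
        y = forward(circuit.mlp, X)
        grid = sensitivity_scan(circuit.mlp, X, y)
        for pid in ("W1:D-ON-Tonic->H1", "W1:D-OFF-Phasic->H2"):
            row = grid.table.loc[pid].to_numpy()
            assert np.allclose(row, row[0], atol=1e-12)

    def test_ground_truth_is_minimum_of_its_own_scan(self, design_truth, circuit):
        grid = sensitivity_scan(circuit.mlp, design_truth.X, design_truth.y,
                                condition_index=design_truth.condition_index,
                                conditions=design_truth.conditions)
        lo = grid.table[grid.table.columns[0]]
        hi = grid.table[grid.table.columns[-1]]
        base = grid.table[1.0]
        assert np.all(base <= lo + 1e-12)
        assert np.all(base <= hi + 1e-12)


@pytest.fixture(scope="module")
def cv_small(design_truth, circuit, protocol):
    """Tiny CV: 20 cells/condition, short fits, coarse check only."""
    traces = {}
    circ = hc.GroundTruthCircuit(circuit.mlp, noise_sd=0.05,
                                 raphe_cells_per_condition=20)
    for i, cond in enumerate(hc.CONDITIONS):
        traces[cond] = hc.simulate_raphe(circ, protocol,
                                         ablation=hc.ABLATION_MAP[cond],
                                         seed=600 + i)
    cv = cross_validate(traces, design_truth.X, protocol, folds=10,
                        seed=2, fit_config={"max_epochs": 300,
                                            "n_restarts": 1})
    return traces, cv


class TestCrossValidate:

    def test_folds_partition_cells(self, cv_small):
        traces, cv = cv_small
        for cond, fold_of in cv.membership.items():
            ids = set(traces[cond].cell_meta["cell_id"])
            assert set(fold_of) == ids
            counts = pd.Series(list(fold_of.values())).value_counts()
            assert sorted(counts.index) == list(range(10))
            assert counts.max() - counts.min() <= 1

    def test_ten_score_pairs_emitted(self, cv_small):
        _, cv = cv_small
        assert len(cv.scores) == 10
        assert {"fold", "rmse_train", "rmse_val"} <= set(cv.scores.columns)
        assert (cv.scores[["rmse_train", "rmse_val"]] >= 0).all().all()

    def test_fold_assignment_deterministic(self, design_truth, protocol, cv_small):
        traces, cv = cv_small
        cv2 = cross_validate(traces, design_truth.X, protocol, folds=10,
                             seed=2, fit_config={"max_epochs": 300,
                                                 "n_restarts": 1})
        assert cv.membership == cv2.membership
        assert np.allclose(cv.scores["rmse_val"], cv2.scores["rmse_val"])

    def test_too_few_cells_rejected(self, design_truth, protocol, circuit):
        circ = hc.GroundTruthCircuit(circuit.mlp, noise_sd=0.0,
                                     raphe_cells_per_condition=10)
        traces = {c: hc.simulate_raphe(circ, protocol, seed=0)
                  for c in hc.CONDITIONS}
        with pytest.raises(ValueError, match="folds"):
            cross_validate(traces, design_truth.X, protocol, folds=11, seed=0)


class TestMakeReport:
    def test_full_bundle_manifest(self, tmp_path, design_truth, circuit, noisy_fits):
        est = noisy_fits[0]
        fit = hc.FitResult(est.params_, est.rmse_, {})
        contribs = {c: node_contributions(est.params_,
                                          design_truth.X[design_truth.condition_index == i],
                                          condition=c)
                    for i, c in enumerate(design_truth.conditions)}
        grid = sensitivity_scan(est.params_, design_truth.X, design_truth.y,
                                factors=default_factors(5),
                                condition_index=design_truth.condition_index,
                                conditions=design_truth.conditions)
        man = make_report(tmp_path, fit=fit, design=design_truth,
                          contributions=contribs, sensitivity=grid, plots=False)
        assert len(man["curves"]) == 4
        assert len(man["contributions"]) == 4
        assert man["sensitivity"] == "sensitivity.csv"
        for f in man["curves"] + man["contributions"]:
            assert (tmp_path / f).exists()

    def test_partial_report_warns_without_cv(self, tmp_path, design_truth, circuit):
        with pytest.warns(UserWarning):
            man = make_report(tmp_path, sensitivity=None, plots=False)
        assert man["cv"] is None

    def test_rerun_byte_identical(self, tmp_path, design_truth, circuit):
        fit = hc.FitResult(circuit.mlp, 0.0, {})
        for d in ("a", "b"):
            make_report(tmp_path / d, fit=fit, design=design_truth, plots=False)
        a = (tmp_path / "a" / "curves_unablated.csv").read_bytes()
        b = (tmp_path / "b" / "curves_unablated.csv").read_bytes()
        assert a == b


class TestSignPatternRecovery:
    def test_inhibitory_dominant_hidden_drive_during_light(self, design_truth,
                                                           circuit, noisy_fits):
        """The ground-truth circuit suppresses the raphe during light through
        its hidden layer: the net hidden->output contribution drops below its
        unexcited-baseline level while the light is on.  This sign pattern is
        invariant to hidden-node permutation and to the output-bias gauge
        (unlike the raw sign of the drive), and fitted models recover it in
        at least 8 of 10 seeds."""
        Xu = design_truth.X[design_truth.condition_index == 0]
        t = np.arange(9901) * 0.01
        light = (t >= 20) & (t < 40)
        rest = t < 20                      # unexcited lead-in

        def light_drive_change(params):
            net = node_contributions(params, Xu).hidden_to_output.sum(1)
            return net[light].mean() - net[rest].mean()

        assert light_drive_change(circuit.mlp) < 0
        hits = sum(light_drive_change(est.params_) < 0 for est in noisy_fits)
        assert hits >= 8
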