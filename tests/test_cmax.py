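from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sauroncp import (GeneratorConfig, SplitSpec, apply_thresholds,
                      build_cmax_matrix, cmax_viability, filter_analyzable_drugs,
                      fit_dose_response, make_dose_response_panel, pam_discretize)


def logistic(conc, ec50_log10, hill):
    return 1.0 / (1.0 + np.exp(hill * (np.log10(conc) - ec50_log10)))


class TestDoseResponseFit:
    def test_noiseless_parameters_recovered(self):
        conc = np.logspace(-3, 1, 9)
        true = dict(ec50_log10=-0.7, hill=1.8)
        viab = logistic(conc, **true)
        curve = fit_dose_response(conc, viab)
        assert curve.kind == "logistic"
        assert curve.log10_ec50 == pytest.approx(true["ec50_log10"], abs=1e-6)
        assert curve.hill == pytest.approx(true["hill"], abs=1e-6)

    def test_constant_viability_gives_flat_curve(self):
        conc = np.logspace(-2, 1, 5)
        curve = fit_dose_response(conc, np.ones(5))
        assert curve.kind == "flat"
        assert np.allclose(curve.viability(conc), 1.0)

    def test_two_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0.1, 0.1, 1.0], [1.0, 0.9, 0.2])

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(ValueError):
            fit_dose_response([0.0, 0.1, 1.0], [1.0, 0.9, 0.2])

    def test_fitted_curve_is_nonincreasing(self):
        rng = np.random.default_rng(2)
        conc = np.logspace(-3, 1, 9)
        viab = logistic(conc, -1.0, 1.2) + 0.05 * rng.standard_normal(9)
        curve = fit_dose_response(conc, viab)
        grid = np.logspace(-5, 3, 200)
        assert np.all(np.diff(curve.viability(grid)) <= 1e-12)

    def test_replicates_and_order_do_not_matter(self):
        rng = np.random.default_rng(3)
        conc = np.logspace(-3, 1, 9)
        viab = logistic(conc, -0.5, 1.5) + 0.02 * rng.standard_normal(9)
        c2 = np.concatenate([conc, conc])
        v2 = np.concatenate([viab, viab])
        perm = rng.permutation(len(c2))
        a = fit_dose_response(conc, viab)
        b = fit_dose_response(c2[perm], v2[perm])
        assert b.log10_ec50 == pytest.approx(a.log10_ec50, abs=1e-6)
        assert b.hill == pytest.approx(a.hill, abs=1e-6)


class TestCMaxViability:
    def test_flat_curve_identity(self):
        curve = fit_dose_response(np.logspace(-2, 1, 5), np.ones(5))
        v, _ = cmax_viability(curve, 0.5)
        assert v == 1.0

    def test_midpoint_gives_half(self):
        conc = np.logspace(-3, 1, 9)
        curve = fit_dose_response(conc, logistic(conc, 0.0, 2.0))
        v, extrapolated = cmax_viability(curve, 1.0)  # CMax at the midpoint
        assert v == pytest.approx(0.5, abs=1e-6)
        assert not extrapolated

    def test_extrapolation_flagged_and_clipped(self):
        conc = np.logspace(-2, 1, 6)
        curve = fit_dose_response(conc, logistic(conc, 0.0, 1.5))
        v, extrapolated = cmax_viability(curve, 1e-5)
        assert extrapolated
        assert 0.0 <= v <= 1.0

    def test_nonpositive_cmax_rejected(self):
        conc = np.logspace(-2, 1, 6)
        curve = fit_dose_response(conc, logistic(conc, 0.0, 1.5))
        with pytest.raises(ValueError):
            cmax_viability(curve, 0.0)


def brute_force_pam(values, counts, k):
    best, best_cost = None, np.inf
    n = len(values)
    for medoid_idx in combinations(range(n), k):
        med = values[list(medoid_idx)]
        cost = np.sum(counts * np.min(np.abs(values[:, None] - med[None, :]), axis=1))
        if cost < best_cost - 1e-15:
            best, best_cost = np.sort(med), cost
    return best


class TestPAM:
    def test_two_separated_blobs_threshold_midpoint(self):
        vals = np.array([0.05, 0.1, 0.15, 0.85, 0.9, 0.95])
        model = pam_discretize(vals, 2)
        assert model.thresholds[0] == pytest.approx(0.5, abs=1e-9)
        assert np.allclose(model.medoids, [0.1, 0.9])

    def test_three_blobs_ordered_thresholds(self):
        vals = np.concatenate([np.linspace(0.0, 0.1, 5),
                               np.linspace(0.45, 0.55, 5),
                               np.linspace(0.9, 1.0, 5)])
        model = pam_discretize(vals, 3)
        assert model.thresholds[0] < model.thresholds[1]
        assert model.thresholds[0] == pytest.approx((0.1 + 0.45) / 2, abs=1e-9)
        assert model.thresholds[1] == pytest.approx((0.55 + 0.9) / 2, abs=1e-9)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            pam_discretize(np.full(10, 0.5), 2)

    @pytest.mark.parametrize("k", [2, 3])
    def test_matches_brute_force_enumeration(self, k):
        rng = np.random.default_rng(4)
        for _ in range(5):
            vals = np.round(rng.uniform(size=12), 3)
            uniq, counts = np.unique(vals, return_counts=True)
            if len(uniq) < k:
                continue
            model = pam_discretize(vals, k)
            expected = brute_force_pam(uniq, counts, k)
            assert np.allclose(model.medoids, expected)

    def test_medoid_threshold_rule(self):
        vals = np.array([0.0, 0.1, 0.2, 0.8, 0.9, 1.0])
        model = pam_discretize(vals, 2, threshold_rule="medoid")
        assert model.thresholds[0] == pytest.approx((0.1 + 0.9) / 2)


class TestApplyThresholds:
    def test_binary_labels(self):
        model = pam_discretize([0.1, 0.2, 0.8, 0.9], 2)
        labels = apply_thresholds([0.2, 0.9, 0.5], model)
        assert labels.tolist() == [1, 0, 1]  # 0.5 == threshold -> sensitive

    def test_boundary_goes_to_more_sensitive_class(self):
        model = pam_discretize([0.1, 0.2, 0.8, 0.9], 2)
        t = model.thresholds[0]
        assert apply_thresholds([t], model)[0] == 1

    def test_ternary_bands(self):
        vals = np.concatenate([np.linspace(0.0, 0.2, 5),
                               np.linspace(0.45, 0.55, 5),
                               np.linspace(0.85, 1.0, 5)])
        model = pam_discretize(vals, 3)
        labels = apply_thresholds([0.05, 0.5, 0.95], model)
        assert labels.tolist() == [1, 2, 3]

    def test_labels_monotone_in_viability(self):
        model = pam_discretize(np.linspace(0, 1, 40), 3)
        grid = np.linspace(0, 1, 200)
        bands = np.searchsorted([1, 2, 3], apply_thresholds(grid, model))
        assert np.all(np.diff(bands) >= 0)


class TestDrugFilter:
    def make_split(self):
        return SplitSpec([f"c{i}" for i in range(8)],
                         [f"c{i}" for i in range(8, 12)],
                         [f"c{i}" for i in range(12, 16)])

    def test_single_class_dropped(self):
        lines = [f"c{i}" for i in range(16)]
        labels = pd.DataFrame({"drugA": [0] * 16,
                               "drugB": [0, 1] * 8}, index=lines)
        retained, report = filter_analyzable_drugs(labels, self.make_split(),
                                                   min_per_class=2)
        assert retained == ["drugB"]
        row = report.set_index("drug").loc["drugA"]
        assert row["status"] == "dropped"
        assert "single class" in row["reason"]

    def test_insufficient_minority_dropped(self):
        lines = [f"c{i}" for i in range(16)]
        col = np.zeros(16, int)
        col[0] = 1  # one sensitive sample, in train only
        labels = pd.DataFrame({"drugA": col}, index=lines)
        retained, report = filter_analyzable_drugs(labels, self.make_split(),
                                                   min_per_class=3)
        assert retained == []

    def test_sufficient_drug_retained(self):
        lines = [f"c{i}" for i in range(16)]
        labels = pd.DataFrame({"drugA": [0, 1] * 8}, index=lines)
        retained, _ = filter_analyzable_drugs(labels, self.make_split(),
                                              min_per_class=2)
        assert retained == ["drugA"]


class TestPanelRecovery:
    def test_cmax_viabilities_recovered_within_tolerance(self):
        cfg = GeneratorConfig(n_samples=12, n_drugs=4, seed=21)
        points, cmax_table, truth = make_dose_response_panel(cfg)
        values, flags = build_cmax_matrix(points, cmax_table)
        err = []
        for _, row in truth.iterrows():
            est = values.loc[row["cell_line"], row["drug"]]
            err.append(abs(est - row["true_cmax_viability"]))
        assert np.max(err) <= 0.05

    def test_noiseless_panel_recovered_exactly(self):
        cfg = GeneratorConfig(n_samples=6, n_drugs=2, viability_noise_sd=0.0,
                              n_replicates=1, seed=22)
        points, cmax_table, truth = make_dose_response_panel(cfg)
        values, _ = build_cmax_matrix(points, cmax_table)
        for _, row in truth.iterrows():
            est = values.loc[row["cell_line"], row["drug"]]
            assert est == pytest.approx(row["true_cmax_viability"], abs=1e-6)
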