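"""Quality criteria, NPARC testing and target calling."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from btpp.curves import MeltingCurveFit, model_value
from btpp.quantio import compute_fold_changes, load_published_targets
from btpp.simdata import SimulationConfig, simulate_study
from btpp.targets import (
    AnalysisThresholds,
    benjamini_hochberg,
    call_targets,
    criterion_fit_quality,
    criterion_shift_consistency,
    criterion_slope,
    criterion_vehicle_plateau,
    nparc_batch,
    nparc_test,
)

TH = AnalysisThresholds()


def fake_fit(r_squared=0.95, plateau=0.1, slope=-0.1, converged=True, tm=50.0):
    return MeltingCurveFit(
        a=900.0, b=18.0, plateau=plateau, r_squared=r_squared, tm=tm,
        steepest_slope=slope, converged=converged, n_points=7,
    )


class TestFitQualityCriterion:
    def test_all_above_threshold_passes(self):
        fits = [fake_fit(r) for r in (0.95, 0.93, 0.97, 0.91)]
        assert criterion_fit_quality(fits, TH)

    def test_single_low_r_squared_fails(self):
        fits = [fake_fit(r) for r in (0.95, 0.79, 0.97, 0.91)]
        assert not criterion_fit_quality(fits, TH)

    def test_threshold_is_strict(self):
        fits = [fake_fit(r) for r in (0.95, 0.8, 0.97, 0.91)]
        assert not criterion_fit_quality(fits, TH)

    def test_non_converged_fit_fails_without_raising(self):
        fits = [fake_fit(), fake_fit(converged=False), fake_fit(), fake_fit()]
        assert not criterion_fit_quality(fits, TH)

    def test_relaxing_threshold_never_shrinks_passing_set(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fits = [fake_fit(r) for r in rng.uniform(0.5, 1.0, 4)]
            strict = criterion_fit_quality(fits, AnalysisThresholds(r2_min=0.9))
            lax = criterion_fit_quality(fits, AnalysisThresholds(r2_min=0.7))
            assert lax or not strict


class TestVehiclePlateauCriterion:
    @pytest.mark.parametrize(
        "plateaus,expected",
        [((0.05, 0.12), True), ((0.05, 0.31), False), ((0.30, 0.10), False)],
    )
    def test_strict_plateau_bound(self, plateaus, expected):
        fits = [fake_fit(plateau=p) for p in plateaus]
        assert criterion_vehicle_plateau(fits, TH) is expected


class TestShiftConsistencyCriterion:
    def test_published_rows_pass(self):
        # replicate shifts 1.42 / 3.68 both exceed the 0.42 vehicle spread
        assert criterion_shift_consistency(45.74, 47.16, 45.32, 49.00)
        # shifts 4.59 / 3.46 both exceed 2.71
        assert criterion_shift_consistency(45.23, 49.82, 47.94, 51.40)

    def test_small_shifts_with_large_vehicle_spread_fail(self):
        assert not criterion_shift_consistency(50.0, 50.5, 52.0, 52.4)

    def test_opposite_sign_shifts_fail(self):
        assert not criterion_shift_consistency(50.0, 53.0, 50.0, 47.0)

    def test_undefined_melting_point_fails(self):
        assert not criterion_shift_consistency(None, 50.0, 50.0, 52.0)
        assert not criterion_shift_consistency(math.nan, 50.0, 50.0, 52.0)

    @pytest.mark.parametrize("method", ["bTPP", "TPP"])
    def test_every_published_target_row_passes(self, method):
        table = load_published_targets(method)
        passing = sum(
            criterion_shift_consistency(
                r.tm_control_1, r.tm_treatment_1, r.tm_control_2, r.tm_treatment_2
            )
            for r in table.itertuples()
        )
        assert passing == len(table)


class TestSlopeCriterion:
    def test_one_steep_curve_per_pair_suffices(self):
        pairs = [
            (fake_fit(slope=-0.10), fake_fit(slope=-0.04)),
            (fake_fit(slope=-0.08), fake_fit(slope=-0.09)),
        ]
        assert criterion_slope(pairs, TH)

    def test_pair_with_both_shallow_fails(self):
        pairs = [
            (fake_fit(slope=-0.05), fake_fit(slope=-0.05)),
            (fake_fit(slope=-0.10), fake_fit(slope=-0.10)),
        ]
        assert not criterion_slope(pairs, TH)

    def test_boundary_is_strict(self):
        pairs = [(fake_fit(slope=-0.06), fake_fit(slope=-0.06))] * 2
        assert not criterion_slope(pairs, TH)


class TestNparc:
    def test_identical_conditions_zero_noise_give_p_one(self, design):
        T = design.gradient.as_array()
        y = model_value(T, 900.0, 18.5, 0.1)  # exact model curve, no noise
        row = {
            design.sample_label(c, r, t): y[j]
            for c, r in design.experiments()
            for j, t in enumerate(design.gradient)
        }
        res = nparc_test(pd.Series(row, name="P1"), design, n_permutations=100, seed=0)
        assert res.rss_null == pytest.approx(0.0, abs=1e-12)
        assert res.rss_alt == pytest.approx(0.0, abs=1e-12)
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_rss_nesting_on_noisy_proteins(self, design):
        truth, abundance, des = simulate_study(
            SimulationConfig(n_proteins=60, target_fraction=0.2, seed=53)
        )
        fc, _ = compute_fold_changes(abundance, des)
        results = nparc_batch(fc, des, method="theoretical_f")
        for r in results:
            assert r.rss_null >= r.rss_alt - 1e-12
            assert r.f_statistic >= 0.0
            assert 0.0 <= r.p_value <= 1.0

    def test_insufficient_points_flagged_not_raised(self, design):
        row = {label: np.nan for label in design.sample_labels()}
        for c, r in design.experiments():
            row[design.sample_label(c, r, 37.0)] = 1.0
        res = nparc_test(pd.Series(row, name="P1"), design, n_permutations=50, seed=0)
        assert res.p_value == 1.0
        assert not res.converged

    def test_large_shift_detected(self, design):
        cfg = SimulationConfig(
            n_proteins=20, target_fraction=1.0, dtm_range=(4.0, 4.0),
            noise_cv=0.05, missing_rate=0.0, seed=59,
        )
        truth, abundance, des = simulate_study(cfg)
        fc, _ = compute_fold_changes(abundance, des)
        results = nparc_batch(fc, des, method="permutation", n_permutations=200, seed=59)
        pvals = np.array([r.p_value for r in results])
        assert np.mean(pvals < 0.05) >= 0.8

    def test_theoretical_f_tracks_permutation_reference(self, design):
        """The F approximation must agree in rank with the exact permutation
        reference on null proteins (monotone association)."""
        cfg = SimulationConfig(n_proteins=200, target_fraction=0.0, seed=61)
        truth, abundance, des = simulate_study(cfg)
        fc, _ = compute_fold_changes(abundance, des)
        perm = nparc_batch(fc, des, method="permutation", n_permutations=1000, seed=61)
        theo = nparc_batch(fc, des, method="theoretical_f")
        rho = spearmanr(
            [r.p_value for r in perm], [r.p_value for r in theo]
        ).statistic
        assert rho > 0.7

    def test_unknown_method_rejected(self, design):
        fc = pd.DataFrame(
            {label: [1.0] for label in design.sample_labels()}, index=["P1"]
        )
        with pytest.raises(ValueError):
            nparc_batch(fc, design, method="bootstrap")


class TestCallTargets:
    def test_zero_noise_separates_targets_exactly(self, design):
        cfg = SimulationConfig(
            n_proteins=40, target_fraction=0.25, noise_cv=0.0, missing_rate=0.0,
            dtm_range=(4.0, 4.0), seed=67,
        )
        truth, abundance, des = simulate_study(cfg)
        fc, _ = compute_fold_changes(abundance, des)
        records = call_targets(fc, des, nparc_method="theoretical_f", seed=67)
        called = {r.accession for r in records if r.is_target}
        true_targets = set(truth.loc[truth["is_target"], "accession"])
        assert called == true_targets
        # with zero noise the shifted curves are perfectly distinguishable
        for r in records:
            if r.accession in true_targets:
                assert r.passes_significance
                assert r.dtm_1 == pytest.approx(4.0, abs=0.3)

    def test_records_sorted_and_failures_annotated(self, design):
        cfg = SimulationConfig(n_proteins=25, target_fraction=0.0, seed=71)
        truth, abundance, des = simulate_study(cfg)
        fc, _ = compute_fold_changes(abundance, des)
        records = call_targets(fc, des, nparc_method="theoretical_f", seed=71)
        accs = [r.accession for r in records]
        assert accs == sorted(accs)
        for r in records:
            if not r.is_target:
                assert r.first_failed in {
                    "fit_quality", "vehicle_plateau", "shift_consistency", "slope",
                }

    def test_requires_two_replicates(self, gradient):
        from btpp.design import ExperimentDesign

        one_rep = ExperimentDesign(gradient=gradient, replicates=(1,))
        fc = pd.DataFrame(
            {label: [1.0] for label in one_rep.sample_labels()}, index=["P1"]
        )
        with pytest.raises(ValueError, match="two biological replicates"):
            call_targets(fc, one_rep)


def test_benjamini_hochberg_matches_statsmodels():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(3)
    p = rng.uniform(0, 1, 200)
    ours = benjamini_hochberg(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(ours, theirs, atol=1e-12)
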