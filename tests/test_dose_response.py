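import numpy as np
import pytest

from biaskit.dose_response import (
    InsufficientDataError,
    LogisticFit,
    NormalizationError,
    classify_nr,
    fit_logistic3,
    logistic3,
    normalize_to_forskolin,
    summarize_panel,
)

from conftest import logistic_cr, make_cr


def grid_search_logec50(cr, direction, step=0.001):
    """Independent oracle: brute-force log EC50 grid with top/bottom solved
    by linear least squares at each grid point."""
    x, y = cr.pooled()
    logx = np.log10(x)
    sign = -1.0 if direction == "stimulation" else 1.0
    grid = np.arange(logx.min() - 2.0, logx.max() + 2.0 + step / 2, step)
    best, best_rss = None, np.inf
    for g in grid:
        w = 1.0 / (1.0 + 10.0 ** (sign * (logx - g)))  # y = bottom + (top-bottom)*w
        A = np.column_stack([w, 1.0 - w])  # coefficients for top, bottom
        coef, rss, *_ = np.linalg.lstsq(A, y, rcond=None)
        rss = float(np.sum((A @ coef - y) ** 2))
        if rss < best_rss:
            best, best_rss = g, rss
    return best


class TestFitLogistic3:
    def test_noiseless_stimulation_recovery(self):
        cr = logistic_cr(p_half=7.0, top=100.0, bottom=0.0)
        fit = fit_logistic3(cr, direction="stimulation")
        assert abs(fit.p_half - 7.0) < 1e-6
        assert abs(fit.top - 100.0) < 1e-6
        assert abs(fit.bottom) < 1e-6
        assert not fit.nr_flag

    def test_noiseless_inhibition_recovery(self):
        cr = logistic_cr(p_half=8.0, top=100.0, bottom=0.0, direction="inhibition")
        fit = fit_logistic3(cr, direction="inhibition")
        assert abs(fit.p_half - 8.0) < 1e-6
        assert fit.response_range < 0

    def test_auto_direction_matches_explicit(self):
        cr = logistic_cr(p_half=7.5, direction="inhibition")
        assert fit_logistic3(cr, direction="auto").direction == "inhibition"

    def test_flat_data_is_nr(self):
        cr = make_cr(np.logspace(-10, -5, 6), [[50.0, 50.0]] * 6)
        fit = fit_logistic3(cr, direction="stimulation")
        assert fit.nr_flag

    def test_too_few_concentrations(self):
        cr = make_cr([1e-9, 1e-8, 1e-7], [[1], [5], [9]])
        with pytest.raises(InsufficientDataError):
            fit_logistic3(cr)

    def test_sems_positive_with_noise(self):
        cr = logistic_cr(noise_sd=2.0, replicates=3, rng=np.random.default_rng(42))
        fit = fit_logistic3(cr, direction="stimulation")
        assert fit.sems["p_half"] > 0
        assert fit.sems["top"] > 0

    def test_fitted_curve_monotone_on_data_grid(self):
        cr = logistic_cr(p_half=6.5, noise_sd=2.0, replicates=3,
                         rng=np.random.default_rng(7))
        fit = fit_logistic3(cr, direction="stimulation")
        pred = fit.predict(cr.concentrations)
        assert np.all(np.diff(pred) >= -1e-12)

    @pytest.mark.parametrize("direction,p_half", [("stimulation", 7.2), ("inhibition", 6.4)])
    def test_matches_grid_search_oracle(self, direction, p_half):
        # <= 6-point noiseless curves: fitted log EC50 within one 0.001 grid step
        cr = logistic_cr(p_half=p_half, n_conc=6, span=2.5, direction=direction)
        fit = fit_logistic3(cr, direction=direction)
        oracle = grid_search_logec50(cr, direction)
        assert abs(-fit.p_half - oracle) <= 0.001

    def test_parameter_recovery_under_study_noise(self):
        # study conditions: noise SD 2% of window, 3 replicates, 8 concentrations
        errors = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            cr = logistic_cr(p_half=7.0, noise_sd=2.0, replicates=3, n_conc=8, rng=rng)
            fit = fit_logistic3(cr, direction="stimulation")
            errors.append(abs(fit.p_half - 7.0))
        assert np.median(errors) < 0.05


class TestClassifyNr:
    def _fit(self, rng_range):
        return LogisticFit("L", "P", p_half=7.0, top=rng_range, bottom=0.0,
                           direction="stimulation", converged=True)

    def test_below_threshold_is_nr(self):
        assert classify_nr(self._fit(2.0), threshold_fraction=0.1)

    def test_above_threshold_not_nr(self):
        assert not classify_nr(self._fit(80.0), threshold_fraction=0.1)

    def test_boundary_is_not_nr(self):
        # strict inequality: range exactly at threshold keeps the curve
        assert not classify_nr(self._fit(10.0), threshold_fraction=0.1)

    def test_unconverged_is_nr(self):
        fit = self._fit(80.0)
        fit.converged = False
        assert classify_nr(fit)


class TestNormalizeToForskolin:
    def _forskolin(self, top=2000.0):
        return logistic_cr(p_half=6.0, top=top, bottom=0.0, ligand="forskolin",
                           assay="cAMP_accumulation")

    def test_self_normalisation_gives_100(self):
        fsk = self._forskolin()
        flat = make_cr(np.logspace(-9, -5, 5), [[2000.0]] * 5)
        out = normalize_to_forskolin(flat, fsk)
        for r in out.responses:
            np.testing.assert_allclose(r, 100.0, rtol=1e-6)

    def test_zero_stays_zero(self):
        fsk = self._forskolin()
        zero = make_cr(np.logspace(-9, -5, 5), [[0.0]] * 5)
        out = normalize_to_forskolin(zero, fsk)
        assert all(np.all(r == 0) for r in out.responses)

    def test_quarter_of_window(self):
        fsk = self._forskolin(top=2000.0)
        raw = make_cr(np.logspace(-9, -5, 5), [[500.0]] * 5)
        out = normalize_to_forskolin(raw, fsk)
        np.testing.assert_allclose(np.concatenate(out.responses), 25.0, rtol=1e-6)
        assert out.meta["forskolin_top"] == pytest.approx(2000.0, rel=1e-6)

    def test_flat_forskolin_raises(self):
        flat_fsk = make_cr(np.logspace(-9, -5, 5), [[1.0]] * 5, ligand="forskolin")
        raw = make_cr(np.logspace(-9, -5, 5), [[500.0]] * 5)
        with pytest.raises(NormalizationError):
            normalize_to_forskolin(raw, flat_fsk)


class TestSummarizePanel:
    def test_matrix_with_nr_cell(self):
        fits = [
            fit_logistic3(logistic_cr(p_half=7.0, ligand="A", pathway="Goa")),
            fit_logistic3(logistic_cr(p_half=6.5, ligand="A", pathway="Gob")),
            fit_logistic3(logistic_cr(p_half=7.5, ligand="B", pathway="Gob")),
            fit_logistic3(make_cr(np.logspace(-10, -5, 6), [[0.0, 0.0]] * 6,
                                  ligand="B", pathway="Goa")),
        ]
        table = summarize_panel(fits)
        assert len(table) == 4
        nr_cell = table[(table.ligand == "B") & (table.pathway == "Goa")]
        assert bool(nr_cell.nr.iloc[0])
        assert np.isnan(nr_cell.p_half.iloc[0])

    def test_single_fit(self):
        table = summarize_panel([fit_logistic3(logistic_cr())])
        assert len(table) == 1
        assert table.p_half.iloc[0] == pytest.approx(7.0, abs=1e-6)

    def test_known_pec50s_recovered(self):
        truth = {"A": 7.0, "B": 6.2}
        fits = [fit_logistic3(logistic_cr(p_half=p, ligand=l, noise_sd=2.0,
                                          replicates=3, rng=np.random.default_rng(3)))
                for l, p in truth.items()]
        table = summarize_panel(fits).set_index("ligand")
        for ligand, p in truth.items():
            assert table.loc[ligand, "p_half"] == pytest.approx(p, abs=0.1)

    def test_empty_panel_raises(self):
        with pytest.raises(InsufficientDataError):
            summarize_panel([])
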