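import warnings

import numpy as np
import pytest

from biaskit.dose_response import fit_logistic3
from biaskit.operational_bias import (
    BiasResult,
    EmptyFitError,
    MissingReferenceError,
    OperationalFit,
    PairingError,
    compute_bias,
    fit_operational_global,
    goa_gob_concordance,
    operational_response,
)

from conftest import make_cr, operational_cr


def _quiet_fit(panel, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return fit_operational_global(panel, **kw)


class TestGlobalFit:
    def test_noiseless_two_agonist_recovery(self, two_agonist_panel):
        fits = {f.ligand_id: f for f in _quiet_fit(two_agonist_panel)}
        assert fits["full"].log_tau == pytest.approx(1.0, abs=1e-4)
        assert fits["full"].log_ka == pytest.approx(-7.0, abs=1e-4)
        assert fits["partial"].log_tau == pytest.approx(0.0, abs=1e-4)
        assert fits["partial"].log_ka == pytest.approx(-6.0, abs=1e-4)
        assert fits["full"].shared_em == pytest.approx(100.0, abs=1e-3)
        assert fits["full"].shared_basal == pytest.approx(0.0, abs=1e-3)

    def test_zero_efficacy_agonist_flagged_nr(self, two_agonist_panel):
        silent = make_cr(two_agonist_panel[0].concentrations,
                         [[0.0, 0.0]] * 17, ligand="silent", pathway="Gob")
        fits = {f.ligand_id: f for f in _quiet_fit(two_agonist_panel + [silent])}
        assert fits["silent"].nr_flag
        assert np.isnan(fits["silent"].log_tau)
        assert not fits["full"].nr_flag

    def test_all_nr_raises(self):
        silent = make_cr(np.logspace(-11, -5, 8), [[0.0, 0.0]] * 8,
                         ligand="silent", pathway="Goa")
        with pytest.raises(EmptyFitError):
            _quiet_fit([silent])

    def test_mixed_pathways_rejected(self, two_agonist_panel):
        other = operational_cr(0.5, -7.0, ligand="x", pathway="Goa")
        with pytest.raises(Exception, match="single pathway"):
            fit_operational_global(two_agonist_panel + [other])

    def test_ec50_closed_form_identity(self):
        # for n = 1 the operational curve is a logistic with EC50 = KA/(1+tau):
        # the fitted parameters must satisfy this against a 3PL refit of the
        # fitted curve to within 1e-6 relative
        panel = [operational_cr(0.8, -7.0, ligand="a", pathway="Gob"),
                 operational_cr(-0.3, -6.5, ligand="b", pathway="Gob")]
        fits = _quiet_fit(panel, slope_mode="fixed")
        for f in fits:
            conc = np.logspace(-12, -3, 19)
            curve = operational_response(conc, f.log_tau, f.log_ka,
                                         f.shared_em, f.shared_basal, 1.0)
            refit = fit_logistic3(make_cr(conc, [[v] for v in curve]),
                                  direction="stimulation")
            ec50_closed = 10.0 ** f.log_ka / (1.0 + 10.0 ** f.log_tau)
            assert 10.0 ** (-refit.p_half) == pytest.approx(ec50_closed, rel=1e-6)

    def test_high_tau_top_approaches_em(self):
        # tau >= 100 drives the curve top to within 1% of Em
        cr = operational_cr(2.0, -7.0, ligand="super", pathway="Gob")
        fit = fit_logistic3(cr, direction="stimulation")
        assert abs(fit.top - 100.0) / 100.0 < 0.01

    def test_rescaling_responses_rescales_system_not_ligand_params(self, two_agonist_panel):
        fits1 = {f.ligand_id: f for f in _quiet_fit(two_agonist_panel, slope_mode="fixed")}
        doubled = [cr.with_responses([r * 2.0 for r in cr.responses])
                   for cr in two_agonist_panel]
        fits2 = {f.ligand_id: f
                 for f in _quiet_fit(doubled, window=200.0, slope_mode="fixed")}
        assert fits2["full"].shared_em == pytest.approx(2 * fits1["full"].shared_em, rel=1e-4)
        for name in ("full", "partial"):
            assert fits2[name].log_tau == pytest.approx(fits1[name].log_tau, abs=1e-4)
            assert fits2[name].log_ka == pytest.approx(fits1[name].log_ka, abs=1e-4)

    def test_log_tau_over_ka_consistency(self, two_agonist_panel):
        for f in _quiet_fit(two_agonist_panel):
            assert f.log_tau_over_ka == pytest.approx(f.log_tau - f.log_ka, abs=1e-10)


class TestComputeBias:
    def _fit(self, ligand, log_r, sem, pathway="Gob"):
        return OperationalFit(ligand_id=ligand, pathway_id=pathway,
                              log_tau=log_r, log_ka=0.0,
                              sems={"log_tau_over_ka": sem})

    def test_reference_vs_itself(self):
        ref = self._fit("ref", 7.5, 0.2)
        out = compute_bias([ref], "ref")[0]
        assert out.delta_log_tau_over_ka == 0.0
        assert out.pooled_sem == pytest.approx(np.sqrt(2) * 0.2)

    def test_pooled_sem_three_four_five(self):
        b = BiasResult("a", "p", "r", 0.5, sem_ligand=3.0, sem_reference=4.0)
        assert b.pooled_sem == pytest.approx(5.0, abs=1e-12)

    def test_hand_arithmetic_delta(self):
        fits = [self._fit("ref", 7.5, 0.1), self._fit("lig", 8.0, 0.1)]
        out = {b.ligand_id: b for b in compute_bias(fits, "ref")}
        assert out["lig"].delta_log_tau_over_ka == pytest.approx(0.5, abs=1e-12)
        assert out["lig"].bias_factor == pytest.approx(10**0.5, rel=1e-12)

    def test_antisymmetry(self):
        fits = [self._fit("a", 7.5, 0.1), self._fit("b", 8.1, 0.2)]
        d_ab = {x.ligand_id: x for x in compute_bias(fits, "a")}["b"].delta_log_tau_over_ka
        d_ba = {x.ligand_id: x for x in compute_bias(fits, "b")}["a"].delta_log_tau_over_ka
        assert d_ab == pytest.approx(-d_ba, abs=1e-12)

    def test_nr_ligand_propagates_nr(self):
        fits = [self._fit("ref", 7.5, 0.1),
                OperationalFit("dead", "Gob", float("nan"), float("nan"), nr_flag=True)]
        out = {b.ligand_id: b for b in compute_bias(fits, "ref")}
        assert out["dead"].nr_flag
        assert np.isnan(out["dead"].delta_log_tau_over_ka)

    def test_missing_reference_raises(self):
        with pytest.raises(MissingReferenceError):
            compute_bias([self._fit("lig", 8.0, 0.1)], "ref")

    def test_nr_reference_raises(self):
        nr_ref = OperationalFit("ref", "Gob", float("nan"), float("nan"), nr_flag=True)
        with pytest.raises(MissingReferenceError):
            compute_bias([nr_ref, self._fit("lig", 8.0, 0.1)], "ref")


class TestRecoveryUnderNoise:
    def test_median_delta_error_small(self):
        # abbreviated version of the full 100-seed study (see acceptance suite)
        truth = {"ref": (0.9, -6.9), "partial": (0.0, -6.5), "probe": (0.7, -7.8)}
        errors = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            panel = [operational_cr(lt, lk, ligand=name, pathway="Gob",
                                    replicates=3, noise_sd=2.0, rng=rng)
                     for name, (lt, lk) in truth.items()]
            bias = compute_bias(_quiet_fit(panel), "ref")
            for b in bias:
                if b.ligand_id == "ref":
                    continue
                lt, lk = truth[b.ligand_id]
                rt, rk = truth["ref"]
                errors.append(abs(b.delta_log_tau_over_ka - ((lt - lk) - (rt - rk))))
        assert np.median(errors) < 0.1


class TestConcordance:
    def _pair(self, shift=0.0):
        conc = np.logspace(-10, -5, 6)
        a = operational_cr(0.8, -7.0, conc=conc, ligand="L", pathway="Goa")
        b = a.with_responses([r + shift for r in a.responses])
        b.pathway_id = "Gob"
        return a, b

    def test_identical_curves_on_unity(self):
        a, b = self._pair(0.0)
        table = goa_gob_concordance(a, b)
        np.testing.assert_allclose(table["deviation_from_unity"], 0.0, atol=1e-12)

    def test_constant_offset(self):
        a, b = self._pair(20.0)
        table = goa_gob_concordance(a, b)
        np.testing.assert_allclose(table["deviation_from_unity"], 20.0, atol=1e-12)

    def test_silent_vs_active_all_one_side(self):
        conc = np.logspace(-10, -5, 6)
        goa = make_cr(conc, [[0.0]] * 6, ligand="probe", pathway="Goa")
        gob = operational_cr(0.7, -7.8, conc=conc, ligand="probe", pathway="Gob")
        table = goa_gob_concordance(goa, gob)
        assert np.all(table["deviation_from_unity"] >= 0)
        assert np.any(table["deviation_from_unity"] > 1)

    def test_mismatched_grids_raise(self):
        a = operational_cr(0.8, -7.0, conc=np.logspace(-10, -5, 6), ligand="L")
        b = operational_cr(0.8, -7.0, conc=np.logspace(-10, -4, 6), ligand="L")
        with pytest.raises(PairingError):
            goa_gob_concordance(a, b)

    def test_ligand_mismatch_raises(self):
        a, b = self._pair()
        b.ligand_id = "other"
        with pytest.raises(PairingError):
            goa_gob_concordance(a, b)
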