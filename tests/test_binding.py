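import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from biaskit.binding import (
    NoDisplacementError,
    cheng_prusoff,
    fit_competition_one_site,
    fit_competition_two_site,
    fit_saturation,
    two_site_displacement,
)
from biaskit.dose_response import InsufficientDataError
from biaskit.synthetic_data import simulate_competition

from conftest import make_cr

TRACER = dict(tracer_conc=1e-9, tracer_kd=1.23e-9)


class TestChengPrusoff:
    def test_zero_tracer_gives_ic50(self):
        assert cheng_prusoff(5e-9, 0.0, 1.23e-9) == 5e-9

    def test_tracer_at_kd_halves(self):
        assert cheng_prusoff(5e-9, 1.23e-9, 1.23e-9) == pytest.approx(2.5e-9, rel=1e-12)

    def test_study_tracer_constants(self):
        # DPCPX tracer at 1 nM with Kd 1.23 nM: IC50 1.813 nM -> Ki ~ 1.000 nM
        ki = cheng_prusoff(1.813e-9, 1e-9, 1.23e-9)
        assert ki == pytest.approx(1.000e-9, rel=1e-3)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cheng_prusoff(-1e-9, 1e-9, 1e-9)
        with pytest.raises(ValueError):
            cheng_prusoff(1e-9, 1e-9, 0.0)
        with pytest.raises(ValueError):
            cheng_prusoff(1e-9, -1e-9, 1e-9)

    @settings(deadline=None, max_examples=50)
    @given(ic50=st.floats(1e-12, 1e-4), occ1=st.floats(1e-6, 1e3), occ2=st.floats(1e-6, 1e3))
    def test_strictly_decreasing_in_occupancy(self, ic50, occ1, occ2):
        # strict within float resolution of 1 + [L]/Kd
        kd = 1e-9
        lo, hi = sorted([occ1, occ2])
        if hi - lo < 1e-9 * max(hi, 1.0):
            return
        assert cheng_prusoff(ic50, hi * kd, kd) < cheng_prusoff(ic50, lo * kd, kd)

    @settings(deadline=None, max_examples=50)
    @given(ic50=st.floats(1e-12, 1e-4), c=st.floats(1e-3, 1e3))
    def test_homogeneous_in_ic50(self, ic50, c):
        base = cheng_prusoff(ic50, 1e-9, 1.23e-9)
        assert cheng_prusoff(c * ic50, 1e-9, 1.23e-9) == pytest.approx(c * base, rel=1e-12)


class TestSaturation:
    def _hyperbola(self, kd=1.23e-9, bmax=1000.0, n=8):
        l = np.logspace(-10.5, -7.5, n)
        return l, bmax * l / (kd + l)

    def test_noiseless_kd_recovery(self):
        l, bound = self._hyperbola()
        res = fit_saturation(l, bound)
        assert res.kd == pytest.approx(1.23e-9, rel=1e-6)
        assert res.bmax == pytest.approx(1000.0, rel=1e-6)

    def test_half_saturation_at_kd(self):
        # with zero nonspecific binding, bound at [L] = K_d is exactly Bmax/2
        kd, bmax = 2e-9, 500.0
        l = np.sort(np.append(np.logspace(-10.5, -7.5, 7), kd))
        bound = bmax * l / (kd + l)
        assert bound[l == kd][0] == pytest.approx(bmax / 2, rel=1e-12)
        res = fit_saturation(l, bound, nonspecific=np.zeros_like(l))
        assert res.bmax == pytest.approx(bmax, rel=1e-6)

    def test_two_points_insufficient(self):
        with pytest.raises(InsufficientDataError):
            fit_saturation(np.array([1e-9, 1e-8]), np.array([100.0, 400.0]))

    def test_nonspecific_exceeding_total_clipped_with_note(self):
        l, bound = self._hyperbola()
        ns = np.full_like(bound, bound[2] + 1.0)  # exceeds total at low [L]
        res = fit_saturation(l, bound, nonspecific=ns)
        assert "clipped" in res.note


class TestOneSite:
    def test_recovers_known_ki(self):
        cr = simulate_competition("one_site", ki=1e-8, noise_sd=1.0, replicates=3,
                                  seed=11, **TRACER)
        res = fit_competition_one_site(cr, **TRACER)
        assert res.pki == pytest.approx(8.0, abs=0.02)

    def test_flat_displacement_raises(self):
        cr = make_cr(np.logspace(-10, -5, 8), [[100.0, 100.0]] * 8)
        with pytest.raises(NoDisplacementError):
            fit_competition_one_site(cr, **TRACER)

    def test_zero_tracer_limit_ki_equals_ic50(self):
        cr = simulate_competition("one_site", ki=1e-8, noise_sd=0.0,
                                  tracer_conc=0.0, tracer_kd=1.23e-9)
        res = fit_competition_one_site(cr, tracer_conc=0.0, tracer_kd=1.23e-9)
        assert res.ki == pytest.approx(1e-8, rel=1e-4)


class TestTwoSite:
    def test_recovers_biphasic_truth(self):
        # high-affinity site at 3.8 nM, low at 1 uM, equal fractions
        cr = simulate_competition("two_site", frac_high=0.5, ki_high=3.8e-9,
                                  ki_low=1e-6, noise_sd=1.0, replicates=3,
                                  seed=5, **TRACER)
        res = fit_competition_two_site(cr, **TRACER)
        assert res.model == "two_site"
        assert abs(np.log10(res.ki_high) - np.log10(3.8e-9)) < 0.1
        assert abs(np.log10(res.ki_low) - np.log10(1e-6)) < 0.1
        assert res.frac_high == pytest.approx(0.5, abs=0.1)
        assert res.ki_high <= res.ki_low

    def test_noiseless_recovery_tight(self):
        cr = simulate_competition("two_site", frac_high=0.5, ki_high=3.8e-9,
                                  ki_low=1e-6, noise_sd=0.0, **TRACER)
        res = fit_competition_two_site(cr, **TRACER)
        assert abs(np.log10(res.ki_high) - np.log10(3.8e-9)) < 0.02
        assert abs(np.log10(res.ki_low) - np.log10(1e-6)) < 0.02

    @pytest.mark.parametrize("frac", [1.0, 0.0])
    def test_monophasic_truth_collapses_to_one_site(self, frac):
        cr = simulate_competition("two_site", frac_high=frac, ki_high=1e-8,
                                  ki_low=1e-8, noise_sd=0.5, replicates=3,
                                  seed=2, **TRACER)
        res = fit_competition_two_site(cr, **TRACER)
        assert res.model == "one_site"
        assert "collapsed" in res.note

    def test_too_few_concentrations(self):
        cr = simulate_competition("two_site", concentrations=np.logspace(-10, -5, 6))
        with pytest.raises(InsufficientDataError):
            fit_competition_two_site(cr, **TRACER)

    def test_two_site_rss_never_worse_than_one_site(self):
        # nesting: the richer model fits at least as well on any data
        from biaskit.dose_response import fit_logistic3
        cr = simulate_competition("one_site", ki=3e-8, noise_sd=3.0, replicates=3,
                                  seed=9, **TRACER)
        one = fit_logistic3(cr, direction="inhibition")
        res = fit_competition_two_site(cr, **TRACER)
        # F statistic is computed from RSS1 >= RSS2; a finite, non-negative
        # value certifies the nesting held on this dataset
        assert np.isnan(res.f_statistic) or res.f_statistic >= 0

    def test_forward_model_plateaus(self):
        c = np.array([1e-15, 1e5])
        y = two_site_displacement(c, 100.0, 10.0, 0.3, 1e-9, 1e-6)
        assert y[0] == pytest.approx(100.0, abs=1e-3)
        assert y[1] == pytest.approx(10.0, abs=1e-3)
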