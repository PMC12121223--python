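"""Sensorgram models, global fitting, K_D arithmetic and binding screens."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgfhs import (binding_screen, fold_change, global_fit, kd_from_rates,
                   model_response, simulate_sensorgram, subtract_reference)
from fgfhs.kinetics import KineticsFitError, Sensorgram
from fgfhs.synthetic import SyntheticSpec

positive_rate = st.floats(0.01, 10.0)


def clean(kon, koff, rmax=1.0, concs=(0.2, 0.4, 0.8), seed=0):
    return simulate_sensorgram(kon, koff, rmax, concentrations=concs,
                               spec=SyntheticSpec(seed=seed, noise_sd=0.0))


class TestModelResponse:
    def test_zero_at_injection_start(self):
        p = {"kon": 0.4, "koff": 0.2, "rmax": 1.0}
        assert model_response(0.0, "association", p, C=0.5) == 0.0

    def test_half_saturation_at_kd(self):
        kon, koff, rmax = 0.42, 0.15, 2.0
        kd = koff / kon
        r = model_response(1e5, "association",
                           {"kon": kon, "koff": koff, "rmax": rmax}, C=kd)
        assert r == pytest.approx(rmax / 2, rel=1e-9)

    def test_observed_rate_is_kon_c_plus_koff(self):
        # time constant check: R(t)/R_inf = 1 - exp(-k_obs t), k_obs = 0.318
        p = {"kon": 0.42, "koff": 0.15, "rmax": 1.0}
        t = 1.0 / 0.318
        r_inf = model_response(1e5, "association", p, C=0.4)
        r = model_response(t, "association", p, C=0.4)
        assert r / r_inf == pytest.approx(1 - np.exp(-1), rel=1e-9)

    def test_dissociation_decays_to_zero(self):
        p = {"kon": 0.42, "koff": 0.15, "rmax": 1.0}
        assert model_response(500.0, "dissociation", p, C=0.4,
                              t_assoc=450.0) == pytest.approx(0.0, abs=1e-12)

    def test_two_equal_sites_equal_one_doubled_site(self):
        t = np.linspace(0, 450, 200)
        one = model_response(t, "association",
                             {"kon": 0.3, "koff": 0.1, "rmax": 2.0}, C=0.4)
        two = model_response(t, "association",
                             {"kon": (0.3, 0.3), "koff": (0.1, 0.1),
                              "rmax": (1.0, 1.0)}, C=0.4)
        assert np.allclose(one, two, rtol=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(positive_rate, positive_rate, st.floats(0.05, 5.0))
    def test_phase_monotonicity(self, kon, koff, conc):
        t = np.linspace(0, 450, 300)
        p = {"kon": kon, "koff": koff, "rmax": 1.0}
        assoc = model_response(t, "association", p, C=conc)
        dissoc = model_response(t, "dissociation", p, C=conc, t_assoc=450.0)
        assert np.all(np.diff(assoc) >= -1e-12)
        assert np.all(np.diff(dissoc) <= 1e-12)


class TestGlobalFit:
    def test_noiseless_round_trip_exact(self):
        fit = global_fit(clean(0.42, 0.15))
        assert fit.kon[0] == pytest.approx(0.42, rel=1e-6)
        assert fit.koff[0] == pytest.approx(0.15, rel=1e-6)
        assert fit.kd_reported == pytest.approx(0.15 / 0.42, rel=1e-6)

    @pytest.mark.parametrize("kon,koff", [(0.19, 1.43), (6.83, 0.52),
                                          (0.71, 0.30)])
    def test_round_trip_across_published_rate_range(self, kon, koff):
        fit = global_fit(clean(kon, koff))
        assert fit.kon[0] == pytest.approx(kon, rel=1e-5)
        assert fit.koff[0] == pytest.approx(koff, rel=1e-5)

    def test_noisy_recovery_median_within_five_percent(self):
        kons = []
        for seed in range(25):
            traces = simulate_sensorgram(0.42, 0.15, 1.0,
                                         spec=SyntheticSpec(seed=seed))
            kons.append(global_fit(traces).kon[0])
        assert abs(np.median(kons) - 0.42) / 0.42 < 0.05

    def test_two_site_data_prefers_two_site_model(self):
        t = np.arange(0.0, 900.5, 0.5)
        rng = np.random.default_rng(11)
        traces = []
        for conc in (0.2, 0.4, 0.8):
            r = (model_response(np.minimum(t, 450.0), "association",
                                {"kon": (0.5, 0.05), "koff": (0.05, 0.8),
                                 "rmax": (0.6, 0.4)}, C=conc)
                 * (t <= 450.0))
            tail = model_response(np.maximum(t - 450.0, 0.0), "dissociation",
                                  {"kon": (0.5, 0.05), "koff": (0.05, 0.8),
                                   "rmax": (0.6, 0.4)}, C=conc, t_assoc=450.0)
            resp = np.where(t <= 450.0, r, tail) + rng.normal(0, 0.002, t.shape)
            traces.append(Sensorgram(t, resp, conc, 450.0))
        fit1 = global_fit(traces, n_sites=1)
        fit2 = global_fit(traces, n_sites=2)
        assert fit2.residual_sd < fit1.residual_sd
        assert fit2.n_sites == 2
        assert fit2.reported_site == int(np.argmax(fit2.rmax))

    def test_stderr_reported_under_noise(self):
        traces = simulate_sensorgram(0.42, 0.15, 1.0,
                                     spec=SyntheticSpec(seed=3))
        fit = global_fit(traces)
        assert 0 < fit.stderr["kon1"] < 0.05

    def test_flat_traces_raise_diagnostic(self):
        t = np.arange(0.0, 900.5, 0.5)
        flat = [Sensorgram(t, np.zeros_like(t), c, 450.0)
                for c in (0.2, 0.4, 0.8)]
        with pytest.raises(KineticsFitError):
            global_fit(flat)


class TestKdArithmetic:
    def test_published_bcd_rates_give_printed_kd(self):
        assert kd_from_rates(0.42, 0.15) == pytest.approx(0.357, abs=5e-4)

    def test_published_hs_rates_give_printed_kd(self):
        assert kd_from_rates(0.19, 1.43) == pytest.approx(7.53, abs=5e-3)

    def test_equal_rates_give_unity(self):
        assert kd_from_rates(0.3, 0.3) == 1.0

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            kd_from_rates(0.0, 0.1)
        with pytest.raises(ValueError):
            fold_change(-1.0, 0.1)

    def test_fold_change_published_claim(self):
        assert fold_change(7.37, 0.35) == pytest.approx(21.06, abs=5e-3)
        assert fold_change(7.37, 0.35) > 20

    def test_fold_change_identity_and_inversion(self):
        assert fold_change(0.35, 0.35) == 1.0
        assert fold_change(2.0, 0.5) == pytest.approx(
            1.0 / fold_change(0.5, 2.0))


class TestBindingScreen:
    def test_strong_binder_called_bound(self):
        traces = simulate_sensorgram(0.42, 0.15, 1.0, ligand="FGFR1",
                                     spec=SyntheticSpec(seed=0, noise_sd=0.0))
        result = binding_screen(traces, threshold=0.05)
        assert result["FGFR1"][0] is True

    def test_flat_trace_not_bound(self):
        t = np.arange(0.0, 900.5, 0.5)
        s = Sensorgram(t, np.zeros_like(t), 0.4, 450.0, ligand="ctrl")
        assert binding_screen([s], threshold=0.05)["ctrl"][0] is False

    def test_bound_set_monotone_in_threshold(self):
        traces = []
        for i, rmax in enumerate((0.1, 0.5, 1.0)):
            traces += simulate_sensorgram(
                0.42, 0.15, rmax, ligand=f"L{i}",
                spec=SyntheticSpec(seed=i, noise_sd=0.0))
        sizes = []
        for thr in (0.01, 0.05, 0.2, 0.6, 2.0):
            called = binding_screen(traces, thr)
            sizes.append(sum(1 for b, _ in called.values() if b))
        assert sizes == sorted(sizes, reverse=True)


def test_reference_subtraction():
    t = np.arange(0.0, 900.5, 0.5)
    base = clean(0.42, 0.15)[0]
    drift = Sensorgram(base.time, np.full_like(base.time, 0.02), 0.2, 450.0)
    corrected = subtract_reference(base, drift)
    assert np.allclose(corrected.response, base.response - 0.02)


def test_csv_round_trip(tmp_path):
    from fgfhs.kinetics import read_sensorgram_csv, write_sensorgram_csv
    traces = clean(0.42, 0.15)
    path = tmp_path / "bli.csv"
    write_sensorgram_csv(traces, path)
    back = read_sensorgram_csv(path)
    assert [s.concentration for s in back] == [0.2, 0.4, 0.8]
    assert np.allclose(back[0].response, traces[0].response)
    assert back[0].t_assoc == traces[0].t_assoc
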